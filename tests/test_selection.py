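"""Stratum assignment, stratified draws and plan design checks."""

import numpy as np
import pytest

from leangrade import (
    Carcass,
    StratificationPlan,
    assign_fat_group,
    assign_weight_group,
    default_plan,
    select_sample,
    validate_plan,
)


def _carcass(i, weight=95.0, f2=14.0):
    return Carcass(id=f"c{i}", sex="gilt", hot_weight=weight, f2=f2, m2=62.0,
                   ytd_true=59.0, ypd_obs=66.0)


class TestAssignment:
    @pytest.mark.parametrize(
        "f2,group",
        [(9.0, 1), (10.0, 1), (10.5, 2), (11.0, 2), (18.0, 2), (18.5, 3), (31.0, 3)],
    )
    def test_fat_group_boundaries(self, f2, group):
        assert assign_fat_group(f2) == group

    @pytest.mark.parametrize(
        "w,group",
        [(60.0, "A"), (84.4, "A"), (84.45, "B"), (84.5, "B"), (105.5, "B"),
         (105.6, "C"), (120.0, "C")],
    )
    def test_weight_group_boundaries(self, w, group):
        assert assign_weight_group(w) == group

    @pytest.mark.parametrize("w", [59.9, 120.1, -5.0])
    def test_weight_outside_plan_range_rejected(self, w):
        with pytest.raises(ValueError, match="range"):
            assign_weight_group(w)

    def test_non_positive_fat_rejected(self):
        with pytest.raises(ValueError):
            assign_fat_group(0.0)

    def test_assignment_partitions_and_is_monotone(self):
        """Every in-range measurement gets exactly one cell; groups are monotone."""
        plan = default_plan()
        fat = [assign_fat_group(x, plan) for x in np.linspace(0.1, 55, 500)]
        wgt = [assign_weight_group(x, plan) for x in np.linspace(60, 120, 500)]
        assert fat == sorted(fat)
        assert wgt == sorted(wgt)
        assert set(fat) == {1, 2, 3} and set(wgt) == {"A", "B", "C"}


class TestSelectSample:
    def test_default_plan_achieved_exactly_on_large_population(self, medium_population):
        plan = default_plan()
        res = select_sample(medium_population, plan, seed=1)
        assert np.array_equal(res.achieved_counts, plan.required_counts)
        assert np.array_equal(res.achieved_subsample, plan.required_subsample)
        assert len(res.selected) == 126
        assert len(res.subsample) == 12
        assert res.shortfalls == []

    def test_labels_match_measurements(self, medium_population):
        plan = default_plan()
        res = select_sample(medium_population, plan, seed=1)
        for c, f, w in zip(res.selected, res.fat_groups, res.weight_groups):
            assert assign_fat_group(c.f2, plan) == f
            assert assign_weight_group(c.hot_weight, plan) == w

    def test_no_carcass_selected_twice(self, medium_population):
        res = select_sample(medium_population, default_plan(), seed=3)
        ids = [c.id for c in res.selected]
        assert len(ids) == len(set(ids))

    def test_exact_fit_population_selected_entirely(self):
        """A population of exactly the required carcasses per cell is taken whole."""
        plan = default_plan()
        pop, k = [], 0
        f2_by_group = {1: 8.0, 2: 14.0, 3: 22.0}
        w_by_group = {"A": 80.0, "B": 95.0, "C": 110.0}
        for wi, wlab in enumerate("ABC"):
            for fi in range(3):
                for _ in range(int(plan.required_counts[wi, fi])):
                    pop.append(_carcass(k, weight=w_by_group[wlab], f2=f2_by_group[fi + 1]))
                    k += 1
        res = select_sample(pop, plan, seed=0)
        assert len(res.selected) == len(pop)
        assert res.shortfalls == []
        assert sorted(c.id for c in res.selected) == sorted(c.id for c in pop)

    def test_empty_cell_recorded_as_shortfall(self):
        """An empty light-weight/fat cell yields its full requirement as deficit."""
        plan = default_plan()
        pop = [_carcass(i, weight=95.0, f2=14.0) for i in range(200)]  # all (B, 2)
        res = select_sample(pop, plan, seed=0)
        assert ("A", 3, 7) in res.shortfalls
        # achieved + deficit = required, cell-wise
        deficit = np.zeros_like(plan.required_counts)
        for w, f, d in res.shortfalls:
            deficit["ABC".index(w), f - 1] = d
        assert np.array_equal(res.achieved_counts + deficit, plan.required_counts)

    def test_duplicate_ids_rejected(self):
        pop = [_carcass(1), _carcass(1)]
        with pytest.raises(ValueError, match="duplicate"):
            select_sample(pop, default_plan(), seed=0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_sample([], default_plan(), seed=0)

    def test_seed_determinism(self, medium_population):
        a = select_sample(medium_population, default_plan(), seed=5)
        b = select_sample(medium_population, default_plan(), seed=5)
        assert [c.id for c in a.selected] == [c.id for c in b.selected]
        assert a.in_subsample == b.in_subsample

    def test_subsample_is_subset_of_selected(self, medium_population):
        res = select_sample(medium_population, default_plan(), seed=2)
        selected_ids = {c.id for c in res.selected}
        assert all(c.id in selected_ids for c in res.subsample)


class TestPlanValidation:
    def test_default_plan_passes_design_checks(self):
        plan = default_plan()
        assert plan.n_required == 126
        assert plan.n_subsample == 12
        assert plan.required_counts.sum(axis=0).tolist() == [30, 66, 30]
        assert plan.required_counts.sum(axis=1).tolist() == [32, 62, 32]
        report = validate_plan(plan)
        assert report.ok

    def test_flat_ratio_fails(self):
        plan = StratificationPlan(
            required_counts=np.full((3, 3), 10),
            required_subsample=np.ones((3, 3), dtype=int),
        )
        report = validate_plan(plan)
        assert not report.fat_ratio_ok and not report.weight_ratio_ok

    def test_tiny_subsample_fails_ten_percent_check(self):
        plan = StratificationPlan(
            required_subsample=np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]])
        )
        report = validate_plan(plan)
        assert not report.subsample_fraction_ok
        assert report.subsample_fraction == pytest.approx(3 / 126)

    def test_subsample_exceeding_sample_rejected(self):
        with pytest.raises(ValueError, match="subsample"):
            StratificationPlan(required_subsample=np.full((3, 3), 20))
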