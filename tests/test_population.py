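"""Synthetic population generator: moments, latent structure, determinism."""

import numpy as np
import pytest
from scipy import stats

from leangrade import (
    Carcass,
    PopulationParams,
    compute_ypd,
    compute_ytd,
    generate_cut_weights,
    generate_population,
)
from leangrade.population import TRUNCATION_BOUNDS


def _columns(pop):
    return (
        np.array([c.hot_weight for c in pop]),
        np.array([c.f2 for c in pop]),
        np.array([c.m2 for c in pop]),
    )


class TestGeneratePopulation:
    def test_moment_recovery_against_truncated_gaussian(self, medium_population):
        """Sample moments match the truncated-Gaussian marginals within MC error.

        Truncation to the measurement bounds shifts the marginal moments
        slightly away from the requested Gaussian parameters; the 1-d
        truncated normal predicts that shift (the 0.15 weight-fat
        correlation perturbs it by well under the tolerance).
        """
        p = PopulationParams()
        n = len(medium_population)
        cols = _columns(medium_population)
        specs = [
            ("weight", p.mean_weight, p.sd_weight),
            ("f2", p.mean_f2, p.sd_f2),
            ("m2", p.mean_m2, p.sd_m2),
        ]
        for (name, mu, sd), x in zip(specs, cols):
            lo, hi = TRUNCATION_BOUNDS[name]
            tn = stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
            se_mean = tn.std() / np.sqrt(n)
            assert x.mean() == pytest.approx(tn.mean(), abs=4 * se_mean + 0.05)
            assert x.std(ddof=1) == pytest.approx(tn.std(), abs=4 * sd / np.sqrt(2 * n) + 0.05)
            # coarse sanity against the requested parameters themselves
            assert x.mean() == pytest.approx(mu, abs=0.05 * sd + 0.3)

    def test_truncation_bounds_hold(self, medium_population):
        w, f, m = _columns(medium_population)
        assert w.min() >= 60 and w.max() <= 120
        assert f.min() >= 3 and f.max() <= 55
        assert m.min() >= 21 and m.max() <= 99

    def test_weight_f2_correlation_sign(self, medium_population):
        w, f, _ = _columns(medium_population)
        r = np.corrcoef(w, f)[0, 1]
        assert 0.05 < r < 0.25  # requested +0.15

    def test_noise_free_identity(self, noise_free_params):
        """With no noise and unit dissection ratio, ypd_obs is exactly linear."""
        p = noise_free_params
        for c in generate_population(p):
            expected = p.beta0 + p.beta_f * c.f2 + p.beta_m * c.m2
            assert c.ypd_obs == pytest.approx(expected, abs=1e-12)
            assert c.ytd_true == pytest.approx(expected, abs=1e-12)

    def test_dissection_ratio_forced_by_construction(self):
        """With no partial-dissection noise, ytd/ypd equals sf_true per carcass."""
        p = PopulationParams(n=10_000, sf_true=0.89, sigma_delta=0.0, seed=5)
        pop = generate_population(p)
        ratios = np.array([c.ytd_true / c.ypd_obs for c in pop])
        assert np.mean(ratios) == pytest.approx(0.89, abs=1e-4)
        assert np.allclose(ratios, 0.89, atol=1e-12)

    def test_seed_determinism(self):
        p = PopulationParams(n=500, seed=99)
        a, b = generate_population(p), generate_population(p)
        assert all(
            x.id == y.id and x.sex == y.sex and x.hot_weight == y.hot_weight
            and x.f2 == y.f2 and x.m2 == y.m2 and x.ytd_true == y.ytd_true
            and x.ypd_obs == y.ypd_obs
            for x, y in zip(a, b)
        )

    def test_sex_fractions(self, medium_population):
        gilts = sum(c.sex == "gilt" for c in medium_population)
        frac = gilts / len(medium_population)
        assert frac == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"sd_f2": -1.0},
            {"gilt_fraction": 1.5},
            {"sf_true": 0.0},
            {"corr_weight_f2": 1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationParams(**kwargs)

    def test_non_positive_definite_correlation_rejected(self):
        p = PopulationParams(corr_weight_f2=0.9, corr_f2_m2=-0.9)
        with pytest.raises(ValueError, match="positive definite"):
            generate_population(p)


class TestGenerateCutWeights:
    def test_round_trip_reproduces_latent_lmp(self, medium_population):
        """Dissection formulas on generated cuts recover both LMP values."""
        for i, c in enumerate(medium_population[:200]):
            cw = generate_cut_weights(c, seed=i)
            assert compute_ypd(cw) == pytest.approx(c.ypd_obs, abs=1e-9)
            ytd = compute_ytd(cw.total_lean_weight, cw.half_carcass_weight)
            assert ytd == pytest.approx(c.ytd_true, abs=1e-9)

    def test_half_and_total_lean_weights(self):
        c = Carcass(id="x", sex="gilt", hot_weight=100.0, f2=14.0, m2=60.0,
                    ytd_true=50.0, ypd_obs=56.0)
        cw = generate_cut_weights(c, seed=0)
        assert cw.half_carcass_weight == 50.0
        assert cw.total_lean_weight == pytest.approx(25.0)

    def test_determinism(self, medium_population):
        c = medium_population[0]
        assert generate_cut_weights(c, seed=7) == generate_cut_weights(c, seed=7)
        assert generate_cut_weights(c, seed=7) != generate_cut_weights(c, seed=8)

    def test_missing_lmp_refused(self):
        c = Carcass(id="x", sex="gilt", hot_weight=100.0, f2=14.0, m2=60.0)
        with pytest.raises(ValueError, match="ypd_obs"):
            generate_cut_weights(c, seed=0)

    def test_infeasible_lean_allocation_refused(self):
        # YPD below the tenderloin's share of the cut mass is unrealizable
        c = Carcass(id="x", sex="gilt", hot_weight=100.0, f2=14.0, m2=60.0,
                    ytd_true=1.0, ypd_obs=0.5)
        with pytest.raises(ValueError, match="feasible|lean"):
            generate_cut_weights(c, seed=0)

    def test_lean_never_exceeds_joint(self, medium_population):
        for i, c in enumerate(medium_population[200:300]):
            cw = generate_cut_weights(c, seed=i)
            assert cw.lean_shoulder <= cw.joint_shoulder
            assert cw.lean_loin <= cw.joint_loin
            assert cw.lean_ham <= cw.joint_ham
            assert cw.lean_belly <= cw.joint_belly
            assert cw.tenderloin + cw.joint_shoulder + cw.joint_loin + cw.joint_ham \
                + cw.joint_belly <= cw.half_carcass_weight
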