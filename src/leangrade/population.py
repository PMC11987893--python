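"""Synthetic pig-carcass population generator.

Emulates the statistical structure of a national slaughter population as
seen by a grading trial: hot carcass weight, backfat depth (F2) and loin
muscle depth (M2) jointly Gaussian with configurable correlations,
truncated to the plausible measurement range; a latent "true" lean meat
percentage (total-dissection LMP, YTD) that is linear in (F2, M2) plus
biological residual; and an observable partial-dissection LMP (YPD) that
over-states YTD by a multiplicative dissection bias (the inverse of the
scaling factor) plus butcher measurement noise.

Default moments follow the surveyed Polish population: weight 95.0 ± 10.6
kg, F2 13.86 ± 4.26 mm, M2 62.20 ± 8.40 mm, half gilts / half castrates,
the 2023 CGM equation as the latent LMP model with residual SD 2.2 LMP
points, and a partial/total dissection ratio of 0.89.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PopulationParams",
    "Carcass",
    "CutWeights",
    "generate_population",
    "generate_cut_weights",
    "DEFAULT_CUT_PROPORTIONS",
    "DEFAULT_CUTOUT_FRACTION",
]

# Measurement truncation range: weight kg, F2 mm, M2 mm (population min/max).
TRUNCATION_BOUNDS = {
    "weight": (60.0, 120.0),
    "f2": (3.0, 55.0),
    "m2": (21.0, 99.0),
}

#: Share of the half carcass in tenderloin, shoulder, loin, ham, belly joints.
DEFAULT_CUT_PROPORTIONS = (0.015, 0.25, 0.23, 0.30, 0.20)
#: Fraction of the half carcass entering the five reference cuts.
DEFAULT_CUTOUT_FRACTION = 0.75

CUT_NAMES = ("tenderloin", "shoulder", "loin", "ham", "belly")


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the synthetic carcass population.

    Means/SDs are in the measurement units (kg, mm); ``beta0``, ``beta_f``,
    ``beta_m`` are the latent LMP equation coefficients (% and % per mm);
    ``sigma_ytd`` is the biological residual SD of true LMP about that
    linear model (LMP points); ``sf_true`` is the total/partial dissection
    ratio (YPD is generated as YTD / sf_true); ``sigma_delta`` is the
    partial-dissection measurement noise SD (LMP points).
    """

    n: int = 1000
    mean_weight: float = 95.0
    sd_weight: float = 10.6
    mean_f2: float = 13.86
    sd_f2: float = 4.26
    mean_m2: float = 62.20
    sd_m2: float = 8.40
    corr_weight_f2: float = 0.15
    corr_f2_m2: float = 0.0
    gilt_fraction: float = 0.5
    beta0: float = 60.7538
    beta_f: float = -0.6465
    beta_m: float = 0.1243
    sigma_ytd: float = 2.2
    sf_true: float = 0.89
    sigma_delta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("sd_weight", "sd_f2", "sd_m2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("sigma_ytd", "sigma_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gilt_fraction <= 1.0:
            raise ValueError("gilt_fraction must be in [0, 1]")
        if not 0.0 < self.sf_true <= 1.2:
            raise ValueError("sf_true must be in (0, 1.2]")
        for name in ("corr_weight_f2", "corr_f2_m2"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (-1, 1)")

    def correlation_matrix(self) -> np.ndarray:
        """3x3 correlation of (weight, f2, m2); weight–m2 assumed uncorrelated."""
        r = np.array(
            [
                [1.0, self.corr_weight_f2, 0.0],
                [self.corr_weight_f2, 1.0, self.corr_f2_m2],
                [0.0, self.corr_f2_m2, 1.0],
            ]
        )
        return r

    def covariance_matrix(self) -> np.ndarray:
        sd = np.array([self.sd_weight, self.sd_f2, self.sd_m2])
        return self.correlation_matrix() * np.outer(sd, sd)

    def with_(self, **kwargs) -> "PopulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class Carcass:
    """One carcass: identity, sex, probe measurements and latent LMP values.

    ``ytd_true`` is the lean meat percentage a full half-carcass dissection
    would find; ``ypd_obs`` the (biased, noisy) partial-dissection LMP.
    """

    id: str
    sex: str  # "gilt" or "castrate"
    hot_weight: float  # kg
    f2: float  # mm
    m2: float  # mm
    ytd_true: Optional[float] = None  # %
    ypd_obs: Optional[float] = None  # %

    def __post_init__(self) -> None:
        if self.hot_weight <= 0 or self.f2 <= 0 or self.m2 <= 0:
            raise ValueError(
                f"carcass {self.id}: weight/f2/m2 must be positive "
                f"(got {self.hot_weight}, {self.f2}, {self.m2})"
            )
        for name in ("ytd_true", "ypd_obs"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 100.0:
                raise ValueError(f"carcass {self.id}: {name}={v} outside (0, 100)")


@dataclass
class CutWeights:
    """Joint and lean weights (kg) of the five reference cuts of a half carcass.

    The tenderloin is removed whole and counts entirely as lean; the four
    main cuts (shoulder, loin, ham, belly) each have a pre-dissection joint
    weight and a dissected lean weight.  ``total_lean_weight`` is only
    available after a total dissection of the half carcass.
    """

    tenderloin: float
    joint_shoulder: float
    joint_loin: float
    joint_ham: float
    joint_belly: float
    lean_shoulder: float
    lean_loin: float
    lean_ham: float
    lean_belly: float
    half_carcass_weight: float
    total_lean_weight: Optional[float] = None

    def __post_init__(self) -> None:
        joints = (self.joint_shoulder, self.joint_loin, self.joint_ham, self.joint_belly)
        leans = (self.lean_shoulder, self.lean_loin, self.lean_ham, self.lean_belly)
        if self.tenderloin < 0 or any(j < 0 for j in joints) or any(l < 0 for l in leans):
            raise ValueError("all cut weights must be non-negative")
        for name, j, l in zip(("shoulder", "loin", "ham", "belly"), joints, leans):
            if l > j * (1 + 1e-12):
                raise ValueError(f"lean weight of {name} ({l}) exceeds its joint weight ({j})")
        if self.tenderloin + sum(joints) > self.half_carcass_weight * (1 + 1e-12):
            raise ValueError("cut weights exceed the half-carcass weight")
        if self.total_lean_weight is not None and (
            self.total_lean_weight < 0
            or self.total_lean_weight > self.half_carcass_weight * (1 + 1e-12)
        ):
            raise ValueError("total lean weight must be within [0, half-carcass weight]")


def _truncated_mvn(
    rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray, n: int
) -> np.ndarray:
    """Rejection-sample n rows of N(mean, cov) inside the measurement bounds."""
    lo = np.array([b[0] for b in TRUNCATION_BOUNDS.values()])
    hi = np.array([b[1] for b in TRUNCATION_BOUNDS.values()])
    out = np.empty((0, 3))
    # acceptance rate is high for the default moments; cap iterations anyway
    for _ in range(1000):
        need = n - len(out)
        if need <= 0:
            break
        draw = rng.multivariate_normal(mean, cov, size=max(need * 2, 128), method="cholesky")
        ok = np.all((draw >= lo) & (draw <= hi), axis=1)
        out = np.vstack([out, draw[ok]])
    if len(out) < n:
        raise RuntimeError(
            "truncated sampling failed to reach the requested size; "
            "the parameters place almost no mass inside the measurement bounds"
        )
    return out[:n]


def generate_population(params: PopulationParams) -> list[Carcass]:
    """Draw a synthetic carcass population.

    (weight, F2, M2) come from a truncated trivariate Gaussian;
    ``ytd_true = beta0 + beta_f*F2 + beta_m*M2 + eps`` with
    ``eps ~ N(0, sigma_ytd)``; ``ypd_obs = ytd_true / sf_true + delta`` with
    ``delta ~ N(0, sigma_delta)``.  Noise draws that would push an LMP value
    outside (0, 100) are redrawn.  Fully reproducible for a fixed seed.

    Raises
    ------
    ValueError
        If the implied correlation matrix is not positive definite.
    """
    corr = params.correlation_matrix()
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"correlation matrix is not positive definite for "
            f"corr_weight_f2={params.corr_weight_f2}, corr_f2_m2={params.corr_f2_m2}"
        ) from exc

    rng = np.random.default_rng(params.seed)
    mean = np.array([params.mean_weight, params.mean_f2, params.mean_m2])
    xyz = _truncated_mvn(rng, mean, params.covariance_matrix(), params.n)
    weight, f2, m2 = xyz.T

    lin = params.beta0 + params.beta_f * f2 + params.beta_m * m2

    def _bounded_noise(base: np.ndarray, sigma: float) -> np.ndarray:
        """base + N(0, sigma), redrawing draws that leave (0, 100)."""
        val = base + rng.normal(0.0, sigma, size=len(base))
        for _ in range(100):
            bad = (val <= 0.0) | (val >= 100.0)
            if not bad.any():
                return val
            val[bad] = base[bad] + rng.normal(0.0, sigma, size=int(bad.sum()))
        raise RuntimeError("could not keep LMP values inside (0, 100); check beta/sigma settings")

    ytd = _bounded_noise(lin, params.sigma_ytd)
    ypd = _bounded_noise(ytd / params.sf_true, params.sigma_delta)
    sex = np.where(rng.random(params.n) < params.gilt_fraction, "gilt", "castrate")

    width = max(6, len(str(params.n)))
    return [
        Carcass(
            id=f"C{i + 1:0{width}d}",
            sex=str(sex[i]),
            hot_weight=float(weight[i]),
            f2=float(f2[i]),
            m2=float(m2[i]),
            ytd_true=float(ytd[i]),
            ypd_obs=float(ypd[i]),
        )
        for i in range(params.n)
    ]


def generate_cut_weights(
    carcass: Carcass,
    seed: int,
    cut_proportions: Sequence[float] = DEFAULT_CUT_PROPORTIONS,
    cutout_fraction: float = DEFAULT_CUTOUT_FRACTION,
    dirichlet_concentration: float = 200.0,
) -> CutWeights:
    """Realize joint/lean cut weights consistent with a carcass's LMP values.

    Joint weights are Dirichlet-perturbed fixed proportions of
    ``cutout_fraction`` of the half carcass.  Lean weights are allocated
    proportionally to joint weights and scaled so that the partial-dissection
    formula reproduces ``carcass.ypd_obs`` exactly, and the total lean weight
    so that the total-dissection formula reproduces ``carcass.ytd_true``.

    Raises
    ------
    ValueError
        If the carcass lacks LMP values or the requested YPD is infeasible
        for the drawn joint weights (required lean negative or above the
        joint weight).
    """
    if carcass.ypd_obs is None or carcass.ytd_true is None:
        raise ValueError(f"carcass {carcass.id}: needs ypd_obs and ytd_true to realize cuts")
    if len(cut_proportions) != 5:
        raise ValueError("cut_proportions must give 5 shares (tenderloin + 4 main cuts)")
    if not 0.0 < cutout_fraction <= 1.0:
        raise ValueError("cutout_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    half = carcass.hot_weight / 2.0
    base = np.asarray(cut_proportions, dtype=float)
    cut_mass = base.sum() * cutout_fraction * half
    shares = rng.dirichlet(dirichlet_concentration * base / base.sum())
    tender, *joints = (shares * cut_mass).tolist()
    joints = np.array(joints)
    joint_sum = joints.sum()

    # lean mass the four main cuts must contribute for the YPD identity
    need_lean = carcass.ypd_obs / 100.0 * (tender + joint_sum) - tender
    if need_lean < 0:
        raise ValueError(
            f"carcass {carcass.id}: ypd_obs={carcass.ypd_obs:.2f}% below the "
            "tenderloin share; no feasible lean allocation"
        )
    if need_lean > joint_sum:
        raise ValueError(
            f"carcass {carcass.id}: required lean {need_lean:.2f} kg exceeds the "
            f"joint weights {joint_sum:.2f} kg"
        )
    leans = joints * (need_lean / joint_sum)
    total_lean = carcass.ytd_true / 100.0 * half

    return CutWeights(
        tenderloin=tender,
        joint_shoulder=float(joints[0]),
        joint_loin=float(joints[1]),
        joint_ham=float(joints[2]),
        joint_belly=float(joints[3]),
        lean_shoulder=float(leans[0]),
        lean_loin=float(leans[1]),
        lean_ham=float(leans[2]),
        lean_belly=float(leans[3]),
        half_carcass_weight=half,
        total_lean_weight=total_lean,
    )
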