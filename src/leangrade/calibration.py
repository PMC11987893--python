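"""Fitting and validating a device prediction equation.

EU rules fit the lean-meat prediction equation of a grading device by
partial least squares / principal components regression (with two
predictors and full rank the three families coincide with ordinary least
squares) and judge it by the cross-validated root mean square error of
prediction, RMSEP = sqrt(PRESS / n), with PRESS the leave-one-out
predicted residual sum of squares.  A device is authorized when
RMSEP < 2.5 LMP points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .equations import PredictionEquation

__all__ = [
    "CalibrationDataset",
    "CalibrationReport",
    "RMSEP_LIMIT",
    "fit_pls_pcr",
    "press_loo_rmsep",
    "authorize",
    "calibrate",
]

#: Authorization threshold on RMSEP, LMP points (strict inequality).
RMSEP_LIMIT = 2.5


@dataclass
class CalibrationDataset:
    """Per-carcass (F2, M2, reference LMP) triples for equation fitting."""

    f2: np.ndarray
    m2: np.ndarray
    lmp_ref: np.ndarray

    def __post_init__(self) -> None:
        self.f2 = np.asarray(self.f2, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        self.lmp_ref = np.asarray(self.lmp_ref, dtype=float)
        if not (self.f2.shape == self.m2.shape == self.lmp_ref.shape) or self.f2.ndim != 1:
            raise ValueError("f2, m2, lmp_ref must be 1-d arrays of equal length")
        if self.n < 3:
            raise ValueError(f"need at least 3 carcasses, got {self.n}")
        for name, a in (("f2", self.f2), ("m2", self.m2), ("lmp_ref", self.lmp_ref)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.lmp_ref)

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.f2, self.m2])


def _check_rank(X: np.ndarray, n_components: int) -> None:
    if n_components == 2 and np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-10) < 2:
        raise ValueError("predictors are collinear; a 2-component fit is not identifiable")


def fit_pls_pcr(data: CalibrationDataset, n_components: int = 2) -> PredictionEquation:
    """Fit the prediction equation by PLS regression on centered (F2, M2).

    With ``n_components=2`` (full rank on two predictors) the fit equals
    ordinary least squares; ``n_components=1`` gives the rank-reduced PLS
    solution.  Coefficients are returned on the original measurement scale.
    """
    if n_components not in (1, 2):
        raise ValueError(f"n_components must be 1 or 2, got {n_components}")
    if data.n < n_components + 1:
        raise ValueError(f"need n > n_components ({data.n} rows for {n_components} components)")
    X = data.X
    _check_rank(X, n_components)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, data.lmp_ref.reshape(-1, 1))
    coef = pls.coef_.ravel()
    # intercept on the original scale: y_bar - beta . x_bar
    intercept = float(data.lmp_ref.mean() - coef @ X.mean(axis=0))
    return PredictionEquation(
        intercept=intercept,
        coef_f2=float(coef[0]),
        coef_m2=float(coef[1]),
        label=f"fitted(n={data.n}, ncomp={n_components})",
    )


def press_loo_rmsep(
    data: CalibrationDataset, n_components: int = 2, method: str = "refit"
) -> float:
    """Leave-one-out RMSEP via the PRESS statistic.

    ``method="refit"`` re-fits the equation on each n-1 subset (the PRESS
    definition, valid for any component count); ``method="hat"`` uses the
    closed-form least-squares identity e_i / (1 - h_ii) and requires the
    full-rank 2-component fit, where it equals the refit loop to machine
    precision.
    """
    if data.n < 4:
        raise ValueError(f"leave-one-out needs at least 4 rows, got {data.n}")
    y = data.lmp_ref
    if method == "hat":
        if n_components != 2:
            raise ValueError("the hat-matrix shortcut requires the full 2-component fit")
        A = np.column_stack([np.ones(data.n), data.X])
        _check_rank(data.X, 2)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        leverage = np.einsum("ij,ji->i", A, np.linalg.solve(A.T @ A, A.T))
        press_resid = resid / (1.0 - leverage)
        return float(np.sqrt(np.mean(press_resid**2)))
    if method != "refit":
        raise ValueError(f"unknown method {method!r}; use 'refit' or 'hat'")

    sq = 0.0
    mask = np.ones(data.n, dtype=bool)
    for i in range(data.n):
        mask[i] = False
        fold = CalibrationDataset(data.f2[mask], data.m2[mask], y[mask])
        eq = fit_pls_pcr(fold, n_components=n_components)
        sq += (y[i] - eq(data.f2[i], data.m2[i])) ** 2
        mask[i] = True
    return float(np.sqrt(sq / data.n))


def authorize(rmsep: float, limit: float = RMSEP_LIMIT) -> bool:
    """Authorization verdict: RMSEP strictly below the limit."""
    if rmsep < 0:
        raise ValueError(f"RMSEP must be non-negative, got {rmsep}")
    return rmsep < limit


@dataclass
class CalibrationReport:
    """Fitted equation, cross-validated error and authorization verdict."""

    equation: PredictionEquation
    rmsep: float
    n: int
    n_components: int
    authorized: bool
    limit: float = RMSEP_LIMIT

    def to_dict(self) -> dict:
        return {
            "equation": self.equation.to_dict(),
            "rmsep": self.rmsep,
            "n": self.n,
            "n_components": self.n_components,
            "authorized": self.authorized,
            "limit": self.limit,
        }


def calibrate(
    data: CalibrationDataset,
    n_components: int = 2,
    cv: str = "loo",
    limit: float = RMSEP_LIMIT,
) -> CalibrationReport:
    """Fit, cross-validate and adjudicate in one step.

    ``cv="loo"`` uses the hat-matrix shortcut for the default full-rank fit
    and the explicit refit loop otherwise; ``cv="refit"`` forces the loop.
    """
    eq = fit_pls_pcr(data, n_components=n_components)
    if cv not in ("loo", "refit"):
        raise ValueError(f"unknown cv {cv!r}")
    method = "hat" if (cv == "loo" and n_components == 2) else "refit"
    rmsep = press_loo_rmsep(data, n_components=n_components, method=method)
    return CalibrationReport(
        equation=eq,
        rmsep=rmsep,
        n=data.n,
        n_components=n_components,
        authorized=authorize(rmsep, limit),
        limit=limit,
    )
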