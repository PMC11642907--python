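"""Nuisance regression and AR(1) prewhitening of node time courses.

Task fMRI time courses carry physiological and scanner noise.  The standard
remedy is twofold: residualize each node series on nuisance regressors
(white-matter and ventricle components, head-motion components) within a GLM
that also removes mean and linear trend, and remove residual lag-1 serial
dependence with an AR(1) filter before correlating two series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ar1Estimate",
    "nuisance_regress",
    "estimate_residual_ar1",
    "prewhiten",
    "prewhiten_pair",
]

_RHO_CLIP = 0.999


@dataclass(frozen=True)
class Ar1Estimate:
    """Lag-1 autocorrelation of a regression residual series."""

    rho: float
    n_used: int

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.n_used < 3:
            raise ValueError(f"need >= 3 residual pairs, got {self.n_used}")


def _design_matrix(n_time: int, nuisance: np.ndarray | None) -> np.ndarray:
    trend = np.linspace(-1.0, 1.0, n_time)
    cols = [np.ones(n_time), trend]
    if nuisance is not None and nuisance.size:
        cols.extend(np.asarray(nuisance, dtype=float))
    return np.column_stack(cols)


def nuisance_regress(tc: np.ndarray, nuisance: np.ndarray | None = None) -> np.ndarray:
    """Least-squares residual of a time course on nuisance regressors.

    The design always contains an intercept and a linear trend; rows of
    ``nuisance`` (regressor x time) are appended.  The residual is orthogonal
    to every design column.

    Raises
    ------
    ValueError
        If the design is rank deficient; the message names the collinear
        columns.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1:
        raise ValueError("tc must be a 1-D series")
    X = _design_matrix(tc.size, nuisance)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        names = ["intercept", "trend"] + [f"nuisance[{i}]" for i in range(X.shape[1] - 2)]
        raise ValueError(
            "rank-deficient nuisance design; collinear columns: "
            + ", ".join(names[j] for j in bad)
        )
    beta, *_ = np.linalg.lstsq(X, tc, rcond=None)
    return tc - X @ beta


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns that do not increase the design rank."""
    bad: list[int] = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        trial = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept, rank = trial, r
        else:
            bad.append(j)
    return bad


def _lag1_autocorr(e: np.ndarray) -> float:
    e = e - e.mean()
    denom = e @ e
    if denom == 0:
        raise ValueError("constant residual series")
    return float((e[:-1] @ e[1:]) / denom)


def _residual_lag1(y: np.ndarray, x: np.ndarray) -> float:
    """Lag-1 autocorrelation of the residual of the simple regression y ~ x."""
    x0 = x - x.mean()
    sxx = x0 @ x0
    if sxx == 0:
        raise ValueError("constant input series")
    beta = (x0 @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - beta * x0
    return _lag1_autocorr(resid)


def estimate_residual_ar1(x: np.ndarray, y: np.ndarray) -> Ar1Estimate:
    """AR(1) coefficient of the residuals when two series are regressed on
    each other.

    The regression direction is ambiguous for a correlational analysis, so the
    lag-1 residual autocorrelation is computed in both directions (y on x and
    x on y) and averaged, yielding one common prewhitening weight per pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 10:
        raise ValueError(f"series too short (n={x.size} < 10)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input series")
    rho = 0.5 * (_residual_lag1(y, x) + _residual_lag1(x, y))
    rho = float(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))
    return Ar1Estimate(rho=rho, n_used=x.size - 1)


def prewhiten(tc: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) filter: subtract the rho-weighted lagged series.

    out[t] = tc[t+1] - rho * tc[t]; the first sample is dropped, so the output
    has length n - 1.  rho = 0 returns the series unchanged apart from the
    dropped sample.
    """
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    tc = np.asarray(tc, dtype=float)
    return tc[1:] - rho * tc[:-1]


def prewhiten_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Estimate the pair's common AR(1) weight and prewhiten both series."""
    est = estimate_residual_ar1(x, y)
    return prewhiten(x, est.rho), prewhiten(y, est.rho), est.rho
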