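"""Stationary block bootstrap with automatic block-length selection.

Confidence intervals for correlations between autocorrelated time series are
biased when the serial dependence is ignored.  The stationary bootstrap
(Politis & Romano 1994) resamples blocks whose starting points are uniform
and whose lengths are geometric with mean ``b``; the expected block length is
chosen automatically from the data by flat-top lag-window spectral estimation
(Politis & White 2004, with the finite-sample correction of Patton, Politis &
White 2009).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BootstrapPlan",
    "CorrelationCI",
    "optimal_block_length",
    "joint_block_length",
    "stationary_bootstrap_indices",
    "bootstrap_correlation_ci",
]


@dataclass(frozen=True)
class BootstrapPlan:
    """Resampling parameters for one bootstrap run.

    Parameters
    ----------
    b
        Expected block length in time points (>= 1).  ``None`` means: select
        automatically from the data via :func:`joint_block_length`.
    n_boot
        Number of bootstrap replicates.
    seed
        Seed for the replicate RNG.
    """

    b: float | None = None
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b is not None and self.b < 1:
            raise ValueError(f"expected block length b must be >= 1, got {self.b}")
        if self.n_boot < 100:
            raise ValueError(f"n_boot must be >= 100, got {self.n_boot}")


@dataclass(frozen=True)
class CorrelationCI:
    """Point correlation with percentile bootstrap bounds."""

    r: float
    lo: float
    hi: float
    #: True when the point estimate fell outside [lo, hi] (pathological
    #: resamples; possible for strongly skewed replicate distributions).
    point_outside: bool = False

    def __post_init__(self) -> None:
        if not (self.lo <= self.hi):
            raise ValueError(f"lo={self.lo} exceeds hi={self.hi}")


def _flat_top_window(t: np.ndarray) -> np.ndarray:
    """Trapezoidal flat-top lag window lambda(t)."""
    at = np.abs(t)
    w = np.where(at <= 0.5, 1.0, 2.0 * (1.0 - at))
    return np.where(at <= 1.0, w, 0.0)


def optimal_block_length(x: np.ndarray) -> float:
    """Automatic expected block length for the stationary bootstrap.

    Implements the flat-top lag-window selection rule: the empirical
    autocorrelation function is scanned for the first lag ``m`` after which a
    run of K_n autocorrelations is insignificant at the 2*sqrt(log10(n)/n)
    band; lags up to M = 2m enter flat-top-weighted estimates of the spectral
    quantities G and D_SB, and

        b = (2 G^2 / D_SB)^(1/3) * n^(1/3),

    floored at 1 and capped at n/3 (never beyond the 3*sqrt(n) finite-sample
    cap).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("optimal_block_length expects a 1-D series")
    n = x.size
    if n < 20:
        raise ValueError(f"series too short for block-length selection (n={n} < 20)")
    if np.ptp(x) == 0:
        raise ValueError("constant series: block length undefined")

    eps = x - x.mean()
    k_n = max(5, int(np.ceil(np.sqrt(np.log10(n)))))
    m_max = int(np.ceil(np.sqrt(n))) + k_n
    m_max = min(m_max, n - 1)
    b_max = min(3.0 * np.sqrt(n), n / 3.0)

    # autocovariances R(k), k = 0..m_max (biased 1/n normalization)
    acov = np.array([eps[k:] @ eps[: n - k] / n for k in range(m_max + 1)])
    if acov[0] <= 0:
        raise ValueError("zero-variance series")
    acorr = acov / acov[0]

    band = 2.0 * np.sqrt(np.log10(n) / n)
    insig = np.abs(acorr[1:]) < band  # index k-1 <-> lag k
    m_hat = None
    for m in range(0, m_max - k_n + 1):
        if insig[m : m + k_n].all():
            m_hat = max(m, 1)
            break
    if m_hat is None:
        # no insignificant run found: fall back to the largest significant lag
        sig = np.nonzero(~insig)[0]
        m_hat = int(sig[-1]) + 1 if sig.size else 1

    big_m = min(2 * m_hat, m_max)
    k = np.arange(-big_m, big_m + 1)
    lam = _flat_top_window(k / big_m) if big_m > 0 else np.ones_like(k, dtype=float)
    r_k = acov[np.abs(k)]
    g_hat = float(np.sum(lam * np.abs(k) * r_k))
    spec0 = float(np.sum(lam * r_k))  # 2*pi*f(0)
    d_sb = 2.0 * spec0**2
    if d_sb <= 0:
        return 1.0
    b = (2.0 * g_hat**2 / d_sb) ** (1.0 / 3.0) * n ** (1.0 / 3.0)
    return float(np.clip(b, 1.0, b_max))


def joint_block_length(series: Sequence[np.ndarray]) -> float:
    """Common expected block length for jointly resampled series.

    Each series gets its own automatic block length and the largest one is
    used for all of them, so no series is resampled with blocks shorter than
    its own dependence requires.
    """
    series = [np.asarray(s, dtype=float) for s in series]
    if len(series) < 2:
        raise ValueError("joint_block_length needs at least two series")
    n = series[0].size
    if any(s.size != n for s in series):
        raise ValueError("all series must have equal length")
    return max(optimal_block_length(s) for s in series)


def stationary_bootstrap_indices(
    n: int, plan: BootstrapPlan, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One stationary-bootstrap index vector of length ``n``.

    Blocks start at uniform random positions; block lengths are geometric
    with mean ``plan.b``; indices wrap circularly at the series end.  With
    b = 1 the draw degenerates to i.i.d. uniform resampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if plan.b is None:
        raise ValueError("plan.b must be set (use joint_block_length first)")
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    return _index_matrix(n, plan.b, 1, rng)[0]


def _index_matrix(n: int, b: float, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n) stationary-bootstrap index matrix, vectorized over replicates."""
    p = 1.0 / float(b)
    restart = rng.random((n_boot, n)) < p
    restart[:, 0] = True
    starts = rng.integers(0, n, size=(n_boot, n))
    idx = np.empty((n_boot, n), dtype=np.intp)
    idx[:, 0] = starts[:, 0]
    for t in range(1, n):
        cont = (idx[:, t - 1] + 1) % n
        idx[:, t] = np.where(restart[:, t], starts[:, t], cont)
    return idx


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``a`` with the matching row of ``b``."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", a, b)
    den = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_correlation_ci(
    series: Sequence[np.ndarray],
    plan: BootstrapPlan,
    statistic: Callable[..., float] | None = None,
    rng: np.random.Generator | None = None,
) -> CorrelationCI:
    """Percentile bootstrap CI of a correlation-valued statistic.

    Every replicate draws ONE index vector and applies it to all series
    jointly, preserving their temporal alignment; the statistic is then
    evaluated on the resampled tuple.  ``statistic=None`` means Pearson
    correlation of the first two series (vectorized fast path).

    Replicates where the statistic is undefined (zero variance) are dropped;
    more than 1% of them is an error.
    """
    series = [np.asarray(s, dtype=float) for s in series]
    n = series[0].size
    if any(s.size != n for s in series):
        raise ValueError("all series must have equal length")
    b = plan.b if plan.b is not None else joint_block_length(series)
    if rng is None:
        rng = np.random.default_rng(plan.seed)

    if statistic is None:
        point = float(_rowwise_pearson(series[0][None, :], series[1][None, :])[0])
        idx = _index_matrix(n, b, plan.n_boot, rng)
        reps = _rowwise_pearson(series[0][idx], series[1][idx])
    else:
        point = float(statistic(*series))
        reps = np.empty(plan.n_boot)
        for i in range(plan.n_boot):
            idx = _index_matrix(n, b, 1, rng)[0]
            reps[i] = statistic(*(s[idx] for s in series))

    good = reps[np.isfinite(reps)]
    n_bad = plan.n_boot - good.size
    if n_bad > 0.01 * plan.n_boot:
        raise ValueError(
            f"{n_bad}/{plan.n_boot} bootstrap replicates degenerate (zero variance)"
        )
    lo, hi = np.percentile(good, [2.5, 97.5])
    return CorrelationCI(
        r=point, lo=float(lo), hi=float(hi), point_outside=not (lo <= point <= hi)
    )
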