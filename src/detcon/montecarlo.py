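"""Monte-Carlo reproducibility experiments over the full pipeline.

Two experiments probe how group reproducibility depends on the study design:
subsampling subjects (sample-size experiment) and drawing random node sets
from a pool in which only some nodes are task driven (random-connectome
experiment).  Both run the per-path NHST + conjunction + Dice machinery at
the Bonferroni point for each of the four connectivity variants (observed,
AR(1)-corrected, detectable, detectable AR(1)-corrected) per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .connectivity import _clip_r, detectable_connectivity, fisher_mean
from .preprocess import prewhiten_pair

__all__ = [
    "CohortMatrices",
    "MonteCarloSummary",
    "compute_matrices",
    "sample_size_experiment",
    "random_connectome_experiment",
]

VARIANTS = ("observed", "ar1", "detectable", "detectable_ar1")


@dataclass
class CohortMatrices:
    """Per-subject node reliabilities and full correlation matrices.

    ``obs``/``obs_ar1`` are [subject, node, node, session] (symmetric, unit
    diagonal); keeping the full matrices lets experiments carve out arbitrary
    node subsets without recomputing time-course correlations.
    """

    rel_raw: np.ndarray
    rel_ar1: np.ndarray
    obs: np.ndarray
    obs_ar1: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.rel_raw.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.rel_raw.shape[1]

    def path_values(self, variant: str, nodes: np.ndarray) -> np.ndarray:
        """[subject, path, session] correlations for the connectome on
        ``nodes`` (lower-triangle path order)."""
        nodes = np.asarray(nodes)
        ii, jj = np.tril_indices(nodes.size, k=-1)
        gi, gj = nodes[ii], nodes[jj]
        if variant == "observed":
            return self.obs[:, gi, gj, :]
        if variant == "ar1":
            return self.obs_ar1[:, gi, gj, :]
        if variant == "detectable":
            obs, rel = self.obs, self.rel_raw
        elif variant == "detectable_ar1":
            obs, rel = self.obs_ar1, self.rel_ar1
        else:
            raise ValueError(f"unknown variant {variant!r}")
        return detectable_connectivity(
            obs[:, gi, gj, :], rel[:, gi, None], rel[:, gj, None]
        )


def compute_matrices(cohort) -> CohortMatrices:
    """Point estimates (no CIs) of reliability and connectivity for every
    node pair, with and without pairwise AR(1) prewhitening."""
    S, N, T = cohort.n_subjects, cohort.n_nodes, cohort.n_time
    rel_raw = np.full((S, N), np.nan)
    rel_ar1 = np.full((S, N), np.nan)
    obs = np.full((S, N, N, 2), np.nan)
    obs_ar1 = np.full((S, N, N, 2), np.nan)
    for s in range(S):
        for n in range(N):
            x = cohort.data[s, n, :, 0]
            y = cohort.data[s, n, :, 1]
            rel_raw[s, n] = np.corrcoef(x, y)[0, 1]
            xw, yw, _ = prewhiten_pair(x, y)
            rel_ar1[s, n] = np.corrcoef(xw, yw)[0, 1]
        for sess in range(2):
            block = cohort.data[s, :, :, sess]
            obs[s, :, :, sess] = np.corrcoef(block)
            m = np.eye(N)
            for i in range(N):
                for j in range(i):
                    xw, yw, _ = prewhiten_pair(block[i], block[j])
                    m[i, j] = m[j, i] = np.corrcoef(xw, yw)[0, 1]
            obs_ar1[s, :, :, sess] = m
    return CohortMatrices(rel_raw=rel_raw, rel_ar1=rel_ar1, obs=obs, obs_ar1=obs_ar1)


@dataclass
class MonteCarloSummary:
    """Per-iteration statistics of one experiment condition with grand
    means, standard deviations and 2.5/97.5 percentiles."""

    condition: str
    stats: dict[str, np.ndarray]
    summary: dict[str, dict[str, float]] = field(default_factory=dict)
    n_iter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {k: _summarize(v) for k, v in self.stats.items()}
        # the grand mean can fall outside the 2.5-97.5 percentile band for
        # discrete statistics with a boundary point mass (e.g. dice == 1 in
        # almost every iteration), so only order and range are enforced
        for name, s in self.summary.items():
            if s["pct_2_5"] > s["pct_97_5"] or s["std"] < 0:
                raise ValueError(f"inconsistent summary for {name}")


def _summarize(v: np.ndarray) -> dict[str, float]:
    v = np.asarray(v, dtype=float)
    good = v[np.isfinite(v)]
    if good.size == 0:
        return {k: float("nan") for k in ("grand_mean", "std", "pct_2_5", "pct_97_5")}
    lo, hi = np.percentile(good, [2.5, 97.5])
    return {
        "grand_mean": float(good.mean()),
        "std": float(good.std(ddof=1)) if good.size > 1 else 0.0,
        "pct_2_5": float(lo),
        "pct_97_5": float(hi),
    }


def _vector_ttest_p(z: np.ndarray) -> np.ndarray:
    """Two-sided one-sample t-test p per column of z [subject, path]."""
    n = z.shape[0]
    m = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    p = np.zeros(z.shape[1])
    ok = sd > 0
    t = np.abs(m[ok]) / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * sps.t.sf(t, df=n - 1)
    p[~ok & (m == 0)] = 1.0
    return p


def _bonferroni_stats(r: np.ndarray, alpha: float) -> tuple[int, float]:
    """Conjunction count and Dice at threshold ``alpha`` for r [subj, path, 2]."""
    z = np.arctanh(_clip_r(np.nan_to_num(r, nan=0.0)))
    sig = [
        _vector_ttest_p(z[:, :, sess]) < alpha for sess in range(2)
    ]
    n_conj = int((sig[0] & sig[1]).sum())
    tot = int(sig[0].sum() + sig[1].sum())
    dice = 2.0 * n_conj / tot if tot else float("nan")
    return n_conj, dice


def _iteration_stats(
    mats: CohortMatrices, subj: np.ndarray, nodes: np.ndarray, alpha: float
) -> dict[str, float]:
    out: dict[str, float] = {}
    for variant in VARIANTS:
        r = mats.path_values(variant, nodes)[subj]
        n_conj, dice = _bonferroni_stats(r, alpha)
        out[f"n_conj_{variant}"] = n_conj
        out[f"dice_{variant}"] = dice
        out[f"mean_r_{variant}"] = fisher_mean(r)
    rel = np.maximum(mats.rel_raw[np.ix_(subj, nodes)], 0.0)  # negatives -> 0
    out["mean_reliability"] = fisher_mean(rel)
    return out


def sample_size_experiment(
    cohort,
    n_range,
    n_iter: int = 200,
    seed: int = 0,
    matrices: CohortMatrices | None = None,
) -> dict[int, MonteCarloSummary]:
    """Subject-subsampling experiment.

    For each sample size n, draw ``n_iter`` subject samples *with
    replacement* (size-n "subsamples" from an n-subject cohort only vary
    under replacement), recompute per-variant NHST conjunction counts and
    Dice at the Bonferroni point, plus mean connectivity and mean reliability
    (negative reliabilities set to zero), and summarize across iterations.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    mats = matrices if matrices is not None else compute_matrices(cohort)
    S = mats.n_subjects
    n_range = list(n_range)
    if any(n < 3 or n > S for n in n_range):
        raise ValueError(f"sample sizes must lie in [3, {S}]")
    nodes = np.arange(mats.n_nodes)
    n_paths = nodes.size * (nodes.size - 1) // 2
    alpha = 0.05 / n_paths
    rng = np.random.default_rng(seed)
    results: dict[int, MonteCarloSummary] = {}
    for n in n_range:
        rows: dict[str, list[float]] = {}
        for _ in range(n_iter):
            subj = rng.integers(0, S, n)
            st = _iteration_stats(mats, subj, nodes, alpha)
            for k, v in st.items():
                rows.setdefault(k, []).append(v)
        results[n] = MonteCarloSummary(
            condition=f"sample_size_{n}",
            stats={k: np.asarray(v) for k, v in rows.items()},
            n_iter=n_iter,
            seed=seed,
        )
    return results


def random_connectome_experiment(
    cohort,
    n_nodes: int,
    n_iter: int = 200,
    seed: int = 0,
    matrices: CohortMatrices | None = None,
) -> MonteCarloSummary:
    """Random-connectome experiment.

    Per iteration, sample ``n_nodes`` distinct nodes uniformly from the
    cohort's node pool, build the lower-triangle connectome, and compute the
    Bonferroni-point conjunction count, Dice and mean connectivity per
    variant over all subjects; summaries carry 2.5/97.5 percentiles against
    which a hypothesis-driven connectome can be compared.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    mats = matrices if matrices is not None else compute_matrices(cohort)
    pool = mats.n_nodes
    if pool < n_nodes:
        raise ValueError(f"node pool ({pool}) smaller than connectome size ({n_nodes})")
    n_paths = n_nodes * (n_nodes - 1) // 2
    alpha = 0.05 / n_paths
    rng = np.random.default_rng(seed)
    subj = np.arange(mats.n_subjects)
    rows: dict[str, list[float]] = {}
    for _ in range(n_iter):
        nodes = rng.choice(pool, size=n_nodes, replace=False)
        st = _iteration_stats(mats, subj, nodes, alpha)
        for k, v in st.items():
            rows.setdefault(k, []).append(v)
    return MonteCarloSummary(
        condition="random_connectome",
        stats={k: np.asarray(v) for k, v in rows.items()},
        n_iter=n_iter,
        seed=seed,
    )
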