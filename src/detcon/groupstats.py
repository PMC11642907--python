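"""Group-level NHST, conjunction, Dice reproducibility and effect-size maps.

Each path's subject correlations (Fisher z transformed, forward only) are
tested against zero with a one-sample t test per session.  A path is called
reproducible under *conjunction* when it is significant in both sessions —
equivalently when the larger of its two p values (the smaller t) passes the
threshold.  Agreement of the two thresholded maps is summarized by the Dice
coefficient over an exponential grid of thresholds p = 0.05^(0.1 n),
n = 1..250, with the Bonferroni point 0.05/n_paths marked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .connectivity import (
    ConnectivityTensor,
    ReliabilityTable,
    _clip_r,
    fisher_mean,
)

__all__ = [
    "SessionStats",
    "PathGroupStats",
    "ThresholdCurve",
    "path_ttest",
    "conjunction",
    "dice_overlap",
    "threshold_grid",
    "threshold_curve",
    "effect_size_maps",
    "behavioral_reliability_analysis",
]

GRID_N = 250


@dataclass
class SessionStats:
    """Per-path one-sample t statistics for one session."""

    t: np.ndarray
    p: np.ndarray
    mean_r: np.ndarray
    session: int
    n_subjects: int


@dataclass
class PathGroupStats:
    """Two sessions of per-path NHST plus their conjunction.

    conj_t is the smaller t of the two sessions, conj_p the larger p; a path
    survives conjunction at threshold alpha iff conj_p < alpha, i.e. iff it
    is significant in both sessions.
    """

    t: np.ndarray  # [path, session]
    p: np.ndarray
    mean_r: np.ndarray
    conj_t: np.ndarray  # [path]
    conj_p: np.ndarray
    n_subjects: int
    path_index: list[tuple[int, int]] | None = None


@dataclass
class ThresholdCurve:
    """Conjunction counts and Dice overlap along the exponential p grid."""

    grid: np.ndarray
    n_conj: np.ndarray
    n_test: np.ndarray
    n_retest: np.ndarray
    dice: np.ndarray
    bonferroni_p: float
    bonferroni_n_conj: int
    bonferroni_dice: float


def path_ttest(tensor: ConnectivityTensor) -> SessionStats:
    """Two-sided one-sample t test of each path's Fisher-z subject
    correlations against zero (df = n_subjects - 1).

    Zero cross-subject variance yields signed-infinity t with p = 0;
    undefined entries (NaN) are excluded per path.
    """
    r = tensor.r
    if r.shape[0] < 3:
        raise ValueError("need at least 3 subjects for NHST")
    z = np.arctanh(_clip_r(r))
    n = np.isfinite(z).sum(axis=0)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(z, axis=0)
        sd = np.nanstd(z, axis=0, ddof=1)
    t = np.full(r.shape[1], np.nan)
    p = np.full(r.shape[1], np.nan)
    ok = n >= 3
    # identical values give sd ~ eps, not exactly 0: compare to the mean scale
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(m))
    zero_sd = ok & degenerate
    reg = ok & ~degenerate
    t[reg] = m[reg] / (sd[reg] / np.sqrt(n[reg]))
    p[reg] = 2.0 * sps.t.sf(np.abs(t[reg]), df=n[reg] - 1)
    # degenerate cross-subject variance: exactly zero everywhere is a true
    # null (t=0, p=1); a nonzero constant is infinitely significant
    null = zero_sd & (m == 0)
    t[null], p[null] = 0.0, 1.0
    inf = zero_sd & (m != 0)
    t[inf] = np.sign(m[inf]) * np.inf
    p[inf] = 0.0
    mean_r = fisher_mean(r, axis=0)
    return SessionStats(
        t=t, p=p, mean_r=np.asarray(mean_r), session=tensor.session,
        n_subjects=r.shape[0],
    )


def conjunction(stats_test: SessionStats, stats_retest: SessionStats) -> PathGroupStats:
    """Combine two sessions: smaller t and larger p per path."""
    if stats_test.t.shape != stats_retest.t.shape:
        raise ValueError("mismatched path sets between sessions")
    t = np.column_stack([stats_test.t, stats_retest.t])
    p = np.column_stack([stats_test.p, stats_retest.p])
    mean_r = np.column_stack([stats_test.mean_r, stats_retest.mean_r])
    return PathGroupStats(
        t=t,
        p=p,
        mean_r=mean_r,
        conj_t=np.min(t, axis=1),
        conj_p=np.max(p, axis=1),
        n_subjects=stats_test.n_subjects,
    )


def dice_overlap(set_test, set_retest) -> float:
    """Dice = 2 |A ∩ B| / (|A| + |B|); NaN when both sets are empty."""
    a, b = set(set_test), set(set_retest)
    if not a and not b:
        return float("nan")
    return 2.0 * len(a & b) / (len(a) + len(b))


def threshold_grid(n: int = GRID_N) -> np.ndarray:
    """Exponential p-threshold grid 0.05^(0.1 k), k = 1..n (0.74 .. 3e-33)."""
    k = np.arange(1, n + 1)
    return 0.05 ** (0.1 * k)


def threshold_curve(stats: PathGroupStats, n_paths_bonf: int | None = None) -> ThresholdCurve:
    """Sweep the exponential threshold grid.

    At each threshold the per-session significant sets are {path: p < thr};
    n_conj is the size of their intersection and Dice follows the two-set
    formula.  The Bonferroni point 0.05/n_paths is evaluated as well.
    """
    grid = threshold_grid()
    p_test, p_retest = stats.p[:, 0], stats.p[:, 1]
    n_paths = stats.p.shape[0]
    n_conj = np.empty(grid.size, dtype=int)
    n_t = np.empty(grid.size, dtype=int)
    n_rt = np.empty(grid.size, dtype=int)
    dice = np.empty(grid.size)
    for k, thr in enumerate(grid):
        a = p_test < thr
        b = p_retest < thr
        n_t[k], n_rt[k] = int(a.sum()), int(b.sum())
        n_conj[k] = int((a & b).sum())
        tot = n_t[k] + n_rt[k]
        dice[k] = 2.0 * n_conj[k] / tot if tot else np.nan
    bonf = 0.05 / (n_paths_bonf if n_paths_bonf is not None else n_paths)
    a = p_test < bonf
    b = p_retest < bonf
    nb = int((a & b).sum())
    tot = int(a.sum() + b.sum())
    return ThresholdCurve(
        grid=grid,
        n_conj=n_conj,
        n_test=n_t,
        n_retest=n_rt,
        dice=dice,
        bonferroni_p=bonf,
        bonferroni_n_conj=nb,
        bonferroni_dice=2.0 * nb / tot if tot else float("nan"),
    )


def effect_size_maps(
    conv_test: ConnectivityTensor,
    conv_retest: ConnectivityTensor,
    det_test: ConnectivityTensor,
    det_retest: ConnectivityTensor,
    thresholds: tuple[float, ...] = (0.3, 0.5),
    sweep_step: float = 0.01,
    sweep_max: float = 0.5,
    top_fraction: float = 0.05,
) -> dict:
    """Effect-size thresholded maps and their best detectable-map match.

    Conventional maps threshold the path-wise Fisher-z group mean at
    |mean r| > threshold per session.  Detectable maps are conjuncted first
    (the session with the smaller |mean r| wins per path); the detectable
    threshold maximizing the Dice overlap with each conventional map is found
    by sweeping [0, sweep_max] and averaging the test and retest Dice curves.
    Also returns the top-``top_fraction`` conjuncted maps by |r| (ties broken
    by path index).
    """
    conv_mean = {
        0: np.asarray(fisher_mean(conv_test.r, axis=0)),
        1: np.asarray(fisher_mean(conv_retest.r, axis=0)),
    }
    det_mean = {
        0: np.asarray(fisher_mean(det_test.r, axis=0)),
        1: np.asarray(fisher_mean(det_retest.r, axis=0)),
    }
    det_conj = np.where(
        np.abs(det_mean[0]) <= np.abs(det_mean[1]), det_mean[0], det_mean[1]
    )
    conv_conj = np.where(
        np.abs(conv_mean[0]) <= np.abs(conv_mean[1]), conv_mean[0], conv_mean[1]
    )

    sweep = np.arange(0.0, sweep_max + sweep_step / 2, sweep_step)
    out: dict = {"conventional_maps": {}, "best_match": {}, "sweep_thresholds": sweep}
    for thr in thresholds:
        maps = {
            sess: set(np.nonzero(np.abs(conv_mean[sess]) > thr)[0]) for sess in (0, 1)
        }
        out["conventional_maps"][thr] = maps
        dice_curves = np.empty((2, sweep.size))
        for sess in (0, 1):
            for k, dthr in enumerate(sweep):
                det_set = set(np.nonzero(np.abs(det_conj) > dthr)[0])
                dice_curves[sess, k] = dice_overlap(det_set, maps[sess])
        # both sessions can yield empty maps at strict thresholds: the
        # averaged Dice is then undefined there, not zero
        empty = np.all(np.isnan(dice_curves), axis=0)
        avg = np.full(sweep.size, np.nan)
        if not empty.all():
            avg[~empty] = np.nanmean(dice_curves[:, ~empty], axis=0)
        if np.all(np.isnan(avg)):
            out["best_match"][thr] = {"threshold": float("nan"), "dice": float("nan")}
        else:
            k = int(np.nanargmax(avg))
            out["best_match"][thr] = {
                "threshold": float(sweep[k]),
                "dice": float(avg[k]),
                "dice_curve": avg,
            }

    n_top = max(1, int(top_fraction * det_conj.size))
    for name, conj in (("detectable", det_conj), ("conventional", conv_conj)):
        order = np.lexsort((np.arange(conj.size), -np.abs(conj)))
        out[f"top_{name}_paths"] = set(order[:n_top].tolist())
    return out


def behavioral_reliability_analysis(
    cohort, reliability: ReliabilityTable
) -> dict:
    """Response-time reliability and its coupling to time-course reliability.

    Returns the group-curve reliability (correlation of the session-mean
    48-item RT curves), each subject's test-retest RT correlation, and the
    coupling: Pearson r between the Fisher-z subject RT reliabilities and the
    Fisher-z subject-mean time-course reliabilities, negative reliabilities
    set to zero before transforming.
    """
    rts = cohort.response_times
    if rts is None or rts.size == 0:
        raise ValueError("cohort has no response times")
    group_curves = rts.mean(axis=0)  # [item, session]
    group_curve_r = float(np.corrcoef(group_curves[:, 0], group_curves[:, 1])[0, 1])

    S = rts.shape[0]
    subject_rt_r = np.array(
        [float(np.corrcoef(rts[s, :, 0], rts[s, :, 1])[0, 1]) for s in range(S)]
    )
    with np.errstate(invalid="ignore"):
        tc_rel = np.nanmean(reliability.rho, axis=1)
    z_rt = np.arctanh(_clip_r(np.maximum(subject_rt_r, 0.0)))
    z_tc = np.arctanh(_clip_r(np.maximum(tc_rel, 0.0)))
    coupling_r = float(np.corrcoef(z_rt, z_tc)[0, 1])
    return {
        "group_curve_r": group_curve_r,
        "subject_rt_r": subject_rt_r,
        "coupling_r": coupling_r,
    }
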