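"""Delimited-text cohort I/O and the end-to-end pipeline driver.

Cohorts live as one TSV per subject per session (rows = time points, columns
= nodes) next to analogous nuisance and response-time files and a JSON
sidecar holding the generating config and seed.  Plain text is deliberate:
the analysis consumes extracted node time courses, not images.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import groupstats as gs
from .blockboot import BootstrapPlan
from .montecarlo import compute_matrices, sample_size_experiment
from .preprocess import nuisance_regress
from .synthetic import CohortConfig, CohortTimeCourses

__all__ = ["RunConfig", "write_cohort", "read_cohort", "run_pipeline"]

log = logging.getLogger("detcon")

SESSIONS = ("test", "retest")


def _tc_name(s: int, sess: str) -> str:
    return f"sub-{s + 1:02d}_ses-{sess}_timecourses.tsv"


def _nuis_name(s: int, sess: str) -> str:
    return f"sub-{s + 1:02d}_ses-{sess}_nuisance.tsv"


def write_cohort(cohort: CohortTimeCourses, out_dir: str | Path) -> Path:
    """Write a cohort as per-subject TSV matrices plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    S, N, T = cohort.n_subjects, cohort.n_nodes, cohort.n_time
    node_cols = [f"node_{n + 1}" for n in range(N)]
    nuis_cols = [f"nuisance_{k + 1}" for k in range(cohort.nuisance.shape[1])]
    for s in range(S):
        for si, sess in enumerate(SESSIONS):
            pd.DataFrame(cohort.data[s, :, :, si].T, columns=node_cols).to_csv(
                out / _tc_name(s, sess), sep="\t", index=False, float_format="%.17g"
            )
            pd.DataFrame(cohort.nuisance[s, :, :, si].T, columns=nuis_cols).to_csv(
                out / _nuis_name(s, sess), sep="\t", index=False, float_format="%.17g"
            )
    rt = pd.DataFrame(
        {
            "item": np.arange(1, cohort.response_times.shape[1] + 1),
            **{
                f"sub-{s + 1:02d}_{sess}": cohort.response_times[s, :, si]
                for s in range(S)
                for si, sess in enumerate(SESSIONS)
            },
        }
    )
    rt.to_csv(out / "response_times.tsv", sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "config": dataclasses.asdict(cohort.config),
        "seed": cohort.config.seed,
        "shape": [S, N, T, 2],
    }
    if sidecar["config"].get("node_amplitude_profile") is not None:
        sidecar["config"]["node_amplitude_profile"] = list(
            map(float, sidecar["config"]["node_amplitude_profile"])
        )
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return out


def _read_matrix(path: Path, n_rows: int | None, what: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(arr))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{what}: missing/non-numeric value in {path.name} at row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    if n_rows is not None and arr.shape[0] != n_rows:
        raise ValueError(
            f"{what}: {path.name} has {arr.shape[0]} time points, expected {n_rows}"
        )
    return arr


def read_cohort(in_dir: str | Path) -> CohortTimeCourses:
    """Assemble a cohort from a directory written by :func:`write_cohort`."""
    d = Path(in_dir)
    sidecar = json.loads((d / "cohort.json").read_text())
    cfg = CohortConfig(**sidecar["config"])
    S, N, T, _ = sidecar["shape"]
    log.info("reading cohort from %s (seed=%s)", d, sidecar["seed"])
    data = np.empty((S, N, T, 2))
    nuisance = np.empty((S, cfg.n_nuisance, T, 2))
    for s in range(S):
        for si, sess in enumerate(SESSIONS):
            p = d / _tc_name(s, sess)
            if not p.exists():
                raise FileNotFoundError(f"missing session file {p.name}")
            arr = _read_matrix(p, T, f"subject {s + 1} {sess}")
            if arr.shape[1] != N:
                raise ValueError(
                    f"subject {s + 1} {sess}: {arr.shape[1]} nodes, expected {N}"
                )
            data[s, :, :, si] = arr.T
            nuisance[s, :, :, si] = _read_matrix(
                d / _nuis_name(s, sess), T, f"subject {s + 1} {sess} nuisance"
            ).T
    rt = pd.read_csv(d / "response_times.tsv", sep="\t", float_precision="round_trip")
    n_items = rt.shape[0]
    rts = np.empty((S, n_items, 2))
    for s in range(S):
        for si, sess in enumerate(SESSIONS):
            rts[s, :, si] = rt[f"sub-{s + 1:02d}_{sess}"].to_numpy(dtype=float)
    return CohortTimeCourses(
        data=data, config=cfg, nuisance=nuisance, response_times=rts
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    in_dir: str | Path | None = None  # None: simulate with `cohort_config`
    cohort_config: CohortConfig | None = None
    out_dir: str | Path = "detcon_out"
    nuisance_regression: bool = True
    with_cis: bool = True
    n_boot: int = 500
    seed: int = 0
    montecarlo: bool = False
    mc_n_range: tuple[int, ...] = (10, 25, 50)
    mc_n_iter: int = 200


def _denoise(cohort: CohortTimeCourses) -> CohortTimeCourses:
    """Residualize every node series on that subject/session's nuisance set."""
    data = np.empty_like(cohort.data)
    for s in range(cohort.n_subjects):
        for sess in range(2):
            nuis = cohort.nuisance[s, :, :, sess]
            for n in range(cohort.n_nodes):
                data[s, n, :, sess] = nuisance_regress(
                    cohort.data[s, n, :, sess], nuis
                )
    return CohortTimeCourses(
        data=data,
        config=cohort.config,
        nuisance=cohort.nuisance,
        response_times=cohort.response_times,
        subject_gains=cohort.subject_gains,
    )


def _summary_row(summ: conn.DistributionSummary) -> dict:
    return {
        "mean_connectivity": round(summ.mean_r, 6),
        "lower_bound_connectivity": round(summ.mean_lo, 6),
        "upper_bound_connectivity": round(summ.mean_hi, 6),
        "pct_2_5": round(summ.pct_2_5, 6),
        "pct_97_5": round(summ.pct_97_5, 6),
        "std": round(summ.std, 6),
        "pct_negative": round(summ.pct_negative, 6),
        "n_undefined": summ.n_undefined,
    }


def _edge_table(tensors: dict) -> pd.DataFrame:
    rows = []
    for (variant, sess), t in tensors.items():
        S = t.r.shape[0]
        for s in range(S):
            for p, (i, j) in enumerate(t.path_index):
                rows.append(
                    {
                        "node_i": i + 1,
                        "node_j": j + 1,
                        "subject": s + 1,
                        "session": SESSIONS[sess],
                        "variant": variant,
                        "r": t.r[s, p],
                        "lo": t.lo[s, p],
                        "hi": t.hi[s, p],
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """preprocess -> reliability -> connectivity (4 variants) -> group stats
    -> optional Monte Carlo; writes TSV/JSON outputs and returns the bundle.

    Every stage failure is re-raised with the stage name; the summary JSON is
    a pure function of (inputs, config) and records the config hash + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.in_dir is not None:
            cohort = read_cohort(config.in_dir)
        else:
            from .synthetic import generate_cohort

            cfg = config.cohort_config or CohortConfig(seed=config.seed)
            cohort = generate_cohort(cfg)

        stage = "preprocess"
        if config.nuisance_regression:
            cohort = _denoise(cohort)

        plan = (
            BootstrapPlan(n_boot=config.n_boot, seed=config.seed)
            if config.with_cis
            else None
        )
        stage = "reliability"
        rel = {
            "raw": conn.within_subject_reliability(cohort, ar1=False, plan=plan),
            "ar1": conn.within_subject_reliability(cohort, ar1=True, plan=plan),
        }
        for k, t in rel.items():
            log.info(
                "reliability (%s): %.1f%% of time courses negative",
                k,
                100 * t.negative_fraction(),
            )

        stage = "connectivity"
        tensors: dict = {}
        for sess in (conn.TEST, conn.RETEST):
            tensors[("observed", sess)] = conn.observed_connectivity(
                cohort, sess, ar1=False, plan=plan
            )
            tensors[("ar1", sess)] = conn.observed_connectivity(
                cohort, sess, ar1=True, plan=plan
            )
            tensors[("detectable", sess)] = conn.detectable_connectivity_tensor(
                cohort, sess, ar1=False, plan=plan
            )
            tensors[("detectable_ar1", sess)] = conn.detectable_connectivity_tensor(
                cohort, sess, ar1=True, plan=plan
            )

        stage = "summaries"
        table1 = {
            f"{variant}_{SESSIONS[sess]}": _summary_row(
                conn.absolute_mean_with_ci(t, seed=config.seed)
            )
            for (variant, sess), t in tensors.items()
        }
        group_rel_paths, group_rel_mean = conn.conventional_group_reliability(
            tensors[("observed", 0)], tensors[("observed", 1)]
        )

        stage = "groupstats"
        pathstats = {}
        curves = {}
        for variant in ("observed", "ar1", "detectable", "detectable_ar1"):
            st = gs.conjunction(
                gs.path_ttest(tensors[(variant, 0)]),
                gs.path_ttest(tensors[(variant, 1)]),
            )
            pathstats[variant] = st
            curves[variant] = gs.threshold_curve(st)
        maps = gs.effect_size_maps(
            tensors[("ar1", 0)],
            tensors[("ar1", 1)],
            tensors[("detectable_ar1", 0)],
            tensors[("detectable_ar1", 1)],
        )
        behavior = gs.behavioral_reliability_analysis(cohort, rel["raw"])

        mc = None
        if config.montecarlo:
            stage = "montecarlo"
            mats = compute_matrices(cohort)
            mc = {
                "sample_size": sample_size_experiment(
                    cohort,
                    [n for n in config.mc_n_range if n <= cohort.n_subjects],
                    n_iter=config.mc_n_iter,
                    seed=config.seed,
                    matrices=mats,
                ),
            }

        stage = "write"
        _edge_table(tensors).to_csv(
            out / "connectivity_edges.tsv", sep="\t", index=False, float_format="%.6g"
        )
        for variant, cv in curves.items():
            pd.DataFrame(
                {
                    "n": np.arange(1, cv.grid.size + 1),
                    "p": cv.grid,
                    "n_conj": cv.n_conj,
                    "dice": cv.dice,
                }
            ).to_csv(
                out / f"threshold_curve_{variant}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
        cfg_hash = hashlib.sha256(
            json.dumps(dataclasses.asdict(cohort.config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        summary = {
            "seed": config.seed,
            "config_hash": cfg_hash,
            "n_boot": config.n_boot,
            "table1": table1,
            "grand_mean_reliability": {
                k: round(float(conn.fisher_mean(t.rho)), 6) for k, t in rel.items()
            },
            "negative_reliability_fraction": {
                k: round(t.negative_fraction(), 6) for k, t in rel.items()
            },
            "conventional_group_reliability_mean": round(float(group_rel_mean), 6),
            "bonferroni": {
                v: {
                    "p": curves[v].bonferroni_p,
                    "n_conj": curves[v].bonferroni_n_conj,
                    "dice": None
                    if np.isnan(curves[v].bonferroni_dice)
                    else round(curves[v].bonferroni_dice, 6),
                }
                for v in curves
            },
            "median_conj_t": {
                v: round(float(np.nanmedian(pathstats[v].conj_t)), 6) for v in pathstats
            },
            "behavior": {
                "group_curve_r": round(behavior["group_curve_r"], 6),
                "coupling_r": round(behavior["coupling_r"], 6),
            },
            "effect_size_best_match": {
                str(thr): {
                    "threshold": maps["best_match"][thr]["threshold"],
                    "dice": maps["best_match"][thr]["dice"],
                }
                for thr in maps["best_match"]
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "cohort": cohort,
        "reliability": rel,
        "tensors": tensors,
        "table1": table1,
        "group_reliability": (group_rel_paths, group_rel_mean),
        "pathstats": pathstats,
        "curves": curves,
        "maps": maps,
        "behavior": behavior,
        "montecarlo": mc,
        "summary": summary,
    }
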