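"""End-to-end orchestration of the empirical and simulation analyses.

The empirical pipeline takes one or more per-trial datasets and
produces, per dataset: per-subject meta-d' fits for the three secondary
variables (confidence, quantile-binned RT, logistic composite), the
exclusion accounting, dataset-level means, cross-subject correlations
with CIs, and — when more than one dataset is supplied — random-effects
meta-analytic pooling. The accuracy-by-RT-bin preparation (20
equal-width bins per subject, confidence levels optionally collapsed
into groups) and the long-format export for external mixed-model
fitting live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_trials import TrialTable
from .metasdt import exclude_subjects
from .reliability_meta import (
    MetaAnalysisResult,
    meta_analyze_r,
    metad_for_variant,
    pearson_ci,
)

logger = logging.getLogger("rtmeta")

VARIANTS = ("confidence", "rt", "composite")


@dataclass
class AnalysisConfig:
    """Defaults follow the analysis conventions used throughout the package."""

    d_range: tuple = (-1.0, 4.0)       # inclusion range for d' and meta-d'
    reliability_threshold: float = 0.45  # Spearman-Brown screen
    rt_cutoff: float = 3000.0          # simulation slow-RT exclusion, ms
    sim_levels: int = 10               # simulation discretization levels
    n_rt_bins: int = 20                # equal-width accuracy bins
    n_bins: int | None = None          # empirical binning (None: dataset K)
    min_trials: int = 20               # per-subject floor for fits
    seed: int = 0
    padding: float | None = None       # None: 1/(2K)


def fit_dataset(table: TrialTable, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-subject meta-d' fits for all three secondary variables.

    Returns one row per subject x variant with d', meta-d', m-ratio,
    convergence, and the exclusion verdict (a subject is excluded as a
    whole if any variant fails to converge or leaves the d' range).
    """
    config = config or AnalysisConfig()
    rows = []
    per_subject_fits: dict = {}
    for subject, sub in table.iter_subjects():
        fits = []
        try:
            for kind in VARIANTS:
                fit = metad_for_variant(sub, kind, n_bins=config.n_bins,
                                        padding=config.padding)
                fits.append((kind, fit))
        except Exception as exc:
            logger.info("fit_dataset: subject %r unfittable (%s)", subject, exc)
            continue
        per_subject_fits[subject] = [f for _, f in fits]
        for kind, fit in fits:
            rows.append(
                {
                    "subject": subject,
                    "variable_kind": kind,
                    "d_prime": fit.d_prime,
                    "c": fit.c,
                    "meta_d": fit.meta_d_prime,
                    "m_ratio": fit.m_ratio,
                    "converged": fit.converged,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    partition = exclude_subjects(per_subject_fits, d_range=config.d_range)
    reasons = dict(partition["excluded"])
    df["excluded"] = df["subject"].map(lambda s: s in reasons)
    df["reason"] = df["subject"].map(lambda s: reasons.get(s, ""))
    logger.info(
        "fit_dataset: %d subjects fit, %d retained, %d excluded",
        len(per_subject_fits), len(partition["retained"]), len(reasons),
    )
    return df


def summarize_dataset(fits: pd.DataFrame) -> dict:
    """Dataset-level means, pairwise correlations and paired contrasts.

    Works on the retained subjects of a ``fit_dataset`` frame. Pairwise
    Pearson correlations (with Fisher-z CIs) are computed between the
    meta-d' indices and d'; meta-d' differences between variants are
    tested with paired two-sided t-tests.
    """
    kept = fits[~fits["excluded"]]
    wide_meta = kept.pivot(index="subject", columns="variable_kind",
                           values="meta_d")
    wide_d = kept.pivot(index="subject", columns="variable_kind",
                        values="d_prime")["confidence"]
    wide_mr = kept.pivot(index="subject", columns="variable_kind",
                         values="m_ratio")
    means = {
        "n_subjects": len(wide_meta),
        "mean_d_prime": float(wide_d.mean()),
        "mean_meta_d_confidence": float(wide_meta["confidence"].mean()),
        "mean_meta_d_rt": float(wide_meta["rt"].mean()),
        "mean_meta_d_composite": float(wide_meta["composite"].mean()),
    }
    out = {"means": means, "correlations": {}, "contrasts": {}}
    if len(wide_meta) >= 4:
        pairs = {
            "meta_conf_vs_meta_rt": (wide_meta["confidence"], wide_meta["rt"]),
            "mratio_conf_vs_mratio_rt": (wide_mr["confidence"], wide_mr["rt"]),
            "d_vs_meta_conf": (wide_d, wide_meta["confidence"]),
            "d_vs_meta_rt": (wide_d, wide_meta["rt"]),
        }
        for name, (x, y) in pairs.items():
            r, ci, p = pearson_ci(x.to_numpy(), y.to_numpy())
            out["correlations"][name] = {"r": r, "ci": ci, "p": p,
                                         "n": len(wide_meta)}
    if len(wide_meta) >= 2:
        for name, (x, y) in {
            "conf_minus_rt": (wide_meta["confidence"], wide_meta["rt"]),
            "comp_minus_conf": (wide_meta["composite"], wide_meta["confidence"]),
        }.items():
            t, p = stats.ttest_rel(x, y)
            out["contrasts"][name] = {"mean_diff": float((x - y).mean()),
                                      "t": float(t), "p": float(p)}
    return out


def run_empirical(tables: dict, config: AnalysisConfig | None = None) -> dict:
    """Full empirical pipeline over named datasets.

    ``tables`` maps dataset label -> TrialTable. Returns per-dataset
    fits and summaries plus, when more than one dataset contributes a
    correlation, the random-effects meta-analysis of the
    meta-d'_confidence x meta-d'_RT correlation (and of the m-ratio
    correlation).
    """
    config = config or AnalysisConfig()
    result: dict = {"datasets": {}}
    study_r: dict = {"meta_conf_vs_meta_rt": [], "mratio_conf_vs_mratio_rt": []}
    study_labels: dict = {k: [] for k in study_r}
    for label, table in tables.items():
        fits = fit_dataset(table, config)
        if fits.empty:
            logger.info("run_empirical: dataset %r produced no fits", label)
            continue
        summary = summarize_dataset(fits)
        result["datasets"][label] = {"fits": fits, "summary": summary}
        for key in study_r:
            corr = summary["correlations"].get(key)
            if corr is not None:
                study_r[key].append((corr["r"], corr["n"]))
                study_labels[key].append(label)
    result["meta_analysis"] = {}
    for key, entries in study_r.items():
        if len(entries) >= 1:
            result["meta_analysis"][key] = meta_analyze_r(
                entries, labels=study_labels[key]
            )
    return result


def accuracy_by_rt_bins(table: TrialTable, n_rt_bins: int = 20,
                        confidence_grouping: dict | None = None) -> pd.DataFrame:
    """Mean accuracy in equal-WIDTH RT bins per subject and confidence group.

    RT bins are 20 equally spaced intervals between each subject's min
    and max RT (not quantiles). ``confidence_grouping`` maps raw
    confidence level -> group label (e.g. {1: 1, 2: 1, 3: 2, ...} to
    collapse six levels into three); by default each level is its own
    group. Empty cells appear with accuracy NaN so downstream smoothing
    sees the full grid.
    """
    frames = []
    for subject, sub in table.iter_subjects():
        rt = sub.data["rt"].to_numpy(float)
        if np.ptp(rt) == 0:
            raise ValueError(f"subject {subject!r} has constant RT; "
                             "equal-width binning is degenerate")
        edges = np.linspace(rt.min(), rt.max(), n_rt_bins + 1)
        rt_bin = np.clip(np.searchsorted(edges, rt, side="right") - 1,
                         0, n_rt_bins - 1) + 1
        conf = sub.data["confidence"].to_numpy(int)
        if confidence_grouping:
            group = np.vectorize(confidence_grouping.get)(conf)
        else:
            group = conf
        df = pd.DataFrame(
            {
                "subject": subject,
                "conf_group": group,
                "rt_bin": rt_bin,
                "correct": sub.data["correct"].to_numpy(float),
            }
        )
        cell = df.groupby(["subject", "conf_group", "rt_bin"], as_index=False)[
            "correct"
        ].agg(accuracy="mean", n_trials="count")
        full = pd.MultiIndex.from_product(
            [[subject], np.unique(group), np.arange(1, n_rt_bins + 1)],
            names=["subject", "conf_group", "rt_bin"],
        ).to_frame(index=False)
        frames.append(full.merge(cell, how="left",
                                 on=["subject", "conf_group", "rt_bin"]))
    out = pd.concat(frames, ignore_index=True)
    out["n_trials"] = out["n_trials"].fillna(0).astype(int)
    return out


def six_to_three_grouping() -> dict:
    """The standard collapse of a 6-level scale: {1,2}->1, {3,4}->2, {5,6}->3."""
    return {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}


def export_glmm_table(tables: dict, path=None) -> pd.DataFrame:
    """One row per trial, ready for external mixed-model fitting.

    Columns: dataset, subject, correct, confidence, rt, conf_x_rt.
    """
    frames = []
    for label, table in tables.items():
        d = table.data
        frames.append(
            pd.DataFrame(
                {
                    "dataset": label,
                    "subject": d["subject"],
                    "correct": d["correct"].astype(int),
                    "confidence": d["confidence"],
                    "rt": d["rt"],
                    "conf_x_rt": d["confidence"].to_numpy(float)
                    * d["rt"].to_numpy(float),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out
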