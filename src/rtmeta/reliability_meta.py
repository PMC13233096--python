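"""Reliability of meta-d' indices and meta-analysis of cross-subject correlations.

Individual meta-d' estimates are noisy, so a raw cross-subject
correlation between two meta-d' indices understates their true
association. This module provides the classical toolkit for that
problem: odd/even split-half estimation, the Spearman-Brown step-up,
attenuation correction r / sqrt(r_xx * r_yy), first-order partial
correlation, and DerSimonian-Laird random-effects pooling of Fisher-z
transformed correlations across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_trials import TrialTable
from .metasdt import MetaSDTFit, fit_meta_d
from .type2 import SecondaryVariable, bin_by_quantiles, confidence_variable, counts_by_cell

logger = logging.getLogger("rtmeta")


# ---------------------------------------------------------------------------
# Secondary-variable -> meta-d' plumbing shared by the pipeline and the
# split-half machinery.
# ---------------------------------------------------------------------------

def metad_for_variant(table: TrialTable, kind: str, n_bins: int | None = None,
                      confidence_values: np.ndarray | None = None,
                      padding: float | None = None) -> MetaSDTFit:
    """Fit meta-d' for one subject's trials under a given secondary variable.

    kind="confidence" uses the ordinal confidence column; kind="rt"
    quantile-bins RT (descending: fast = high) into ``n_bins`` levels
    (default: the table's confidence K); kind="composite" fits the
    per-subject logistic composite and bins its logit ascending.
    """
    if n_bins is None:
        n_bins = table.k_levels
    if kind == "confidence":
        sv = confidence_variable(table)
    elif kind == "rt":
        sv = bin_by_quantiles(table.data["rt"].to_numpy(float), n_bins,
                              orientation="descending", kind="rt")
    elif kind == "composite":
        from .composite import composite_logits, fit_composite

        model = fit_composite(table, confidence_values=confidence_values)
        sv = composite_logits(model, table, n_bins,
                              confidence_values=confidence_values)
    else:
        raise ValueError(f"unknown secondary-variable kind: {kind!r}")
    counts = counts_by_cell(table, sv)
    return fit_meta_d(counts, padding=padding)


# ---------------------------------------------------------------------------
# Split-half reliability
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    r_half: float
    r_sb: float
    passes_screen: bool


def spearman_brown(r_half: float) -> float:
    """Full-length reliability predicted from a split-half correlation."""
    return 2.0 * r_half / (1.0 + r_half)


def split_half_metad(table: TrialTable, sv_kind: str,
                     n_bins: int | None = None, min_trials_half: int = 20,
                     padding: float | None = None) -> dict:
    """Per-subject meta-d' fit separately on odd and on even trials.

    Trials are partitioned by the parity of ``trial_index`` (file/
    simulation order within subject); binning and fitting run
    independently within each half. Subjects whose halves are too small
    or fail to fit are dropped with a log message.

    Returns subject -> (meta_d_odd, meta_d_even).
    """
    out = {}
    for subject, sub in table.iter_subjects():
        halves = []
        ok = True
        for parity in (1, 0):
            mask = (sub.data["trial_index"] % 2) == parity
            if mask.sum() < min_trials_half:
                ok = False
                break
            half = TrialTable(
                sub.data[mask].drop(columns=["trial_index"]).reset_index(drop=True),
                k_levels=sub.k_levels,
            )
            try:
                fit = metad_for_variant(half, sv_kind, n_bins=n_bins,
                                        padding=padding)
            except Exception as exc:  # unfittable half
                logger.info("split-half: subject %r dropped (%s)", subject, exc)
                ok = False
                break
            if not fit.converged:
                logger.info("split-half: subject %r dropped (non-convergent half)",
                            subject)
                ok = False
                break
            halves.append(fit.meta_d_prime)
        if ok:
            out[subject] = (halves[0], halves[1])
    return out


def reliability_from_halves(odd: np.ndarray, even: np.ndarray,
                            threshold: float = 0.45) -> ReliabilityResult:
    """Odd-even correlation across subjects, stepped up by Spearman-Brown."""
    r_half = float(np.corrcoef(odd, even)[0, 1])
    r_sb = spearman_brown(r_half)
    return ReliabilityResult(r_half=r_half, r_sb=r_sb,
                             passes_screen=bool(r_sb > threshold))


# ---------------------------------------------------------------------------
# Correlation corrections
# ---------------------------------------------------------------------------

def disattenuate(r_xy: float, r_xx: float, r_yy: float):
    """Attenuation-corrected correlation r_xy / sqrt(r_xx * r_yy).

    Returns ``(r_corrected, over_corrected)``; the value is clamped to
    [-1, 1] and flagged when the raw ratio leaves that interval.
    """
    if r_xx <= 0 or r_yy <= 0:
        raise ValueError("reliabilities must be positive for disattenuation")
    raw = r_xy / np.sqrt(r_xx * r_yy)
    over = bool(abs(raw) > 1.0)
    return float(np.clip(raw, -1.0, 1.0)), over


def partial_correlation(x, y, z):
    """First-order partial correlation of x and y controlling for z.

    Returns ``(r, (ci_lo, ci_hi), p)``; the CI uses the Fisher-z
    approximation with one control variable (variance 1/(n-4)).
    """
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("a control correlation is degenerate (|r| = 1)")
    r_p = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    se = 1.0 / np.sqrt(n - 4)
    zr = np.arctanh(np.clip(r_p, -1 + 1e-15, 1 - 1e-15))
    lo, hi = np.tanh(zr - 1.959963984540054 * se), np.tanh(zr + 1.959963984540054 * se)
    p = 2.0 * stats.norm.sf(abs(zr) / se)
    return float(r_p), (float(lo), float(hi)), float(p)


def pearson_ci(x, y):
    """Pearson r with Fisher-z 95% CI and two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    r, p = stats.pearsonr(x, y)
    se = 1.0 / np.sqrt(n - 3)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    lo, hi = np.tanh(zr - 1.959963984540054 * se), np.tanh(zr + 1.959963984540054 * se)
    return float(r), (float(lo), float(hi)), float(p)


# ---------------------------------------------------------------------------
# Random-effects meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaAnalysisResult:
    per_study: list          # (label, r, n, (ci_lo, ci_hi))
    pooled_r: float
    pooled_ci: tuple
    tau2: float              # between-study variance on the Fisher-z scale
    p_value: float


def meta_analyze_r(per_study, labels=None) -> MetaAnalysisResult:
    """DerSimonian-Laird random-effects pooling of correlations.

    ``per_study`` is a list of (r, n); each r is Fisher-z transformed
    with sampling variance 1/(n-3), the DL moment estimator gives tau^2,
    and the inverse-variance-weighted pooled z is back-transformed.
    """
    rs = np.array([r for r, _ in per_study], float)
    ns = np.array([n for _, n in per_study], float)
    if np.any(np.abs(rs) >= 1.0):
        raise ValueError("|r| = 1 has infinite Fisher z; cannot pool")
    if np.any(ns < 4):
        raise ValueError("each study needs n >= 4")
    if labels is None:
        labels = [f"study_{i + 1}" for i in range(len(rs))]
    zs = np.arctanh(rs)
    v = 1.0 / (ns - 3.0)
    w = 1.0 / v
    k = len(rs)
    z_fixed = np.sum(w * zs) / np.sum(w)
    if k > 1:
        q = float(np.sum(w * (zs - z_fixed) ** 2))
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    z_pooled = float(np.sum(w_star * zs) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    zcrit = 1.959963984540054
    pooled_r = float(np.tanh(z_pooled))
    pooled_ci = (float(np.tanh(z_pooled - zcrit * se)),
                 float(np.tanh(z_pooled + zcrit * se)))
    p = float(2.0 * stats.norm.sf(abs(z_pooled) / se))
    per = []
    for label, r, n, vi in zip(labels, rs, ns, v):
        sei = np.sqrt(vi)
        zi = np.arctanh(r)
        per.append((label, float(r), int(n),
                    (float(np.tanh(zi - zcrit * sei)),
                     float(np.tanh(zi + zcrit * sei)))))
    return MetaAnalysisResult(per_study=per, pooled_r=pooled_r,
                              pooled_ci=pooled_ci, tau2=tau2, p_value=p)


def export_forest(result: MetaAnalysisResult, path) -> None:
    """Forest-plot-ready CSV: per-study rows plus the pooled row."""
    import pandas as pd

    rows = [
        {"study": label, "r": r, "n": n, "ci_lo": ci[0], "ci_hi": ci[1]}
        for label, r, n, ci in result.per_study
    ]
    rows.append(
        {"study": "pooled (random effects)", "r": result.pooled_r,
         "n": int(sum(s[2] for s in result.per_study)),
         "ci_lo": result.pooled_ci[0], "ci_hi": result.pooled_ci[1]}
    )
    pd.DataFrame(rows).to_csv(path, index=False)
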