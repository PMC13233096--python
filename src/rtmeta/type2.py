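"""Type-2 ROC construction from an ordinal secondary variable.

A *secondary variable* is any per-trial graded quantity — confidence,
quantile-binned RT, or a composite logit — reduced to ordinal levels
1..K with the convention that level K is the "highest" (most confident /
fastest / largest logit). The type-2 ROC plots, across cutoffs, the
proportion of trials labeled "high" among incorrect responses against
that proportion among correct responses; its area quantifies how
diagnostic the variable is of the observer's own accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_trials import TrialTable


@dataclass
class SecondaryVariable:
    """Per-trial ordinal levels 1..K annotating a trial table.

    For ``kind="rt"`` the orientation is fixed so that level K is the
    FASTEST bin (short RT <-> "high"); a fast-error regime then shows up
    honestly as type-2 AUC < 0.5 instead of being silently re-oriented.
    """

    values: np.ndarray  # int levels in 1..K
    kind: str           # "confidence" | "rt" | "composite"
    K: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.values.min() < 1 or self.values.max() > self.K:
            raise ValueError("levels must lie in 1..K")


@dataclass
class Type2Curve:
    """Type-2 ROC: interior (FAR2, HR2) points from stringent to lenient."""

    points: np.ndarray  # shape (K-1, 2): (p_high|incorrect, p_high|correct)
    auc: float


class DegenerateBinningWarning(UserWarning):
    pass


def bin_by_quantiles(values, n_bins: int, orientation: str = "descending",
                     kind: str = "rt") -> SecondaryVariable:
    """Discretize a continuous variable into quantile bins.

    Cutoffs are the i/n_bins empirical quantiles (linear interpolation,
    i.e. R type 7). Ties at a cutoff fall to the lower level
    (left-closed assignment). ``orientation="descending"`` maps the
    SMALLEST values to level ``n_bins`` — the convention for RT, where
    fast responses are "high".

    With fewer distinct values than bins, duplicate cutoffs are merged
    and a :class:`DegenerateBinningWarning` is issued; all-identical
    input yields a single level.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if orientation not in ("ascending", "descending"):
        raise ValueError("orientation must be 'ascending' or 'descending'")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")

    qs = np.arange(1, n_bins) / n_bins
    cutoffs = np.unique(np.quantile(x, qs, method="linear"))
    if len(cutoffs) < n_bins - 1 or np.ptp(x) == 0:
        warnings.warn(
            "fewer distinct values than requested bins; bins merged",
            DegenerateBinningWarning,
            stacklevel=2,
        )
    if np.ptp(x) == 0:
        return SecondaryVariable(np.ones(len(x), int), kind, 1)
    # level = 1 + number of cutoffs strictly below the value
    levels = np.searchsorted(cutoffs, x, side="left") + 1
    # collapse empty levels so levels are contiguous 1..K
    present = np.unique(levels)
    relabel = {old: new for new, old in enumerate(present, start=1)}
    levels = np.vectorize(relabel.get)(levels)
    k = len(present)
    if orientation == "descending":
        levels = k + 1 - levels
    return SecondaryVariable(levels.astype(int), kind, k)


def confidence_variable(table: TrialTable) -> SecondaryVariable:
    """The confidence column itself as a secondary variable."""
    return SecondaryVariable(table.data["confidence"].to_numpy(int),
                             "confidence", table.k_levels)


def counts_by_cell(table: TrialTable, sv: SecondaryVariable):
    """Stimulus x response x level frequency counts in the nR_S1/nR_S2 layout.

    For each stimulus class the 2K-vector is ordered
    (response=S1, level K..1, then response=S2, level 1..K) — the
    standard input layout for meta-SDT analysis.
    """
    from .metasdt import CountMatrix  # local import to avoid a cycle

    if len(sv.values) != len(table):
        raise ValueError("secondary variable length does not match table")
    k = sv.K
    stim = table.data["stimulus"].to_numpy()
    resp = table.data["response"].to_numpy()
    lev = sv.values
    out = {}
    for s in ("S1", "S2"):
        m = stim == s
        vec = np.zeros(2 * k, dtype=int)
        for j in range(1, k + 1):
            vec[k - j] = np.sum(m & (resp == "S1") & (lev == j))
            vec[k - 1 + j] = np.sum(m & (resp == "S2") & (lev == j))
        out[s] = vec
    return CountMatrix(nR_S1=out["S1"], nR_S2=out["S2"], K=k)


def type2_roc(table: TrialTable, sv: SecondaryVariable) -> Type2Curve:
    """Type-2 ROC curve and trapezoidal AUC.

    The leftmost point counts only level K as "high"; successive points
    use progressively more lenient cutoffs (levels >= K-1, >= K-2, ...).
    The AUC integrates over the interior points plus (0,0) and (1,1).
    """
    if len(sv.values) != len(table):
        raise ValueError("secondary variable length does not match table")
    correct = table.data["correct"].to_numpy(bool)
    n_corr = int(correct.sum())
    n_inc = int(len(correct) - n_corr)
    if n_corr == 0 or n_inc == 0:
        raise ValueError(
            "type-2 ROC undefined: need at least one correct and one "
            "incorrect trial"
        )
    lev = sv.values
    pts = []
    for cut in range(sv.K, 1, -1):  # stringent -> lenient
        high = lev >= cut
        far2 = np.sum(high & ~correct) / n_inc
        hr2 = np.sum(high & correct) / n_corr
        pts.append((far2, hr2))
    pts_arr = np.array(pts, dtype=float).reshape(-1, 2)
    xs = np.concatenate([[0.0], pts_arr[:, 0], [1.0]])
    ys = np.concatenate([[0.0], pts_arr[:, 1], [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return Type2Curve(points=pts_arr, auc=auc)


def export_curve(curve: Type2Curve, path) -> None:
    """Write a type-2 curve as CSV (cutoff_index, far2, hr2)."""
    import pandas as pd

    pd.DataFrame(
        {
            "cutoff_index": np.arange(1, len(curve.points) + 1),
            "far2": curve.points[:, 0],
            "hr2": curve.points[:, 1],
        }
    ).to_csv(path, index=False)
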