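"""Reading, writing and validation of per-trial 2AFC behavioral tables.

The universal input of every analysis in this package is a *trial table*:
one row per trial of a two-alternative forced-choice task, with the
subject label, the presented stimulus class (S1/S2), the observer's
response class (S1/S2), an ordinal confidence rating (1..K) and the
decision response time. Files follow the Confidence Database CSV dialect
(columns ``Subj_idx``, ``Stimulus``, ``Response``, ``Confidence``,
``RT_dec``); a ``column_map`` lets callers rebind names for datasets that
deviate from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rtmeta")

#: Default column bindings of the Confidence Database dialect.
DEFAULT_COLUMNS = {
    "subject": "Subj_idx",
    "stimulus": "Stimulus",
    "response": "Response",
    "confidence": "Confidence",
    "rt": "RT_dec",
}

_CANONICAL = ["subject", "stimulus", "response", "confidence", "rt",
              "correct", "trial_index"]


class TrialTableError(ValueError):
    """Raised when a trial table violates the format contract."""


@dataclass
class TrialTable:
    """Validated per-trial 2AFC data.

    Parameters
    ----------
    data
        DataFrame with columns ``subject`` (label), ``stimulus`` and
        ``response`` (strings ``"S1"``/``"S2"``), ``confidence`` (int,
        1..K), ``rt`` (float, ms, > 0), plus derived ``correct`` (bool)
        and ``trial_index`` (1-based order within subject). Extra
        columns (e.g. raw post-decisional evidence from the simulator)
        are carried through untouched.
    """

    data: pd.DataFrame
    k_levels: int = field(default=0)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _CANONICAL if c not in df.columns]
        if "correct" in missing or "trial_index" in missing:
            df = df.copy()
            if "correct" not in df.columns:
                df["correct"] = df["stimulus"].to_numpy() == df["response"].to_numpy()
            if "trial_index" not in df.columns:
                df["trial_index"] = (
                    df.groupby("subject", sort=False).cumcount().to_numpy() + 1
                )
            missing = [c for c in _CANONICAL if c not in df.columns]
        if missing:
            raise TrialTableError(f"missing required columns: {missing}")
        if len(df) == 0:
            raise TrialTableError("empty trial table")
        for col in ("stimulus", "response"):
            bad = set(df[col].unique()) - {"S1", "S2"}
            if bad:
                raise TrialTableError(f"{col} contains non-S1/S2 values: {bad}")
        conf = df["confidence"].to_numpy()
        if not np.issubdtype(np.asarray(conf).dtype, np.integer):
            if not np.allclose(conf, np.round(conf)):
                raise TrialTableError("confidence must be ordinal integers")
            df = df.assign(confidence=np.round(conf).astype(int))
        if df["confidence"].min() < 1:
            raise TrialTableError("confidence levels must start at 1")
        rt = df["rt"].to_numpy(float)
        if not np.all(np.isfinite(rt)) or np.any(rt <= 0):
            raise TrialTableError("rt must be strictly positive and finite")
        expected = df["stimulus"].to_numpy() == df["response"].to_numpy()
        if not np.array_equal(df["correct"].to_numpy(bool), expected):
            raise TrialTableError("correct column inconsistent with stimulus/response")
        for _, sub in df.groupby("subject", sort=False):
            idx = np.sort(sub["trial_index"].to_numpy())
            if not np.array_equal(idx, np.arange(1, len(sub) + 1)):
                raise TrialTableError("trial_index is not 1..n within subject")
        if self.k_levels <= 0:
            self.k_levels = int(df["confidence"].max())
        elif df["confidence"].max() > self.k_levels:
            raise TrialTableError("confidence exceeds declared K")
        if self.k_levels < 2:
            raise TrialTableError("confidence scale needs K >= 2 levels")
        self.data = df.reset_index(drop=True)

    # -- convenience ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.data["subject"]))

    def for_subject(self, subject) -> "TrialTable":
        sub = self.data[self.data["subject"] == subject]
        if len(sub) == 0:
            raise TrialTableError(f"no trials for subject {subject!r}")
        return TrialTable(sub.reset_index(drop=True), k_levels=self.k_levels)

    def iter_subjects(self):
        for s in self.subjects:
            yield s, self.for_subject(s)

    def equals(self, other: "TrialTable") -> bool:
        a = self.data[_CANONICAL].reset_index(drop=True)
        b = other.data[_CANONICAL].reset_index(drop=True)
        if len(a) != len(b):
            return False
        same = (
            (a["subject"].astype(str) == b["subject"].astype(str)).all()
            and (a["stimulus"] == b["stimulus"]).all()
            and (a["response"] == b["response"]).all()
            and (a["confidence"].to_numpy() == b["confidence"].to_numpy()).all()
            and np.allclose(a["rt"], b["rt"])
            and (a["trial_index"].to_numpy() == b["trial_index"].to_numpy()).all()
        )
        return bool(same)


def _coerce_class(values: pd.Series, colname: str) -> pd.Series:
    """Map {1,2}, {0,1} or {'S1','S2'} encodings onto 'S1'/'S2'."""
    vals = set(pd.unique(values.dropna()))
    if vals <= {"S1", "S2"}:
        return values.astype(str)
    numeric = pd.to_numeric(values, errors="coerce")
    nvals = set(numeric.dropna().unique())
    if nvals <= {0.0, 1.0}:
        return numeric.map({0.0: "S1", 1.0: "S2"})
    if nvals <= {1.0, 2.0}:
        return numeric.map({1.0: "S1", 2.0: "S2"})
    raise TrialTableError(
        f"column {colname!r} uses an unrecognized class encoding: {sorted(vals)[:6]}"
    )


def read_trials(path, column_map: dict | None = None,
                rt_scale: float = 1.0) -> TrialTable:
    """Read a Confidence-Database-dialect CSV into a :class:`TrialTable`.

    Rows with a missing stimulus, response, confidence or RT are dropped
    (the count is logged). ``rt_scale`` multiplies the RT column (the file's
    unit is taken as given; pass e.g. 1000 for seconds-coded files).
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path)
    for role, name in cols.items():
        if name not in raw.columns:
            raise TrialTableError(
                f"required column {name!r} (role: {role}) not found in {path}"
            )
    df = pd.DataFrame(
        {
            "subject": raw[cols["subject"]],
            "stimulus": raw[cols["stimulus"]],
            "response": raw[cols["response"]],
            "confidence": pd.to_numeric(raw[cols["confidence"]], errors="coerce"),
            "rt": pd.to_numeric(raw[cols["rt"]], errors="coerce") * rt_scale,
        }
    )
    n_raw = len(df)
    keep = (
        df["subject"].notna()
        & df["stimulus"].notna()
        & df["response"].notna()
        & df["confidence"].notna()
        & df["rt"].notna()
        & (df["rt"] > 0)
    )
    dropped = int(n_raw - keep.sum())
    if dropped:
        logger.info("read_trials(%s): dropped %d of %d rows with missing fields",
                    path, dropped, n_raw)
    df = df[keep].reset_index(drop=True)
    if len(df) == 0:
        raise TrialTableError(f"no valid trials left in {path}")
    df["stimulus"] = _coerce_class(df["stimulus"], cols["stimulus"])
    df["response"] = _coerce_class(df["response"], cols["response"])
    df["confidence"] = df["confidence"].astype(int)
    return TrialTable(df)


def write_trials(table: TrialTable, path) -> None:
    """Write a trial table back to the CSV dialect read by :func:`read_trials`.

    ``read_trials(write_trials(t)) == t`` field-for-field.
    """
    out = pd.DataFrame(
        {
            "Subj_idx": table.data["subject"],
            "Stimulus": table.data["stimulus"],
            "Response": table.data["response"],
            "Confidence": table.data["confidence"],
            "RT_dec": table.data["rt"],
        }
    )
    out.to_csv(path, index=False)
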