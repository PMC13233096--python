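"""Confidence + RT composite secondary variable via per-subject logistic regression.

Trial-by-trial response correctness is regressed on raw confidence, raw
RT and their interaction within each subject; the fitted linear
predictor (the log-odds of being correct) then serves as a single
composite secondary variable for type-2 analysis. The construction is
deliberately in-sample — the same trials are used to fit the logit and
to score it — mirroring how the composite index is defined; at small n
the composite can therefore beat its ingredients through overfitting,
a property that shrinks as n grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .io_trials import TrialTable
from .type2 import SecondaryVariable, bin_by_quantiles

#: |coefficient| beyond which a logistic fit is treated as separated.
_SEPARATION_COEF = 1e2
_RIDGE_ALPHA = 1e-4


class UnfittableModelError(ValueError):
    """Subject has no correct (or no incorrect) trials; logistic fit undefined."""


@dataclass
class CompositeModel:
    beta0: float
    beta_conf: float
    beta_rt: float
    beta_interaction: float
    subject_id: object
    fitted: bool
    separation_flag: bool


def _design(confidence: np.ndarray, rt: np.ndarray) -> np.ndarray:
    x = np.column_stack([
        np.ones_like(rt),
        confidence,
        rt,
        confidence * rt,
    ])
    return x


def fit_composite(table: TrialTable, min_trials: int = 20,
                  confidence_values: np.ndarray | None = None) -> CompositeModel:
    """Fit correct ~ confidence + RT + confidence x RT for one subject.

    Predictors enter raw (no standardization or discretization).
    ``confidence_values`` overrides the ordinal confidence column with a
    continuous rating (the simulator's raw post-decisional evidence).
    On complete or quasi-separation the model is refit with a small L2
    penalty and flagged.
    """
    if len(table.subjects) != 1:
        raise ValueError("fit_composite expects a single subject's trials")
    subject = table.subjects[0]
    if len(table) < min_trials:
        raise UnfittableModelError(
            f"subject {subject!r}: {len(table)} trials < floor {min_trials}"
        )
    y = table.data["correct"].to_numpy(float)
    if y.min() == y.max():
        raise UnfittableModelError(
            f"subject {subject!r} is all-correct or all-incorrect"
        )
    conf = (np.asarray(confidence_values, float) if confidence_values is not None
            else table.data["confidence"].to_numpy(float))
    rt = table.data["rt"].to_numpy(float)
    x = _design(conf, rt)

    separated = False
    params = None
    with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=200)
            params = np.asarray(res.params)
            scaled = np.abs(params[1:]) * np.std(x[:, 1:], axis=0)
            if (not np.all(np.isfinite(params))
                    or np.max(scaled) > _SEPARATION_COEF
                    or any(issubclass(w.category, PerfectSeparationWarning)
                           for w in caught)):
                separated = True
        except Exception:
            separated = True
    if separated:
        res = sm.GLM(y, x, family=sm.families.Binomial()).fit_regularized(
            alpha=_RIDGE_ALPHA, L1_wt=0.0, maxiter=500
        )
        params = np.asarray(res.params)
    return CompositeModel(
        beta0=float(params[0]),
        beta_conf=float(params[1]),
        beta_rt=float(params[2]),
        beta_interaction=float(params[3]),
        subject_id=subject,
        fitted=True,
        separation_flag=separated,
    )


def composite_logits(model: CompositeModel, table: TrialTable, n_bins: int,
                     confidence_values: np.ndarray | None = None) -> SecondaryVariable:
    """Score the fitted logit on the subject's trials and quantile-bin it.

    Returns a ``kind="composite"`` secondary variable with ascending
    orientation (larger logit = more likely correct = higher level).
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    conf = (np.asarray(confidence_values, float) if confidence_values is not None
            else table.data["confidence"].to_numpy(float))
    rt = table.data["rt"].to_numpy(float)
    logit = _design(conf, rt) @ np.array(
        [model.beta0, model.beta_conf, model.beta_rt, model.beta_interaction]
    )
    return bin_by_quantiles(logit, n_bins, orientation="ascending",
                            kind="composite")


def export_models(models: list, path) -> None:
    """Coefficient table CSV, one row per subject."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "subject": m.subject_id,
                "beta0": m.beta0,
                "beta_conf": m.beta_conf,
                "beta_rt": m.beta_rt,
                "beta_interaction": m.beta_interaction,
                "separation_flag": m.separation_flag,
            }
            for m in models
        ]
    ).to_csv(path, index=False)
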