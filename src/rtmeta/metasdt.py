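"""Equal-variance SDT and maximum-likelihood meta-d' estimation.

Meta-d' asks: what type-1 sensitivity would an ideal signal-detection
observer need so that, rating confidence by distance from the criterion,
it reproduces the observed response-conditional distribution of the
secondary variable? Because meta-d' is expressed in d' units it is
directly comparable to the type-1 d' of the same data, and their ratio
(the m-ratio) indexes metacognitive efficiency.

The estimator is the classic single-meta-d' maximum-likelihood fit: the
meta-level stimulus distributions are Normal(-meta_d'/2, 1) and
Normal(+meta_d'/2, 1), the meta-level type-1 criterion is linked to the
empirical relative criterion c' = c/d', and K-1 free type-2 criteria on
each side of it (ordering enforced by construction) are chosen together
with meta-d' to maximize the multinomial likelihood of the
response-conditional level counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

_PFLOOR = 1e-12  # probability floor inside the log-likelihood


class DegenerateFitError(ValueError):
    """An entire response side is empty; the meta-level fit is undefined."""


@dataclass
class CountMatrix:
    """Response-conditional secondary-level counts per stimulus class.

    ``nR_S1[i]`` / ``nR_S2[i]`` count trials of stimulus S1 / S2 in the
    standard 2K layout: (response=S1, level K..1) then
    (response=S2, level 1..K).
    """

    nR_S1: np.ndarray
    nR_S2: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.nR_S1 = np.asarray(self.nR_S1)
        self.nR_S2 = np.asarray(self.nR_S2)
        if self.nR_S1.shape != (2 * self.K,) or self.nR_S2.shape != (2 * self.K,):
            raise ValueError("count vectors must have length 2K")
        if np.any(self.nR_S1 < 0) or np.any(self.nR_S2 < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.nR_S1.sum() + self.nR_S2.sum())


@dataclass
class MetaSDTFit:
    d_prime: float
    c: float
    meta_d_prime: float
    meta_c: float
    t2_criteria: np.ndarray  # 2K-2 values, ascending, meta_c between halves
    m_ratio: float
    loglik: float
    converged: bool
    K: int = field(default=0)


def fit_type1(counts: CountMatrix, padding: float | None = None):
    """Equal-variance SDT d' and criterion c from a count matrix.

    HR = P(resp S2 | S2), FAR = P(resp S2 | S1) after adding ``padding``
    to every cell (default 1/(2K)); d' = z(HR) - z(FAR),
    c = -(z(HR) + z(FAR)) / 2.
    """
    if padding is None:
        padding = 1.0 / (2 * counts.K)
    k = counts.K
    if padding == 0 and (counts.nR_S1.sum() == 0 or counts.nR_S2.sum() == 0):
        raise ValueError("a stimulus class has zero trials and padding is 0")
    s1 = counts.nR_S1 + padding
    s2 = counts.nR_S2 + padding
    far = s1[k:].sum() / s1.sum()
    hr = s2[k:].sum() / s2.sum()
    if padding == 0 and (hr in (0.0, 1.0) or far in (0.0, 1.0)):
        raise ValueError("degenerate hit/false-alarm rate with zero padding")
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def _criteria_from_theta(theta: np.ndarray, meta_c: float, K: int) -> np.ndarray:
    """Map unconstrained log-increments to 2K-2 ordered criteria."""
    left = meta_c - np.cumsum(np.exp(theta[: K - 1]))
    right = meta_c + np.cumsum(np.exp(theta[K - 1:]))
    return np.concatenate([left[::-1], right])


def _neg_loglik(params: np.ndarray, obs_s1: np.ndarray, obs_s2: np.ndarray,
                cprime: float, K: int) -> float:
    meta_d = params[0]
    meta_c = cprime * meta_d
    crit = _criteria_from_theta(params[1:], meta_c, K)
    total = 0.0
    for obs, mu in ((obs_s1, -meta_d / 2.0), (obs_s2, +meta_d / 2.0)):
        # response S1: region (-inf, meta_c); level j between b[K-j] and b[K-j+1]
        b_left = np.concatenate([[-np.inf], crit[: K - 1], [meta_c]])
        cdf_left = norm.cdf(b_left - mu)
        p_resp_s1 = cdf_left[-1]
        seg = np.diff(cdf_left)            # level K .. level 1
        p_s1_side = seg[::-1] / max(p_resp_s1, _PFLOOR)   # level 1..K
        # response S2: region (meta_c, inf)
        b_right = np.concatenate([[meta_c], crit[K - 1:], [np.inf]])
        sf_right = norm.sf(b_right - mu)
        p_resp_s2 = sf_right[0]
        p_s2_side = (-np.diff(sf_right)) / max(p_resp_s2, _PFLOOR)  # level 1..K
        # observed layout: (resp S1, level K..1), (resp S2, level 1..K)
        pred = np.concatenate([p_s1_side[::-1], p_s2_side])
        total -= np.sum(obs * np.log(np.maximum(pred, _PFLOOR)))
    return total


def _init_criteria(counts: CountMatrix, padding: float, K: int) -> np.ndarray:
    """Type-2 criteria starting values from empirical cumulative-rate z-scores."""
    s1 = counts.nR_S1 + padding
    s2 = counts.nR_S2 + padding
    crit = []
    for j in range(K - 1, 0, -1):  # left side, most extreme first
        # P(resp S1 & level > j | stim) = P(x < c_{-j} | stim)
        p1 = s1[: K - j].sum() / s1.sum()
        p2 = s2[: K - j].sum() / s2.sum()
        crit.append(-0.5 * (norm.ppf(1 - np.clip(p1, 1e-6, 1 - 1e-6))
                            + norm.ppf(1 - np.clip(p2, 1e-6, 1 - 1e-6))))
    for j in range(1, K):  # right side
        p1 = s1[K + j:].sum() / s1.sum()
        p2 = s2[K + j:].sum() / s2.sum()
        crit.append(-0.5 * (norm.ppf(np.clip(p1, 1e-6, 1 - 1e-6))
                            + norm.ppf(np.clip(p2, 1e-6, 1 - 1e-6))))
    return np.asarray(crit)


def fit_meta_d(counts: CountMatrix, padding: float | None = None,
               maxiter: int = 2000) -> MetaSDTFit:
    """Maximum-likelihood meta-d' fit of a count matrix.

    Every cell receives ``padding`` (default 1/(2K)) before fitting, the
    convention that keeps sparse subjects finite. The optimization runs
    from a deterministic start (meta-d' at the type-1 d', criteria at
    empirical cumulative-rate z-scores) with the criterion ordering
    enforced through a log-increment parameterization; ``converged``
    reports the optimizer's success flag.
    """
    K = counts.K
    if padding is None:
        padding = 1.0 / (2 * K)
    raw_s1_side = counts.nR_S1[:K].sum() + counts.nR_S2[:K].sum()
    raw_s2_side = counts.nR_S1[K:].sum() + counts.nR_S2[K:].sum()
    if raw_s1_side == 0 or raw_s2_side == 0:
        raise DegenerateFitError("an entire response side has zero trials")

    d_prime, c = fit_type1(counts, padding=padding)
    cprime = c / d_prime if abs(d_prime) > 1e-6 else 0.0

    obs_s1 = counts.nR_S1 + padding
    obs_s2 = counts.nR_S2 + padding

    meta_c0 = cprime * d_prime
    crit0 = _init_criteria(counts, padding, K)
    left0 = np.minimum(crit0[: K - 1], meta_c0 - 1e-3)   # ascending, < meta_c
    right0 = np.maximum(crit0[K - 1:], meta_c0 + 1e-3)   # ascending, > meta_c
    left_inc = np.diff(np.concatenate([[meta_c0], left0[::-1]])) * -1
    right_inc = np.diff(np.concatenate([[meta_c0], right0]))
    left_inc = np.where(left_inc > 1e-3, left_inc, 0.1)
    right_inc = np.where(right_inc > 1e-3, right_inc, 0.1)
    theta0 = np.concatenate([[d_prime], np.log(left_inc), np.log(right_inc)])

    res = minimize(
        _neg_loglik, theta0, args=(obs_s1, obs_s2, cprime, K),
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
    )
    meta_d = float(res.x[0])
    meta_c = cprime * meta_d
    crit = _criteria_from_theta(res.x[1:], meta_c, K)
    return MetaSDTFit(
        d_prime=d_prime,
        c=c,
        meta_d_prime=meta_d,
        meta_c=float(meta_c),
        t2_criteria=crit,
        m_ratio=float(meta_d / d_prime) if abs(d_prime) > 1e-12 else np.nan,
        loglik=float(-res.fun),
        converged=bool(res.success),
        K=K,
    )


def exclude_subjects(fits: dict, d_range: tuple = (-1.0, 4.0)) -> dict:
    """Partition per-subject fits into retained and excluded, with reasons.

    A subject is excluded when any of their fits failed to converge, or
    when any d' or meta-d' falls strictly outside ``d_range`` (endpoints
    inclusive). ``fits`` maps subject -> MetaSDTFit or a sequence of
    MetaSDTFit (one per secondary variable).

    Returns ``{"retained": [...], "excluded": [(subject, reason), ...]}``.
    """
    lo, hi = d_range
    retained, excluded = [], []
    for subject, f in fits.items():
        flist = list(f) if isinstance(f, (list, tuple)) else [f]
        reason = None
        for fit in flist:
            if not fit.converged:
                reason = "non-convergence"
                break
            if not (lo <= fit.d_prime <= hi) or not (lo <= fit.meta_d_prime <= hi):
                reason = "out-of-range"
                break
        if reason is None:
            retained.append(subject)
        else:
            excluded.append((subject, reason))
    return {"retained": retained, "excluded": excluded}


def export_fits(fits: list, path) -> None:
    """Write per-subject fit rows (subject, kind, d', c, meta-d', m-ratio, ...)."""
    import pandas as pd

    rows = []
    for entry in fits:
        subject, kind, fit, excl, reason = entry
        rows.append(
            {
                "subject": subject,
                "variable_kind": kind,
                "d_prime": fit.d_prime,
                "c": fit.c,
                "meta_d": fit.meta_d_prime,
                "m_ratio": fit.m_ratio,
                "converged": fit.converged,
                "excluded": excl,
                "reason": reason,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
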