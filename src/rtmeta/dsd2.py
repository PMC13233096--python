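"""Two-stage dynamic signal detection (2DSD) simulator.

A drift-diffusion decision stage plus a post-decisional accumulation
window. Evidence for the target and the distractor evolves in discrete
1-ms steps; a single relative-evidence accumulator (target minus
distractor) starts at a uniformly jittered point between boundaries at
±a/2 and a choice is made at the first boundary crossing. Accumulation
then continues for ``t_pd`` further steps, and raw confidence is the
relative evidence in favor of the *chosen* option at that moment — so
confidence carries graded information only insofar as the
post-decisional window lets the true drift reassert itself.

Two sources of trial-to-trial variability shape the RT-accuracy
relationship: drift-rate variability ``eta`` makes correct responses
faster than errors (slow errors), whereas starting-point variability
``s_z`` produces fast errors; crossing the two regimes with a range of
target drift rates yields the condition grid whose summaries the rest
of the package analyzes. The simulator doubles as the package's
synthetic-data generator: every downstream stage can be exercised on
its output without any external dataset.

The boundary separation ``a`` and the post-decisional window ``t_pd``
are fixed package-wide constants obtained by a one-off calibration of
the default grid (20,000 trials/condition): ``a`` was tuned so the
grid-average type-1 d' is 1.13 and ``t_pd`` so the grid-average
confidence meta-d' is 0.81 (see :func:`calibrate_defaults`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_trials import TrialTable
from .type2 import bin_by_quantiles

# ---------------------------------------------------------------------------
# Parameters and the default manipulation grid
# ---------------------------------------------------------------------------

#: Manipulated parameter values of the default condition grid.
NU_TARGET_VALUES = (0.004, 0.007, 0.010, 0.014, 0.020)
ETA_VALUES = (0.002, 0.012)
SZ_VALUES = (0.5, 2.0)

#: Calibrated constants (see module docstring and ``calibrate_defaults``).
DEFAULT_A = 2.257
DEFAULT_T_PD = 16
DEFAULT_S = 0.1
DEFAULT_T_ER = 300
DEFAULT_RT_CUTOFF = 3000.0


@dataclass
class DSDParams:
    """Full 2DSD parameterization (units: evidence/step, steps of 1 ms)."""

    nu_target: float = 0.009      # mean target drift rate
    nu_distractor: float = 0.0    # mean distractor drift rate
    eta: float = 0.002            # trial-to-trial drift SD (per stream)
    s: float = DEFAULT_S          # within-trial increment SD (per stream)
    s_z: float = 0.5              # starting-point variability range
    t_er: int = DEFAULT_T_ER      # non-decision time, steps
    a: float = DEFAULT_A          # boundary separation (relative axis)
    t_pd: int = DEFAULT_T_PD      # post-decisional steps
    dt: float = 1.0               # step duration, ms (fixed)
    max_steps: int = 3000         # decision-stage cap

    def __post_init__(self) -> None:
        if self.s <= 0 or self.a <= 0 or self.t_pd < 0:
            raise ValueError("require s > 0, a > 0, t_pd >= 0")
        if not (0 <= self.s_z < self.a):
            raise ValueError("require 0 <= s_z < a")


def default_grid() -> list:
    """The full cross of the manipulated parameters with calibrated constants."""
    return [
        replace(DSDParams(), nu_target=nu, eta=eta, s_z=sz)
        for nu, eta, sz in itertools.product(NU_TARGET_VALUES, ETA_VALUES,
                                             SZ_VALUES)
    ]


def grid_from_config(config: dict) -> list:
    """Build a condition grid from a declarative mapping.

    ``config`` holds lists for the manipulated parameters
    (``nu_target``, ``eta``, ``s_z``) and optional scalars for any
    other :class:`DSDParams` field; omitted entries use the defaults.
    """
    nus = config.get("nu_target", list(NU_TARGET_VALUES))
    etas = config.get("eta", list(ETA_VALUES))
    szs = config.get("s_z", list(SZ_VALUES))
    manipulated = {"nu_target", "eta", "s_z"}
    scalars = {k: v for k, v in config.items()
               if k not in manipulated and k in DSDParams.__dataclass_fields__}
    return [
        DSDParams(nu_target=nu, eta=eta, s_z=sz, **scalars)
        for nu, eta, sz in itertools.product(nus, etas, szs)
    ]


# ---------------------------------------------------------------------------
# Core stochastic process
# ---------------------------------------------------------------------------

def _first_passage(rng, mu, sigma, z0, bound, max_steps, block=256):
    """Vectorized first boundary crossing of per-trial Gaussian random walks.

    Returns (decision step, choice sign +1 upper / -1 lower, evidence at
    crossing, censored mask). Censored trials never crossed within
    ``max_steps``.
    """
    n = len(mu)
    step_of = np.zeros(n, dtype=int)
    sign = np.zeros(n, dtype=int)
    x_dec = np.zeros(n, dtype=float)
    x = np.asarray(z0, float).copy()
    active = np.arange(n)
    t = 0
    while t < max_steps and len(active):
        b = min(block, max_steps - t)
        inc = rng.normal(mu[active][:, None], sigma, size=(len(active), b))
        paths = x[active][:, None] + np.cumsum(inc, axis=1)
        hit = (paths >= bound) | (paths <= -bound)
        any_hit = hit.any(axis=1)
        first = hit.argmax(axis=1)
        idx = active[any_hit]
        fh = first[any_hit]
        step_of[idx] = t + fh + 1
        xv = paths[any_hit, fh]
        x_dec[idx] = xv
        sign[idx] = np.where(xv >= bound, 1, -1)
        x[active[~any_hit]] = paths[~any_hit, b - 1]
        active = active[~any_hit]
        t += b
    censored = np.zeros(n, dtype=bool)
    censored[active] = True
    return step_of, sign, x_dec, censored


def simulate_trials(params: DSDParams, n_trials: int, rng) -> pd.DataFrame:
    """Raw simulated trials (before exclusion), target counterbalanced.

    Exactly half the trials assign the target to S1 (random order).
    Columns: stimulus, response, correct, rt (steps incl. t_er),
    conf_raw (relative evidence for the chosen option at decision +
    t_pd), censored.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even for counterbalancing")
    drift_t = rng.normal(params.nu_target, params.eta, n_trials)
    drift_d = rng.normal(params.nu_distractor, params.eta, n_trials)
    mu = drift_t - drift_d
    sigma = params.s * np.sqrt(2.0)
    z0 = rng.uniform(-params.s_z / 2.0, params.s_z / 2.0, n_trials)
    bound = params.a / 2.0

    step, sign, x_dec, censored = _first_passage(
        rng, mu, sigma, z0, bound, params.max_steps
    )
    # post-decisional stage has no boundary, so its increment sum is drawn
    # in closed form: Normal(t_pd * mu, sigma * sqrt(t_pd))
    if params.t_pd > 0:
        post = rng.normal(params.t_pd * mu,
                          sigma * np.sqrt(params.t_pd), n_trials)
    else:
        post = np.zeros(n_trials)
    conf_raw = sign * (x_dec + post)

    target_is_s1 = np.zeros(n_trials, dtype=bool)
    target_is_s1[: n_trials // 2] = True
    rng.shuffle(target_is_s1)

    chose_target = sign == 1
    stimulus = np.where(target_is_s1, "S1", "S2")
    response = np.where(chose_target, stimulus,
                        np.where(target_is_s1, "S2", "S1"))
    rt = step.astype(float) * params.dt + params.t_er
    return pd.DataFrame(
        {
            "stimulus": stimulus,
            "response": response,
            "correct": chose_target,
            "rt": rt,
            "conf_raw": conf_raw,
            "censored": censored,
        }
    )


def simulate_condition(params: DSDParams, n_trials: int, seed,
                       subject="sim", n_levels: int = 10,
                       rt_cutoff: float = DEFAULT_RT_CUTOFF) -> TrialTable:
    """Simulate one condition and return an analysis-ready trial table.

    Censored trials and trials with RT > ``rt_cutoff`` (non-decision time
    included) are excluded; raw confidence is carried in the ``conf_raw``
    column and also pre-discretized into ``n_levels`` quantile levels in
    the ``confidence`` column (re-derivable at any resolution with
    :func:`discretize_outputs`).
    """
    rng = np.random.default_rng(seed)
    raw = simulate_trials(params, n_trials, rng)
    keep = (~raw["censored"]) & (raw["rt"] <= rt_cutoff)
    df = raw[keep].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("all trials censored/excluded; pathological parameters")
    conf_sv = bin_by_quantiles(df["conf_raw"].to_numpy(), n_levels,
                               orientation="ascending", kind="confidence")
    out = pd.DataFrame(
        {
            "subject": subject,
            "stimulus": df["stimulus"],
            "response": df["response"],
            "confidence": conf_sv.values,
            "rt": df["rt"],
            "conf_raw": df["conf_raw"],
        }
    )
    return TrialTable(out, k_levels=conf_sv.K)


def discretize_outputs(table: TrialTable, n_levels: int = 10):
    """Re-discretize raw confidence and bin RT, both per condition.

    Returns ``(table, rt_sv)`` where the table's ``confidence`` column
    holds ``n_levels`` quantile levels of ``conf_raw`` (ascending) and
    ``rt_sv`` is the RT secondary variable (descending: fast = high).
    """
    if "conf_raw" not in table.data.columns:
        raise ValueError("table lacks the simulator's conf_raw column")
    conf_sv = bin_by_quantiles(table.data["conf_raw"].to_numpy(), n_levels,
                               orientation="ascending", kind="confidence")
    df = table.data.copy()
    df["confidence"] = conf_sv.values
    new_table = TrialTable(df, k_levels=conf_sv.K)
    rt_sv = bin_by_quantiles(df["rt"].to_numpy(), n_levels,
                             orientation="descending", kind="rt")
    return new_table, rt_sv


# ---------------------------------------------------------------------------
# Condition-grid analysis
# ---------------------------------------------------------------------------

def run_grid(grid=None, n_trials: int = 20_000, seed=0,
             n_levels: int = 10) -> pd.DataFrame:
    """Simulate every grid condition and fit the three meta-d' variants.

    Per condition: simulate, exclude slow/censored trials, discretize
    confidence and RT into ``n_levels`` quantile levels, fit meta-d' for
    confidence, RT, and the logistic confidence x RT composite (the
    regression sees the *raw* conf_raw and RT). One master ``seed``
    spawns an independent substream per condition.
    """
    from .metasdt import DegenerateFitError
    from .reliability_meta import metad_for_variant

    if grid is None:
        grid = default_grid()
    children = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for i, (params, ss) in enumerate(zip(grid, children)):
        table = simulate_condition(params, n_trials, ss,
                                   subject=f"cond_{i:02d}", n_levels=n_levels)
        conf_raw = table.data["conf_raw"].to_numpy()
        row = {
            "condition": i,
            "nu_target": params.nu_target,
            "eta": params.eta,
            "s_z": params.s_z,
            "n_retained": len(table),
        }
        try:
            fit_conf = metad_for_variant(table, "confidence")
            fit_rt = metad_for_variant(table, "rt", n_bins=n_levels)
            fit_comp = metad_for_variant(table, "composite", n_bins=n_levels,
                                         confidence_values=conf_raw)
        except DegenerateFitError as exc:
            row.update({"failed": str(exc)})
            rows.append(row)
            continue
        row.update(
            {
                "d_prime": fit_conf.d_prime,
                "meta_d_conf": fit_conf.meta_d_prime,
                "meta_d_rt": fit_rt.meta_d_prime,
                "meta_d_comp": fit_comp.meta_d_prime,
                "m_ratio_conf": fit_conf.m_ratio,
                "m_ratio_rt": fit_rt.m_ratio,
                "m_ratio_comp": fit_comp.m_ratio,
                "ratio_comp_conf": fit_comp.meta_d_prime / fit_conf.meta_d_prime,
                "converged": fit_conf.converged and fit_rt.converged
                and fit_comp.converged,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_subjects(n_subjects: int, n_trials: int, seed,
                      nu_range=(0.004, 0.020), eta_range=(0.001, 0.017),
                      sz_range=(0.2, 2.1), n_levels: int = 10) -> TrialTable:
    """A synthetic "dataset" of heterogeneous 2DSD observers.

    Each subject draws their own (nu_target, eta, s_z) uniformly from
    the given ranges, inducing real between-subject variation in both
    type-1 and type-2 performance — the structure the reliability and
    meta-analysis stages need.
    """
    master = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    children = master.spawn(n_subjects + 1)[1:]
    frames = []
    k = None
    for j, ss in enumerate(children):
        params = replace(
            DSDParams(),
            nu_target=param_rng.uniform(*nu_range),
            eta=param_rng.uniform(*eta_range),
            s_z=param_rng.uniform(*sz_range),
        )
        t = simulate_condition(params, n_trials, ss,
                               subject=f"subj_{j:03d}", n_levels=n_levels)
        k = t.k_levels
        frames.append(t.data)
    return TrialTable(pd.concat(frames, ignore_index=True), k_levels=k)


# ---------------------------------------------------------------------------
# One-off calibration of the fixed constants
# ---------------------------------------------------------------------------

def calibrate_defaults(target_d: float = 1.13, target_meta_d: float = 0.81,
                       n_trials: int = 20_000, seed: int = 12345,
                       verbose: bool = False):
    """Re-derive the calibrated constants ``a`` and ``t_pd``.

    Bisects the boundary separation so the grid-average d' hits
    ``target_d``, then bisects the post-decisional window so the
    grid-average confidence meta-d' hits ``target_meta_d`` (confidence
    information grows monotonically with t_pd). This reproduces the
    shipped DEFAULT_A / DEFAULT_T_PD; it is not run as part of any
    pipeline.
    """
    from .metasdt import fit_type1
    from .reliability_meta import metad_for_variant
    from .type2 import confidence_variable, counts_by_cell

    def avg_d(a):
        grid = [replace(p, a=a, s_z=min(p.s_z, a * 0.95)) for p in default_grid()]
        children = np.random.SeedSequence(seed).spawn(len(grid))
        ds = []
        for params, ss in zip(grid, children):
            t = simulate_condition(params, n_trials, ss)
            d, _ = fit_type1(counts_by_cell(t, confidence_variable(t)))
            ds.append(d)
        return float(np.mean(ds))

    lo, hi = 1.0, 10.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        d = avg_d(mid)
        if verbose:
            print(f"a={mid:.4f} -> avg d'={d:.4f}")
        if d < target_d:
            lo = mid
        else:
            hi = mid
        if hi - lo < 0.02:
            break
    a_star = 0.5 * (lo + hi)

    def avg_meta(tpd):
        grid = [replace(p, a=a_star, t_pd=int(tpd)) for p in default_grid()]
        children = np.random.SeedSequence(seed).spawn(len(grid))
        ms = []
        for params, ss in zip(grid, children):
            t = simulate_condition(params, n_trials, ss)
            ms.append(metad_for_variant(t, "confidence").meta_d_prime)
        return float(np.mean(ms))

    lo, hi = 10, 3000
    for _ in range(14):
        mid = int(0.5 * (lo + hi))
        m = avg_meta(mid)
        if verbose:
            print(f"t_pd={mid} -> avg meta-d'={m:.4f}")
        if m < target_meta_d:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 5:
            break
    return a_star, int(0.5 * (lo + hi))
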