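"""Bounded nonlinear least-squares estimation of the dynamic model's free
parameters: the transmission delay, the direct-pathway gain G_acc and the
integrator-pathway gain G_i.

The objective is the per-sample difference between measured and simulated
horizontal eye velocity over the whole series of trials, with quick-phase /
saccade samples excluded. Minimization uses a damped least-squares method
with bound support (scipy's trust-region-reflective solver): the delay is
bounded to [0, 75 ms] and the gains are required only to be non-negative.
The delay enters the simulation as a fractional-sample interpolation shift,
so the objective is smooth in all three parameters. A seeded multi-start
guards against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .dynamic_model import DELAY_MAX, ModelParameters, simulate_tvor
from .exceptions import InsufficientDataError
from .synthetic_data import Trial


def _params_for_trial(params: ModelParameters, trial: Trial) -> ModelParameters:
    d = trial.meta.get("distance")
    if d is not None and float(d) != params.distance:
        return params.replace(distance=float(d))
    return params


def error_vector(params: ModelParameters, trials: list[Trial]) -> np.ndarray:
    """Concatenated (measured - simulated) eye velocity over unmasked samples.

    The geometry stage uses each trial's viewing distance from its metadata
    when present. A fully masked trial contributes no rows.
    """
    if not trials:
        raise ValueError("at least one trial is required")
    pieces = []
    for trial in trials:
        p = _params_for_trial(params, trial)
        sim = simulate_tvor(p, trial.chair, dt=trial.eye.dt)
        sim_vel = np.interp(trial.eye.time, sim.time, sim.eye_velocity)
        keep = ~trial.eye.mask
        pieces.append((trial.eye.velocity - sim_vel)[keep])
    resid = np.concatenate(pieces) if pieces else np.empty(0)
    if resid.size == 0:
        raise InsufficientDataError("no unmasked samples available for the error function")
    return resid


@dataclass
class OptimizationResult:
    params: ModelParameters
    residual_ss: float
    n_iterations: int
    status: int
    message: str
    converged: bool
    start_points: list[tuple[float, float, float]] = field(default_factory=list)
    start_costs: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def optimize_parameters(
    trials: list[Trial],
    init: tuple[float, float, float] = (0.3, 0.05, 0.030),
    base_params: ModelParameters | None = None,
    n_starts: int = 5,
    seed: int = 0,
    max_nfev: int = 200,
) -> OptimizationResult:
    """Fit (G_i, G_acc, delay) to the trials by bounded least squares.

    ``init`` is the first start point (g_i, g_acc, tau); the remaining
    ``n_starts - 1`` starts are drawn from a seeded generator over plausible
    ranges. The best (lowest-residual) solution is returned; non-convergence
    is flagged on the result rather than raised.
    """
    if base_params is None:
        base_params = ModelParameters()
    lower = np.array([0.0, 0.0, 0.0])
    upper = np.array([np.inf, np.inf, DELAY_MAX])
    x0 = np.clip(np.asarray(init, dtype=float), lower, [1e6, 1e6, DELAY_MAX])

    def fun(x):
        p = base_params.replace(g_i=x[0], g_acc=x[1], tau_delay=x[2])
        return error_vector(p, trials)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.array(
                [
                    np.exp(rng.uniform(np.log(0.05), np.log(2.0))),
                    np.exp(rng.uniform(np.log(0.01), np.log(0.5))),
                    rng.uniform(0.005, 0.070),
                ]
            )
        )

    best = None
    start_points, start_costs = [], []
    for x_start in starts:
        res = least_squares(
            fun,
            x_start,
            bounds=(lower, upper),
            method="trf",
            x_scale=[0.3, 0.05, 0.01],
            max_nfev=max_nfev,
        )
        start_points.append(tuple(float(v) for v in x_start))
        start_costs.append(2.0 * float(res.cost))
        if best is None or res.cost < best.cost:
            best = res

    fitted = base_params.replace(
        g_i=float(best.x[0]),
        g_acc=float(best.x[1]),
        tau_delay=float(min(best.x[2], DELAY_MAX)),
    )
    meta = dict(trials[0].meta) if trials else {}
    meta.pop("trial_index", None)
    meta.pop("direction_index", None)
    return OptimizationResult(
        params=fitted,
        residual_ss=float(np.sum(best.fun**2)),
        n_iterations=int(best.nfev),
        status=int(best.status),
        message=str(best.message),
        converged=bool(best.status > 0),
        start_points=start_points,
        start_costs=start_costs,
        meta=meta,
    )


@dataclass
class LesionContrast:
    """Per-condition percent changes with t-based 95% CI and p-values."""

    table: pd.DataFrame
    summary: dict


def _condition_key(meta: dict) -> tuple:
    return tuple(meta.get(k) for k in ("animal", "eye", "direction", "distance", "target"))


def lesion_contrast(
    pre_fits: list[OptimizationResult], post_fits: list[OptimizationResult]
) -> LesionContrast:
    """Percent change (post vs pre) of G_i and G_acc across matched conditions."""
    pre_by = {_condition_key(r.meta): r for r in pre_fits}
    post_by = {_condition_key(r.meta): r for r in post_fits}
    if set(pre_by) != set(post_by) or len(pre_by) != len(pre_fits):
        raise ValueError("pre/post condition lists must match one-to-one")
    rows = []
    for key in sorted(pre_by, key=str):
        p, q = pre_by[key].params, post_by[key].params
        rows.append(
            {
                "condition": key,
                "gi_pct_change": 100.0 * (q.g_i - p.g_i) / p.g_i,
                "gacc_pct_change": 100.0 * (q.g_acc - p.g_acc) / p.g_acc,
                "tau_pre_ms": 1e3 * p.tau_delay,
                "tau_post_ms": 1e3 * q.tau_delay,
            }
        )
    table = pd.DataFrame(rows)
    summary = {}
    for name, col in (("g_i", "gi_pct_change"), ("g_acc", "gacc_pct_change")):
        changes = table[col].to_numpy()
        mean = float(np.mean(changes))
        n = len(changes)
        if n > 1 and np.ptp(changes) > 0:
            sem = float(stats.sem(changes))
            ci = float(stats.t.ppf(0.975, n - 1) * sem)
            t, p_val = stats.ttest_1samp(changes, 0.0)
        else:
            ci, t, p_val = 0.0, (0.0 if mean == 0 else np.inf), (1.0 if mean == 0 else 0.0)
        summary[name] = {
            "mean_pct_change": mean,
            "ci95": ci,
            "t": float(t),
            "p": float(p_val),
            "n": n,
        }
    return LesionContrast(table, summary)
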