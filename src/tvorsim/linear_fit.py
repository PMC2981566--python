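"""Two-parameter linear model of the tVOR with latency grid search.

Eye velocity is modeled as a delayed linear combination of head velocity and
head acceleration,

    omega_fit(t) = g_v * xdot_h(t - dt) + g_a * xddot_h(t - dt),

with the latency dt searched over a 10-80 ms grid in 2 ms steps (the chair
signal's sampling period). For each candidate latency the coefficients are
estimated by robust (Huber) least squares over the unmasked eye-velocity
samples pooled across all trials of one condition; the latency with the
smallest squared residual wins, ties going to the smallest latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .synthetic_data import Trial

DEFAULT_LATENCY_GRID = np.round(np.arange(0.010, 0.0801, 0.002), 6)

#: Huber tuning constant, the conventional 95%-efficiency choice
HUBER_TUNING = 1.345


@dataclass
class LinearFitResult:
    g_v: float  # (deg/s) per (cm/s)
    g_a: float  # (deg/s) per (cm/s^2)
    delta_t: float  # s
    residual_ss: float  # (deg/s)^2
    n_samples: int
    meta: dict = field(default_factory=dict)


def robust_regress(
    design: np.ndarray,
    response: np.ndarray,
    tuning: float = HUBER_TUNING,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Iteratively reweighted least squares with a Huber loss.

    Backed by statsmodels' RLM. An exact (zero-residual) fit short-circuits
    to the ordinary least-squares solution, since the robust scale estimate
    degenerates there.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix in robust regression")
    beta, *_ = np.linalg.lstsq(design, response, rcond=None)
    resid = response - design @ beta
    scale_ref = max(float(np.abs(response).max(initial=0.0)), 1.0)
    if np.abs(resid).max(initial=0.0) <= 1e-10 * scale_ref:
        return beta
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = sm.RLM(response, design, M=sm.robust.norms.HuberT(t=tuning))
    with warnings.catch_warnings():
        # a majority-exact fit drives the MAD scale to zero; the coefficient
        # estimate is still the one we want
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        fit = model.fit(conv="coefs", tol=tol, maxiter=max_iter)
    return np.asarray(fit.params)


def _delayed_regressors(trial: Trial, delta_t: float) -> tuple[np.ndarray, np.ndarray]:
    """Chair velocity/acceleration at (t - delta_t), sampled on the eye grid."""
    te = trial.eye.time
    tc = trial.chair.time
    v = np.interp(te - delta_t, tc, trial.chair.velocity, left=0.0)
    a = np.interp(te - delta_t, tc, trial.chair.acceleration, left=0.0)
    return v, a


def fit_linear_model(
    trials: list[Trial],
    latency_grid: np.ndarray | None = None,
    regressors: str = "both",
    **regress_kwargs,
) -> LinearFitResult:
    """Fit the delayed linear combination over a pooled set of trials.

    ``regressors`` may be 'both' (the model), or 'velocity' / 'acceleration'
    for the single-term control fits. All trials must share condition
    metadata (they are one pooled regression).
    """
    if not trials:
        raise ValueError("at least one trial is required")
    if latency_grid is None:
        latency_grid = DEFAULT_LATENCY_GRID
    latency_grid = np.asarray(latency_grid, dtype=float)
    keys = ("animal", "eye", "direction", "distance", "target", "epoch")
    ref = {k: trials[0].meta.get(k) for k in keys}
    for trial in trials[1:]:
        if {k: trial.meta.get(k) for k in keys} != ref:
            raise ValueError("all trials in one fit must share condition metadata")

    n_params = 2 if regressors == "both" else 1
    best = None
    for delta_t in latency_grid:
        cols_v, cols_a, ys = [], [], []
        for trial in trials:
            v, a = _delayed_regressors(trial, delta_t)
            keep = ~trial.eye.mask
            cols_v.append(v[keep])
            cols_a.append(a[keep])
            ys.append(trial.eye.velocity[keep])
        v = np.concatenate(cols_v)
        a = np.concatenate(cols_a)
        y = np.concatenate(ys)
        if len(y) < 10 * n_params:
            raise InsufficientDataError(
                f"{len(y)} unmasked samples < {10 * n_params} required"
            )
        if regressors == "both":
            X = np.column_stack([v, a])
        elif regressors == "velocity":
            X = v[:, None]
        elif regressors == "acceleration":
            X = a[:, None]
        else:
            raise ValueError("regressors must be 'both', 'velocity' or 'acceleration'")
        if not y.any() and not X.any():
            beta = np.zeros(X.shape[1])
        else:
            beta = robust_regress(X, y, **regress_kwargs)
        rss = float(np.sum((y - X @ beta) ** 2))
        if best is None or rss < best[0]:
            if regressors == "both":
                g_v, g_a = float(beta[0]), float(beta[1])
            elif regressors == "velocity":
                g_v, g_a = float(beta[0]), 0.0
            else:
                g_v, g_a = 0.0, float(beta[0])
            best = (rss, LinearFitResult(g_v, g_a, float(delta_t), rss, len(y), meta=dict(ref)))
    return best[1]


@dataclass
class EpochComparison:
    """Post/pre parameter ratios per condition, with a t-test of ratio = 1."""

    table: pd.DataFrame
    summary: dict


def _condition_key(meta: dict) -> tuple:
    return tuple(meta.get(k) for k in ("animal", "eye", "direction", "distance", "target"))


def compare_epochs(pre: list[LinearFitResult], post: list[LinearFitResult]) -> EpochComparison:
    """Per-condition post/pre ratios of g_v and g_a, averaged across conditions.

    The conditions (animal x eye x direction x distance x target) must match
    one-to-one between epochs. The summary reports the mean ratio and a
    one-sample t-test against ratio = 1 for each coefficient.
    """
    pre_by = {_condition_key(r.meta): r for r in pre}
    post_by = {_condition_key(r.meta): r for r in post}
    if set(pre_by) != set(post_by) or len(pre_by) != len(pre) or len(post_by) != len(post):
        raise ValueError("pre/post condition lists must match one-to-one")
    rows = []
    for key in sorted(pre_by, key=str):
        p, q = pre_by[key], post_by[key]
        rows.append(
            {
                "condition": key,
                "gv_ratio": q.g_v / p.g_v if p.g_v != 0 else np.nan,
                "ga_ratio": q.g_a / p.g_a if p.g_a != 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    summary = {}
    for name, col in (("g_v", "gv_ratio"), ("g_a", "ga_ratio")):
        ratios = table[col].dropna().to_numpy()
        mean = float(np.mean(ratios)) if ratios.size else np.nan
        if ratios.size > 1 and np.ptp(ratios) > 0:
            t, p_val = stats.ttest_1samp(ratios, 1.0)
        elif ratios.size >= 1 and np.ptp(ratios) == 0:
            t, p_val = (0.0, 1.0) if ratios[0] == 1.0 else (np.inf, 0.0)
        else:
            t, p_val = np.nan, np.nan
        summary[name] = {"mean_ratio": mean, "t": float(t), "p": float(p_val)}
    return EpochComparison(table, summary)
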