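"""Sensitivity of the dynamic model to fractional parameter variation.

Each parameter is varied as a fractional change f in [-1, 1]: gains scale to
(1 + f) times the baseline (f = -1 sets the parameter to zero, f = +1 doubles
it); the delay, which is bounded rather than scaled, is varied additively
from the baseline toward its bounds. Three metrics are reported against the
baseline (fitted) parameter set for a standard translation step:

* peak_velocity_ratio — peak |simulated eye velocity| / baseline peak;
* final_position_ratio — simulated eye position at the end of the trace
  (after the motion has stopped) / baseline value;
* error_percent_of_baseline — the fitting error function (summed squared
  velocity residual against the reference trials), as a percent of baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamic_model import DELAY_MAX, ModelParameters, simulate_tvor
from .model_fit import error_vector
from .synthetic_data import Trial

#: sensitivity-analysis symbols -> dynamic-model parameter names
PARAMETER_MAP = {"g_a": "g_acc", "g_v": "g_i", "delay": "tau_delay"}

METRICS = ("peak_velocity_ratio", "final_position_ratio", "error_percent_of_baseline")


@dataclass
class SensitivitySweep:
    parameter: str
    fractions: np.ndarray
    metric: str
    values: np.ndarray


@dataclass
class ErrorSurface:
    ga_fractions: np.ndarray
    gv_fractions: np.ndarray
    error_percent: np.ndarray  # shape (len(ga), len(gv))
    baseline_is_minimum: bool


def _vary(base: ModelParameters, parameter: str, f: float) -> ModelParameters:
    name = PARAMETER_MAP[parameter]
    if parameter == "delay":
        tau = base.tau_delay
        new = tau * (1 + f) if f < 0 else tau + f * (DELAY_MAX - tau)
        return base.replace(tau_delay=float(np.clip(new, 0.0, DELAY_MAX)))
    return base.replace(**{name: getattr(base, name) * (1.0 + f)})


def _response_metrics(params: ModelParameters, trial: Trial) -> tuple[float, float]:
    sim = simulate_tvor(params, trial.chair, dt=trial.eye.dt)
    return float(np.abs(sim.eye_velocity).max()), float(sim.eye_position[-1])


def _error_ss(params: ModelParameters, trials: list[Trial]) -> float:
    return float(np.sum(error_vector(params, trials) ** 2))


def _error_percent(err: float, err0: float) -> float:
    if err0 == 0.0:
        return 100.0 if err == 0.0 else np.inf
    return 100.0 * err / err0


def sweep_1d(
    base_params: ModelParameters,
    parameter: str,
    fractions,
    trials: list[Trial],
) -> list[SensitivitySweep]:
    """1-D fractional sweep of one parameter; returns one sweep per metric.

    The response metrics use the first trial's chair trajectory as the
    standard translation step; the error metric uses the full trial series.
    """
    if parameter not in PARAMETER_MAP:
        raise ValueError(f"parameter must be one of {sorted(PARAMETER_MAP)}")
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < -1) or np.any(fractions > 1):
        raise ValueError("fractional changes must lie in [-1, 1]")
    if not trials:
        raise ValueError("at least one trial is required")

    peak0, fin0 = _response_metrics(base_params, trials[0])
    err0 = _error_ss(base_params, trials)

    peaks, finals, errors = [], [], []
    for f in fractions:
        if f == 0.0:
            peaks.append(1.0)
            finals.append(1.0)
            errors.append(100.0)
            continue
        p = _vary(base_params, parameter, float(f))
        peak, fin = _response_metrics(p, trials[0])
        peaks.append(peak / peak0 if peak0 != 0 else np.nan)
        finals.append(fin / fin0 if fin0 != 0 else np.nan)
        errors.append(_error_percent(_error_ss(p, trials), err0))

    return [
        SensitivitySweep(parameter, fractions, "peak_velocity_ratio", np.asarray(peaks)),
        SensitivitySweep(parameter, fractions, "final_position_ratio", np.asarray(finals)),
        SensitivitySweep(parameter, fractions, "error_percent_of_baseline", np.asarray(errors)),
    ]


def sweep_2d(
    base_params: ModelParameters,
    ga_fractions,
    gv_fractions,
    trials: list[Trial],
) -> ErrorSurface:
    """Error surface under simultaneous fractional variation of g_a and g_v."""
    ga = np.asarray(ga_fractions, dtype=float)
    gv = np.asarray(gv_fractions, dtype=float)
    if ga.size == 0 or gv.size == 0:
        raise ValueError("fraction grids must be non-empty")
    for arr in (ga, gv):
        if np.any(arr < -1) or np.any(arr > 1):
            raise ValueError("fractional changes must lie in [-1, 1]")
    if not trials:
        raise ValueError("at least one trial is required")

    err0 = _error_ss(base_params, trials)
    surface = np.empty((ga.size, gv.size))
    for i, fa in enumerate(ga):
        for j, fv in enumerate(gv):
            if fa == 0.0 and fv == 0.0:
                surface[i, j] = 100.0
                continue
            p = base_params.replace(
                g_acc=base_params.g_acc * (1.0 + fa), g_i=base_params.g_i * (1.0 + fv)
            )
            surface[i, j] = _error_percent(_error_ss(p, trials), err0)

    i0 = np.flatnonzero(ga == 0.0)
    j0 = np.flatnonzero(gv == 0.0)
    if i0.size and j0.size:
        baseline_is_min = bool(surface[i0[0], j0[0]] <= surface.min() + 1e-12)
    else:
        baseline_is_min = False
    return ErrorSurface(ga, gv, surface, baseline_is_min)
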