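"""Previously published tVOR architectures and the comparative simulations.

Three single-integration architectures are implemented alongside the
double-integration model this package proposes:

* ``telford`` — Telford/Paige lineage: a leaky tVOR integrator (0.25 s) in
  series with a high-pass stage (0.05 s) and the common velocity-to-position
  neural integrator; no plant dynamics.
* ``green_galiana`` — Green & Galiana lineage: a single central leaky
  integrator (same 0.25 s dynamics) driving a first-order ocular plant
  (0.27 s).
* ``angelaki`` — Angelaki lineage: as ``green_galiana`` with first-order
  otolith-afferent lead-lag dynamics in front; the semicircular-canal input
  of the published model is omitted since only pure translation is simulated.
* ``proposed`` — the package's own dynamic model with its defaults.

The internal constants of the prior models live in their original papers;
the values here are declared defaults, and every comparative property is
robust to moderate (±20%) variation of them. Outputs are scaled to a common
peak eye velocity and all models share the proposed model's fitted delay
(31 ms), so that only the dynamics differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _lti
from ._lti import TF
from .chair_kinematics import RAD2DEG, ChairTrajectory, resample_trajectory
from .dynamic_model import (
    DEFAULT_FIRST_ORDER_PLANT,
    DEFAULT_THIRD_ORDER_PLANT,
    ModelParameters,
    SimulationResult,
    position_tf,
)

MODEL_IDS = ("telford", "green_galiana", "angelaki", "proposed")

PRIOR_MODEL_DEFAULTS: dict[str, dict[str, float]] = {
    # Telford et al. / Paige: leaky tVOR integrator + high-pass + NI, no plant
    "telford": {"tvor_tc": 0.25, "highpass_tc": 0.05, "ni_tc": 20.0},
    # Green & Galiana: central leaky integrator + first-order plant
    "green_galiana": {"central_tc": 0.25, "plant_tc": 0.27},
    # Angelaki et al.: Green/Galiana chain behind otolith-afferent lead-lag
    "angelaki": {
        "central_tc": 0.25,
        "plant_tc": 0.27,
        "otolith_t_lead": 0.04,
        "otolith_t_lag": 0.01,
    },
}


@dataclass
class PriorModelSpec:
    model_id: str
    constants: dict[str, float] = field(default_factory=dict)
    scale: float = 1.0
    delay: float = 0.031  # s, matched to the proposed model's fitted delay
    distance: float = 70.0  # cm, geometry stage

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}; choose from {MODEL_IDS}")
        merged = dict(PRIOR_MODEL_DEFAULTS.get(self.model_id, {}))
        merged.update(self.constants)
        self.constants = merged


def prior_position_tf(spec: PriorModelSpec, plant_order: str | None = None) -> TF:
    """Acceleration -> eye position transfer function for the architecture.

    ``plant_order`` ('first'/'third') overrides the plant for the
    plant-substitution comparison; it applies to the Green/Galiana and
    Angelaki architectures.
    """
    c = spec.constants
    geom = _lti.gain(RAD2DEG / spec.distance)

    def plant_block(default_tc: float) -> TF:
        if plant_order is None:
            return _lti.tf([1.0], [default_tc, 1.0])
        tcs = (
            DEFAULT_FIRST_ORDER_PLANT if plant_order == "first" else DEFAULT_THIRD_ORDER_PLANT
        )
        block = _lti.tf([1.0], [1.0])
        for tc in tcs:
            block = _lti.series(block, _lti.tf([1.0], [tc, 1.0]))
        return block

    if spec.model_id == "telford":
        leaky = _lti.tf([1.0], [1.0, 1.0 / c["tvor_tc"]])
        highpass = _lti.tf([c["highpass_tc"], 0.0], [c["highpass_tc"], 1.0])
        ni = _lti.tf([1.0], [1.0, 1.0 / c["ni_tc"]])
        return _lti.series(leaky, highpass, geom, ni)
    if spec.model_id == "green_galiana":
        central = _lti.tf([1.0], [1.0, 1.0 / c["central_tc"]])
        return _lti.series(central, geom, plant_block(c["plant_tc"]))
    if spec.model_id == "angelaki":
        central = _lti.tf([1.0], [1.0, 1.0 / c["central_tc"]])
        lead = c["otolith_t_lead"]
        lag = c["otolith_t_lag"]
        otolith = _lti.tf([lead, 1.0], [lag, 1.0])
        return _lti.series(otolith, central, geom, plant_block(c["plant_tc"]))
    # proposed
    params = ModelParameters(tau_delay=spec.delay, distance=spec.distance)
    if plant_order is not None:
        params = params.replace(plant_order=plant_order, plant_tcs=None)
    return position_tf(params)


def simulate_prior(
    spec: PriorModelSpec,
    traj: ChairTrajectory,
    duration: float | None = None,
    dt: float = 0.001,
    plant_order: str | None = None,
) -> SimulationResult:
    """Simulate a prior architecture on a chair trajectory (LTI, ZOH at 1 ms)."""
    rs = resample_trajectory(traj, dt) if abs(traj.dt - dt) > 1e-12 else traj
    t, a = rs.time, rs.acceleration
    if duration is not None:
        keep = t - t[0] <= duration + 1e-12
        t, a = t[keep], a[keep]
    pos = _lti.simulate(prior_position_tf(spec, plant_order=plant_order), a, dt)
    pos = spec.scale * _lti.delay_shift(pos, t, spec.delay)
    vel = np.gradient(pos, dt)
    return SimulationResult(t, pos, vel)


def plant_substitution(
    spec: PriorModelSpec, traj: ChairTrajectory, dt: float = 0.001
) -> tuple[SimulationResult, SimulationResult]:
    """Same architecture with the first-order vs the third-order plant."""
    if spec.model_id not in ("green_galiana", "angelaki"):
        raise ValueError("plant substitution applies to 'green_galiana' or 'angelaki'")
    first = simulate_prior(spec, traj, dt=dt, plant_order="first")
    third = simulate_prior(spec, traj, dt=dt, plant_order="third")
    return first, third


def _motion_end_time(traj: ChairTrajectory, threshold: float = 1e-9) -> float:
    moving = np.flatnonzero(np.abs(traj.velocity) > threshold)
    if moving.size == 0:
        raise ValueError("trajectory contains no motion")
    return float(traj.time[moving[-1]])


def step_comparison(
    specs: list[PriorModelSpec],
    traj: ChairTrajectory,
    dt: float = 0.001,
    lookahead: float = 1.2,
) -> pd.DataFrame:
    """Step-response comparison table across models.

    All outputs are scaled to the same peak eye velocity (the proposed
    model's peak if present, otherwise the first model's). The trajectory
    must extend at least ``lookahead`` seconds beyond motion end. When both
    the Telford and Green/Galiana architectures are included, the table's
    ``attrs['telford_gg_rms_frac']`` holds their RMS velocity-trace
    difference as a fraction of the common peak.
    """
    if len(specs) < 1:
        raise ValueError("at least one model spec is required")
    t_end = _motion_end_time(traj)
    if traj.time[-1] < t_end + lookahead - 1e-9:
        raise ValueError(
            f"trajectory must extend >= {lookahead} s beyond motion end for the comparison"
        )

    results = {s.model_id: simulate_prior(s, traj, dt=dt) for s in specs}
    ref_id = "proposed" if "proposed" in results else specs[0].model_id
    ref_peak = float(np.abs(results[ref_id].eye_velocity).max())

    # end of the constant-speed plateau: last sample at (essentially) peak speed;
    # the sustained response there is not confounded by the anti-compensatory
    # deceleration transient that dominates the traces at motion end
    speed = np.abs(traj.velocity)
    at_peak = np.flatnonzero(speed >= 0.999 * speed.max())
    t_plateau = float(traj.time[at_peak[-1]]) if at_peak.size else t_end

    rows = []
    scaled = {}
    for s in specs:
        r = results[s.model_id]
        peak = float(np.abs(r.eye_velocity).max())
        k = ref_peak / peak if peak > 0 else 1.0
        vel = k * r.eye_velocity
        pos = k * r.eye_position
        scaled[s.model_id] = vel
        i_end = int(np.searchsorted(r.time, t_end))
        i_plateau = int(np.searchsorted(r.time, t_plateau))
        i_late = int(np.searchsorted(r.time, t_end + lookahead))
        i_late = min(i_late, len(r.time) - 1)
        rows.append(
            {
                "model": s.model_id,
                "scale": k * s.scale,
                "peak_velocity": float(np.abs(vel).max()),
                "velocity_at_plateau_end": float(vel[i_plateau]),
                "velocity_at_motion_end": float(vel[i_end]),
                "position_at_motion_end": float(pos[i_end]),
                "position_at_plus_lookahead": float(pos[i_late]),
            }
        )
    table = pd.DataFrame(rows)
    if {"telford", "green_galiana"} <= set(scaled):
        diff = scaled["telford"] - scaled["green_galiana"]
        table.attrs["telford_gg_rms_frac"] = float(
            np.sqrt(np.mean(diff**2)) / ref_peak
        )
    return table
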