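"""The block-diagram tVOR model: otolith dynamics feeding a direct
acceleration pathway in parallel with an acceleration-to-velocity integrator,
a transmission delay, a linear-to-angular geometry stage, the common
velocity-to-position neural integrator (NI), and the ocular plant.

Signal path (input = linear head acceleration, cm/s^2)::

    a_h -> O(s) -> [ G_acc  +  G_i * I(s) ] -> delay tau -> geometry (1/D)
        -> NI 1/(s + 1/T_ni) -> plant P(s) -> eye position E_H (deg)

where I(s) is the tVOR integrator, a pure integrator 1/s by default or a
leaky one 1/(s + 1/T) when ``tvor_integrator_tc`` is finite. Eye velocity is
reported as the time derivative of eye position. All blocks are LTI; the
chain is composed symbolically and discretized once (zero-order hold, 1 ms
default step), with the delay applied as a fractional-sample shift of the
output so that objective functions remain smooth in the delay.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _lti
from ._lti import TF
from .chair_kinematics import RAD2DEG, ChairTrajectory, resample_trajectory

#: third-order ocular plant time constants (s); unity DC gain low-pass
DEFAULT_THIRD_ORDER_PLANT = (0.224, 0.013, 0.004)
#: first-order plant time constant (s), as used by earlier single-integrator models
DEFAULT_FIRST_ORDER_PLANT = (0.25,)

DELAY_MAX = 0.075  # s; upper bound on the transmission delay


@dataclass
class ModelParameters:
    """Full parameter set of the dynamic tVOR model.

    The free parameters of the data fit are ``g_i`` (integrator-pathway gain,
    dimensionless), ``g_acc`` (direct-pathway gain, units of s since it maps
    cm/s^2 to a cm/s command) and ``tau_delay`` (s, bounded [0, 0.075]).
    Everything else is fixed configuration: otolith lead-lag constants
    (identity/pure-gain by default), NI time constant (20 s), plant order and
    time constants, and the perpendicular target distance D (cm) of the
    geometry stage.
    """

    g_i: float = 0.5
    g_acc: float = 0.15
    tau_delay: float = 0.031
    tvor_integrator_tc: float | None = None  # None = pure integrator
    ni_tc: float = 20.0
    otolith_gain: float = 1.0
    otolith_t_lead: float = 0.01
    otolith_t_lag: float = 0.01
    plant_order: str = "third"
    plant_tcs: tuple[float, ...] | None = None
    distance: float = 70.0
    exact_geometry: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.g_i < 0 or self.g_acc < 0:
            raise ValueError("gains g_i and g_acc must be non-negative")
        if not 0.0 <= self.tau_delay <= DELAY_MAX:
            raise ValueError(f"tau_delay must lie in [0, {DELAY_MAX}] s")
        if self.tvor_integrator_tc is not None and self.tvor_integrator_tc <= 0:
            raise ValueError("tvor_integrator_tc must be positive (or None for pure)")
        for name in ("ni_tc", "otolith_t_lead", "otolith_t_lag", "distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.plant_order not in ("first", "third"):
            raise ValueError("plant_order must be 'first' or 'third'")
        n_expected = 1 if self.plant_order == "first" else 3
        if self.plant_tcs is not None:
            if len(self.plant_tcs) != n_expected:
                raise ValueError(
                    f"{self.plant_order}-order plant needs {n_expected} time constants"
                )
            if any(tc <= 0 for tc in self.plant_tcs):
                raise ValueError("plant time constants must be strictly positive")

    def effective_plant_tcs(self) -> tuple[float, ...]:
        if self.plant_tcs is not None:
            return tuple(self.plant_tcs)
        return (
            DEFAULT_FIRST_ORDER_PLANT
            if self.plant_order == "first"
            else DEFAULT_THIRD_ORDER_PLANT
        )

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulationResult:
    """Simulated eye movement plus diagnostic intermediate signals."""

    time: np.ndarray
    eye_position: np.ndarray  # deg
    eye_velocity: np.ndarray  # deg/s
    otolith_output: np.ndarray = field(default=None, repr=False)  # cm/s^2
    integrator_output: np.ndarray = field(default=None, repr=False)  # cm/s

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def otolith_tf(params: ModelParameters) -> TF:
    """First-order lead-lag otolith block k(1 + T_lead s)/(1 + T_lag s).

    With T_lead == T_lag (the default) the block is a pure gain, which is the
    reference configuration used throughout the tests.
    """
    params.validate()
    k = params.otolith_gain
    return _lti.tf([k * params.otolith_t_lead, k], [params.otolith_t_lag, 1.0])


def plant_tf(params: ModelParameters) -> TF:
    """Unity-DC-gain low-pass ocular plant of the configured order."""
    params.validate()
    block = _lti.tf([1.0], [1.0])
    for tc in params.effective_plant_tcs():
        block = _lti.series(block, _lti.tf([1.0], [tc, 1.0]))
    return block


def ni_tf(params: ModelParameters) -> TF:
    """Velocity-to-position neural integrator 1/(s + 1/T_ni)."""
    return _lti.tf([1.0], [1.0, 1.0 / params.ni_tc])


def tvor_integrator_tf(params: ModelParameters) -> TF:
    """Acceleration-to-velocity tVOR integrator: 1/s, or leaky 1/(s + 1/T)."""
    if params.tvor_integrator_tc is None:
        return _lti.tf([1.0], [1.0, 0.0])
    return _lti.tf([1.0], [1.0, 1.0 / params.tvor_integrator_tc])


def command_tf(params: ModelParameters) -> TF:
    """Acceleration -> commanded linear eye velocity (cm/s), before delay/geometry."""
    branches = _lti.parallel(
        _lti.gain(params.g_acc),
        _lti.series(_lti.gain(params.g_i), tvor_integrator_tf(params)),
    )
    return _lti.series(otolith_tf(params), branches)


def position_tf(params: ModelParameters) -> TF:
    """Full acceleration -> eye position (deg) transfer function, excluding the delay."""
    geom = _lti.gain(RAD2DEG / params.distance)
    return _lti.series(command_tf(params), geom, ni_tf(params), plant_tf(params))


def simulate_tvor(
    params: ModelParameters,
    traj: ChairTrajectory,
    duration: float | None = None,
    dt: float = 0.001,
) -> SimulationResult:
    """Simulate the model's response to a chair trajectory.

    The trajectory is resampled to the simulation step (1 ms default, linear
    interpolation); the delay is applied to the outputs as a fractional-sample
    shift, which is exactly equivalent for an at-rest LTI chain.
    """
    params.validate()
    if duration is not None:
        if duration - params.tau_delay > traj.duration + 1e-12:
            raise ValueError("trajectory must cover [0, duration - tau_delay]")
    rs = resample_trajectory(traj, dt) if abs(traj.dt - dt) > 1e-12 else traj
    t, a = rs.time, rs.acceleration
    if duration is not None:
        keep = t - t[0] <= duration + 1e-12
        t, a = t[keep], a[keep]

    oto = _lti.simulate(otolith_tf(params), a, dt)
    integ = _lti.simulate(
        _lti.series(otolith_tf(params), _lti.gain(params.g_i), tvor_integrator_tf(params)),
        a,
        dt,
    )

    if params.exact_geometry:
        # time-varying geometry: commanded linear velocity scaled by
        # d/(d^2 + x^2) instead of 1/d; breaks the single-chain composition
        cmd = _lti.simulate(command_tf(params), a, dt)
        cmd = _lti.delay_shift(cmd, t, params.tau_delay)
        x = _lti.delay_shift(np.interp(t, traj.time, traj.position), t, params.tau_delay)
        omega_cmd = RAD2DEG * cmd * params.distance / (params.distance**2 + x**2)
        pos = _lti.simulate(_lti.series(ni_tf(params), plant_tf(params)), omega_cmd, dt)
    else:
        pos = _lti.simulate(position_tf(params), a, dt)
        pos = _lti.delay_shift(pos, t, params.tau_delay)

    vel = np.gradient(pos, dt)
    oto = _lti.delay_shift(oto, t, params.tau_delay)
    integ = _lti.delay_shift(integ, t, params.tau_delay)
    return SimulationResult(t, pos, vel, otolith_output=oto, integrator_output=integ)


def analytic_frequency_response(
    params: ModelParameters, freqs, reference: str = "velocity"
) -> np.ndarray:
    """Closed-form eye-velocity frequency response at s = j*2*pi*f.

    ``reference`` selects the input the gain/phase are taken relative to:
    head velocity ('velocity') or head acceleration ('acceleration'). The
    transmission delay contributes a phase factor exp(-j*omega*tau).
    """
    freqs = np.asarray(freqs, dtype=float)
    s = 2j * np.pi * freqs
    h_pos = _lti.freq_response(position_tf(params), freqs)  # accel -> position
    h_vel = s * h_pos  # accel -> eye velocity
    h_vel = h_vel * np.exp(-s * params.tau_delay)
    if reference == "velocity":
        return h_vel * s  # head velocity -> accel is multiplication by s
    if reference == "acceleration":
        return h_vel
    raise ValueError("reference must be 'velocity' or 'acceleration'")


def frequency_response(
    params: ModelParameters,
    freqs,
    amplitude: float = 10.0,
    reference: str = "velocity",
    normalize_1hz: bool = False,
    dt: float = 0.001,
    min_cycles: int = 5,
) -> "pandas.DataFrame":
    """Measure the model's gain and phase by simulating sinusoidal translation.

    For each frequency a sinusoidal head velocity (amplitude cm/s, starting at
    zero) drives the model; after discarding a settle window of at least seven
    slowest-pole decay times, a sine+cosine (plus constant) least-squares fit
    at the known frequency yields the steady-state amplitude and phase of the
    simulated eye velocity. Gains are amplitude ratios relative to the chosen
    reference signal; ``normalize_1hz`` rescales gains so the gain at 1 Hz is
    exactly 1 (1 Hz must then be among the frequencies).
    """
    import pandas as pd

    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    params.validate()

    settle = 7.0 * _lti.slowest_decay_time(position_tf(params)) + params.tau_delay
    rows = []
    for f in freqs:
        omega = 2 * np.pi * f
        n_cyc = max(min_cycles, 1)
        t_total = settle + n_cyc / f
        t = np.arange(0.0, t_total, dt)
        accel = amplitude * omega * np.cos(omega * t)
        traj = ChairTrajectory(
            t,
            (amplitude / omega) * (1 - np.cos(omega * t)),
            amplitude * np.sin(omega * t),
            accel,
        )
        res = simulate_tvor(params, traj, dt=dt)
        win = res.time >= settle
        tw = res.time[win]
        yw = res.eye_velocity[win]
        design = np.column_stack([np.sin(omega * tw), np.cos(omega * tw), np.ones_like(tw)])
        (a, b, _), *_ = np.linalg.lstsq(design, yw, rcond=None)
        amp_out = float(np.hypot(a, b))
        phase_out = float(np.arctan2(b, a))  # relative to sin(omega t)
        if reference == "velocity":
            amp_ref, phase_ref = amplitude, 0.0
        elif reference == "acceleration":
            amp_ref, phase_ref = amplitude * omega, np.pi / 2
        else:
            raise ValueError("reference must be 'velocity' or 'acceleration'")
        phase = np.degrees(
            np.angle(np.exp(1j * (phase_out - phase_ref)))
        )  # wrapped to (-180, 180]
        rows.append({"freq": f, "gain": amp_out / amp_ref, "phase_deg": phase})

    table = pd.DataFrame(rows)
    if normalize_1hz:
        at_1 = np.isclose(table["freq"], 1.0)
        if not at_1.any():
            raise ValueError("normalize_1hz requires 1.0 Hz among the frequencies")
        table["gain"] = table["gain"] / float(table.loc[at_1, "gain"].iloc[0])
    return table
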