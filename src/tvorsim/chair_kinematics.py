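"""Chair motion stimulus and ideal (geometric) eye velocity.

The sled protocol is a trapezoidal velocity profile along the interaural
axis: constant acceleration up to a peak speed, a constant-speed plateau, and
constant deceleration to rest. Internal units are cm, s and deg; printed
g-units are converted with standard gravity. Sign convention follows the
right-hand rule: leftward position and velocity are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: standard gravity in cm/s^2, used to convert protocol g-units
STANDARD_GRAVITY = 980.665

RAD2DEG = 180.0 / np.pi


@dataclass(frozen=True)
class StimulusProtocol:
    """Trapezoidal translation protocol.

    Defaults are the standard step: 0.26 g acceleration to 40 cm/s, 320 ms at
    constant speed, 0.20 g deceleration, ~20 cm total displacement.
    """

    a_accel: float = 0.26  # g-units
    v_peak: float = 40.0  # cm/s
    t_const: float = 0.320  # s
    a_decel: float = 0.20  # g-units
    displacement_nominal: float = 20.0  # cm
    direction: str = "left"

    def __post_init__(self):
        for name in ("a_accel", "v_peak", "t_const", "a_decel", "displacement_nominal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"protocol field {name!r} must be strictly positive")
        if self.direction not in ("left", "right"):
            raise ValueError(f"direction must be 'left' or 'right', got {self.direction!r}")

    @property
    def sign(self) -> float:
        """+1 for leftward motion (right-hand rule), -1 for rightward."""
        return 1.0 if self.direction == "left" else -1.0

    @property
    def t_accel(self) -> float:
        """Duration of the acceleration phase (s)."""
        return self.v_peak / (self.a_accel * STANDARD_GRAVITY)

    @property
    def t_decel(self) -> float:
        """Duration of the deceleration phase (s)."""
        return self.v_peak / (self.a_decel * STANDARD_GRAVITY)

    @property
    def t_motion(self) -> float:
        """Total duration of the motion (s)."""
        return self.t_accel + self.t_const + self.t_decel

    @property
    def displacement(self) -> float:
        """Analytic total displacement of the trapezoid (cm, unsigned)."""
        v, g = self.v_peak, STANDARD_GRAVITY
        return v * v / (2 * self.a_accel * g) + v * self.t_const + v * v / (2 * self.a_decel * g)


@dataclass
class ChairTrajectory:
    """Sampled linear chair motion along the interaural axis (cm, cm/s, cm/s^2)."""

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    protocol: StimulusProtocol | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.time)
        if not (len(self.position) == len(self.velocity) == len(self.acceleration) == n):
            raise ValueError("trajectory arrays must have equal length")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def make_trapezoid_profile(
    protocol: StimulusProtocol,
    dt: float = 0.002,
    pad_before: float = 0.0,
    pad_after: float = 0.0,
) -> ChairTrajectory:
    """Sample the trapezoidal velocity profile on a uniform grid.

    Motion onset is at ``t = pad_before``. Velocity and acceleration are
    evaluated from the piecewise-analytic profile; position is obtained by
    trapezoidal integration of the sampled velocity, so integrating the
    generated velocity recovers the generated position identically and the
    total displacement matches the protocol to within one sample's travel.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    g = STANDARD_GRAVITY
    a1 = protocol.a_accel * g
    a2 = protocol.a_decel * g
    vp = protocol.v_peak
    t1 = protocol.t_accel
    t2 = t1 + protocol.t_const
    t3 = protocol.t_motion

    total = pad_before + t3 + pad_after
    t = np.arange(0.0, total + 0.5 * dt, dt)
    u = t - pad_before  # time since motion onset

    vel = np.zeros_like(t)
    acc = np.zeros_like(t)

    ph1 = (u >= 0) & (u < t1)
    ph2 = (u >= t1) & (u < t2)
    ph3 = (u >= t2) & (u < t3)

    vel[ph1] = a1 * u[ph1]
    acc[ph1] = a1
    vel[ph2] = vp
    ud = u[ph3] - t2
    vel[ph3] = vp - a2 * ud
    acc[ph3] = -a2

    from scipy.integrate import cumulative_trapezoid

    pos = cumulative_trapezoid(vel, t, initial=0.0)

    s = protocol.sign
    return ChairTrajectory(t, s * pos, s * vel, s * acc, protocol=protocol)


def ideal_eye_velocity(traj: ChairTrajectory, d: float) -> np.ndarray:
    """Eye angular velocity (deg/s) that keeps gaze on a target at distance ``d`` cm.

    This is the time derivative of the gaze angle atan(x_h/d):
    omega = d * xdot_h / (d^2 + x_h^2), converted from rad/s to deg/s.
    """
    if d <= 0:
        raise ValueError("target distance d must be strictly positive")
    return RAD2DEG * d * traj.velocity / (d**2 + traj.position**2)


def resample_trajectory(traj: ChairTrajectory, dt: float) -> ChairTrajectory:
    """Linearly interpolate a trajectory onto a new uniform grid."""
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    t = np.arange(traj.time[0], traj.time[-1] + 0.5 * dt, dt)
    return ChairTrajectory(
        t,
        np.interp(t, traj.time, traj.position),
        np.interp(t, traj.time, traj.velocity),
        np.interp(t, traj.time, traj.acceleration),
        protocol=traj.protocol,
    )
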