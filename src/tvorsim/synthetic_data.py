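"""Synthetic trial generation.

Stands in for binocular scleral-coil recordings during interaural translation
steps: the slow-phase component comes from the forward dynamic model, to which
band-limited Gaussian velocity noise and injected quick phases (brief
raised-cosine velocity pulses) are added. Ground truth (generating parameters
and quick-phase windows) travels with each trial so that recovery can be
tested. Everything is deterministic given the seed.

The generator emulates the statistical structure the analysis pipeline
assumes, not the physiology of noise: quick-phase amplitudes are chosen so
that their peak accelerations comfortably exceed the detection thresholds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .chair_kinematics import ChairTrajectory, StimulusProtocol, make_trapezoid_profile
from .dynamic_model import ModelParameters, simulate_tvor


@dataclass
class EyeTrace:
    """Horizontal eye movement of one eye, sampled at 1000 Hz by default."""

    time: np.ndarray  # s
    position: np.ndarray  # deg
    velocity: np.ndarray  # deg/s
    mask: np.ndarray  # bool, True = excluded (quick phase / saccade)

    def __post_init__(self):
        if not (len(self.time) == len(self.position) == len(self.velocity) == len(self.mask)):
            raise ValueError("eye trace arrays must have equal length")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class Trial:
    """One translation step: chair trajectory, eye trace, condition metadata."""

    chair: ChairTrajectory
    eye: EyeTrace
    meta: dict = field(default_factory=dict)
    ground_truth: dict | None = None


@dataclass
class NoiseSpec:
    velocity_noise_sd: float = 2.0  # deg/s, after band-limiting
    noise_bandwidth: float = 50.0  # Hz low-pass corner
    quick_phase_rate: float = 1.0  # per s
    quick_phase_amp_range: tuple[float, float] = (80.0, 250.0)  # deg/s peak
    quick_phase_duration_range: tuple[float, float] = (0.02, 0.04)  # s

    def __post_init__(self):
        if self.velocity_noise_sd < 0 or self.quick_phase_rate < 0:
            raise ValueError("noise sd and quick-phase rate must be non-negative")
        if self.noise_bandwidth <= 0:
            raise ValueError("noise bandwidth must be positive")


def _band_limited_noise(rng, n: int, dt: float, sd: float, bandwidth: float) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = 0.5 / dt
    if bandwidth >= nyq:
        filtered = white
    else:
        sos = signal.butter(4, bandwidth, fs=1.0 / dt, output="sos")
        filtered = signal.sosfiltfilt(sos, white)
    scale = filtered.std()
    return sd * filtered / scale if scale > 0 else filtered


def _raised_cosine_pulse(t: np.ndarray, onset: float, duration: float, peak: float) -> np.ndarray:
    u = (t - onset) / duration
    pulse = np.where((u >= 0) & (u <= 1), 0.5 * peak * (1 - np.cos(2 * np.pi * u)), 0.0)
    return pulse


def generate_trial(
    params: ModelParameters,
    protocol: StimulusProtocol,
    noise: NoiseSpec,
    seed,
    dt: float = 0.001,
    chair_dt: float = 0.002,
    pad_before: float = 0.1,
    pad_after: float = 0.6,
    meta: dict | None = None,
) -> Trial:
    """Generate one synthetic trial.

    The chair signal is sampled at its native period (2 ms default) and the
    eye trace at 1 ms. The eye mask starts all-False; flagging quick phases is
    the preprocessing stage's job. Ground truth stores the generating
    parameters and the injected quick-phase windows.
    """
    rng = np.random.default_rng(seed)
    chair = make_trapezoid_profile(protocol, dt=chair_dt, pad_before=pad_before, pad_after=pad_after)
    sim = simulate_tvor(params, chair, dt=dt)
    t = sim.time
    vel = sim.eye_velocity.copy()

    if noise.velocity_noise_sd > 0:
        vel += _band_limited_noise(rng, len(t), dt, noise.velocity_noise_sd, noise.noise_bandwidth)

    qp_windows: list[tuple[float, float]] = []
    duration = t[-1] - t[0]
    if noise.quick_phase_rate > 0:
        n_qp = int(rng.poisson(noise.quick_phase_rate * duration))
        max_dur = noise.quick_phase_duration_range[1]
        for _ in range(n_qp):
            onset = float(rng.uniform(t[0] + 0.02, t[-1] - max_dur - 0.02))
            dur = float(rng.uniform(*noise.quick_phase_duration_range))
            amp = float(rng.uniform(*noise.quick_phase_amp_range)) * rng.choice([-1.0, 1.0])
            vel += _raised_cosine_pulse(t, onset, dur, amp)
            qp_windows.append((onset, onset + dur))

    pos = cumulative_trapezoid(vel, t, initial=0.0)
    eye = EyeTrace(t, pos, vel, np.zeros(len(t), dtype=bool))
    gt = {
        "params": dataclasses.asdict(params),
        "quick_phase_windows": qp_windows,
        "seed": int(np.random.SeedSequence(seed).entropy) if isinstance(seed, int) else None,
    }
    return Trial(chair, eye, meta=dict(meta or {}), ground_truth=gt)


#: one animal, both viewing distances, dark (target-off) trials
DEFAULT_CONDITIONS = [
    {"animal": "M1", "eye": "L", "distance": 27.0, "target": "off"},
    {"animal": "M1", "eye": "L", "distance": 70.0, "target": "off"},
]


def generate_session(
    pre_params: ModelParameters,
    post_params: ModelParameters,
    n_trials: int = 4,
    conditions: list[dict] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
    **trial_kwargs,
) -> list[Trial]:
    """Generate a pre/post session of alternating-direction trials.

    For every condition and epoch, ``n_trials`` trials are produced with
    leftward/rightward direction alternating, the experimental protocol's
    trial order. ``post_params`` is typically ``pre_params`` with the pathway
    gains scaled down (the lesion surrogate). Per-trial seeds are spawned from
    the session seed, so the session is reproducible and individual trials are
    independent streams.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    conditions = DEFAULT_CONDITIONS if conditions is None else conditions
    if not conditions:
        raise ValueError("condition list must not be empty")
    noise = NoiseSpec() if noise is None else noise
    base_protocol = StimulusProtocol() if protocol is None else protocol

    n_total = len(conditions) * 2 * n_trials
    children = np.random.SeedSequence(seed).spawn(n_total)
    trials: list[Trial] = []
    i = 0
    for cond in conditions:
        for epoch, params in (("pre", pre_params), ("post", post_params)):
            p = params.replace(distance=float(cond.get("distance", params.distance)))
            for k in range(n_trials):
                direction = "left" if k % 2 == 0 else "right"
                proto = dataclasses.replace(base_protocol, direction=direction)
                meta = dict(cond)
                meta.update(epoch=epoch, direction=direction, trial_index=k)
                trials.append(
                    generate_trial(p, proto, noise, children[i], meta=meta, **trial_kwargs)
                )
                i += 1
    return trials


def lesion_surrogate(params: ModelParameters, gi_scale: float = 0.38, gacc_scale: float = 0.87):
    """Post-lesion parameter regime: scale down the two pathway gains.

    The default scalings reproduce the qualitative post-lesion signature:
    strongly reduced sustained (integrated) response with a largely preserved
    early acceleration-driven transient.
    """
    return params.replace(g_i=params.g_i * gi_scale, g_acc=params.g_acc * gacc_scale)
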