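"""Slow-phase extraction, trial synchronization and summary velocity profiles.

Quick phases and saccades are detected on eye velocity with paired threshold
criteria on acceleration (1400 deg/s^2) and jerk (50,000 deg/s^3); both
derivatives are computed by Savitzky-Golay local polynomial differentiation
to avoid amplifying 1 kHz sampling noise, and flagged runs are dilated to
exclude the pre/post-saccadic shoulders the thresholds miss. Trials are
synchronized on the time the chair speed first crosses 1 cm/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.signal import savgol_filter

from .chair_kinematics import ChairTrajectory
from .synthetic_data import EyeTrace, Trial

logger = logging.getLogger(__name__)

ACCEL_THRESHOLD = 1400.0  # deg/s^2
JERK_THRESHOLD = 50_000.0  # deg/s^3

# relative guard so that a derivative exactly at threshold (up to float
# round-off in the filter arithmetic) is NOT flagged: strict inequality
_THRESHOLD_GUARD = 1e-9


def differentiate(x: np.ndarray, dt: float, deriv: int, window: float = 0.035, polyorder: int = 2):
    """Savitzky-Golay derivative of order ``deriv`` (window in seconds)."""
    n_win = int(round(window / dt))
    if n_win % 2 == 0:
        n_win += 1
    if n_win < polyorder + 2:
        n_win = polyorder + 2 + ((polyorder + 1) % 2)
    if len(x) < n_win:
        raise ValueError(f"trace of {len(x)} samples is shorter than the {n_win}-sample window")
    return savgol_filter(x, n_win, polyorder, deriv=deriv, delta=dt)


def detect_fast_phases(
    eye: EyeTrace,
    accel_threshold: float = ACCEL_THRESHOLD,
    jerk_threshold: float = JERK_THRESHOLD,
    dilation: float = 0.010,
    window: float = 0.035,
    polyorder: int = 2,
) -> np.ndarray:
    """Boolean mask of samples belonging to quick phases / saccades.

    A sample is flagged when |acceleration| strictly exceeds
    ``accel_threshold`` or |jerk| strictly exceeds ``jerk_threshold``;
    flagged runs are then dilated by ``dilation`` seconds on each side.
    """
    dt = eye.dt
    accel = differentiate(eye.velocity, dt, 1, window=window, polyorder=polyorder)
    jerk = differentiate(eye.velocity, dt, 2, window=window, polyorder=polyorder)
    mask = (np.abs(accel) > accel_threshold * (1 + _THRESHOLD_GUARD)) | (
        np.abs(jerk) > jerk_threshold * (1 + _THRESHOLD_GUARD)
    )
    n_dilate = int(round(dilation / dt))
    if n_dilate > 0 and mask.any():
        mask = binary_dilation(mask, structure=np.ones(2 * n_dilate + 1, dtype=bool))
    return mask


def mask_trial(trial: Trial, **kwargs) -> Trial:
    """Return a copy of the trial with the fast-phase mask applied."""
    mask = detect_fast_phases(trial.eye, **kwargs)
    eye = EyeTrace(trial.eye.time, trial.eye.position, trial.eye.velocity, trial.eye.mask | mask)
    return Trial(trial.chair, eye, meta=dict(trial.meta), ground_truth=trial.ground_truth)


def synchronize_trials(trials: list[Trial], speed_threshold: float = 1.0) -> list[Trial]:
    """Shift time axes so t = 0 at the first sample with chair speed >= 1 cm/s.

    Trials whose chair speed never crosses the threshold are rejected with a
    logged warning. Already-aligned trials pass through unchanged (idempotent).
    """
    aligned = []
    for i, trial in enumerate(trials):
        speed = np.abs(trial.chair.velocity)
        idx = np.flatnonzero(speed >= speed_threshold)
        if idx.size == 0:
            logger.warning("trial %d rejected: chair speed never reaches %g cm/s", i, speed_threshold)
            continue
        t0 = trial.chair.time[idx[0]]
        if t0 == 0.0:
            aligned.append(trial)
            continue
        chair = ChairTrajectory(
            trial.chair.time - t0,
            trial.chair.position,
            trial.chair.velocity,
            trial.chair.acceleration,
            protocol=trial.chair.protocol,
        )
        eye = EyeTrace(
            trial.eye.time - t0, trial.eye.position, trial.eye.velocity, trial.eye.mask
        )
        aligned.append(Trial(chair, eye, meta=dict(trial.meta), ground_truth=trial.ground_truth))
    return aligned


@dataclass
class VelocityProfile:
    """Per-sample median and interquartile band over unmasked trial samples."""

    time: np.ndarray
    median: np.ndarray
    p25: np.ndarray
    p75: np.ndarray
    n_trials: np.ndarray


def median_velocity_profile(trials: list[Trial], window: float = 0.4) -> VelocityProfile:
    """Median / 25th / 75th percentile eye velocity over synchronized trials.

    Percentiles use linear interpolation between order statistics. A sample
    with zero contributing (unmasked, in-range) trials is reported as NaN.
    """
    if not trials:
        raise ValueError("at least one trial is required")
    dt = trials[0].eye.dt
    grid = np.arange(0.0, window + 0.5 * dt, dt)
    stacked = np.full((len(trials), len(grid)), np.nan)
    for i, trial in enumerate(trials):
        t = trial.eye.time
        idx = np.round((grid - t[0]) / dt).astype(int)
        ok = (idx >= 0) & (idx < len(t))
        sel = idx[ok]
        vals = trial.eye.velocity[sel].astype(float).copy()
        vals[trial.eye.mask[sel]] = np.nan
        stacked[i, ok] = vals
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(stacked, axis=0)
            p25 = np.nanpercentile(stacked, 25, axis=0)
            p75 = np.nanpercentile(stacked, 75, axis=0)
    n = np.sum(~np.isnan(stacked), axis=0)
    return VelocityProfile(grid, med, p25, p75, n)
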