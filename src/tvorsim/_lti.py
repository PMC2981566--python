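"""Minimal continuous-time transfer-function algebra and fixed-step simulation.

Transfer functions are ``(num, den)`` pairs of 1-D float arrays holding
polynomial coefficients in descending powers of *s*, the convention used by
:mod:`scipy.signal`. Blocks are composed symbolically (polynomial products and
sums) and the composed rational function is discretized once with a zero-order
hold for time-domain simulation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

TF = tuple[np.ndarray, np.ndarray]


def tf(num, den) -> TF:
    return np.atleast_1d(np.asarray(num, dtype=float)), np.atleast_1d(
        np.asarray(den, dtype=float)
    )


def gain(k: float) -> TF:
    return tf([k], [1.0])


def series(*tfs: TF) -> TF:
    """Cascade of blocks: product of the rational functions."""
    num, den = tf([1.0], [1.0])
    for n, d in tfs:
        num = np.polymul(num, n)
        den = np.polymul(den, d)
    return num, den


def parallel(tf1: TF, tf2: TF) -> TF:
    """Sum of two parallel branches."""
    n1, d1 = tf1
    n2, d2 = tf2
    num = np.polyadd(np.polymul(n1, d2), np.polymul(n2, d1))
    return num, np.polymul(d1, d2)


def freq_response(tfn: TF, freqs_hz) -> np.ndarray:
    """Evaluate the transfer function at s = j*2*pi*f (complex array)."""
    num, den = tfn
    s = 2j * np.pi * np.asarray(freqs_hz, dtype=float)
    return np.polyval(num, s) / np.polyval(den, s)


def simulate(tfn: TF, u: np.ndarray, dt: float) -> np.ndarray:
    """Simulate the response to input ``u`` sampled at ``dt`` (ZOH discretization).

    The rational function is split into first-order continuous modes
    (partial fractions) and each mode is discretized exactly under the
    zero-order hold; the outputs are summed. Because the hold commutes with a
    parallel sum, this equals the ZOH solution of the full system, but every
    recursion is a well-conditioned scalar one — a single high-order
    direct-form filter loses several digits at low frequency once the
    discrete poles cluster near 1. Marginally stable modes (a pure
    integrator) are handled exactly. Coincident poles are separated by a
    relative 1e-6 perturbation, which is far below the package's numerical
    tolerances.
    """
    num, den = tfn
    u = np.asarray(u, float)
    num = np.trim_zeros(np.atleast_1d(np.asarray(num, float)), "f")
    den = np.trim_zeros(np.atleast_1d(np.asarray(den, float)), "f")
    if len(num) == 0:
        return np.zeros_like(u)
    y = np.zeros(len(u), dtype=complex)
    if len(num) >= len(den):
        if len(num) > len(den):
            raise ValueError("improper transfer function cannot be simulated")
        c = num[0] / den[0]
        num = np.polysub(num, c * den)
        num = np.trim_zeros(np.atleast_1d(num), "f")
        y += c * u
        if len(num) == 0:
            return np.real(y)

    poles = np.roots(den)
    # nudge coincident poles apart so simple-pole residues are defined
    scale = max(1.0, float(np.abs(poles).max(initial=0.0)))
    for i in range(len(poles)):
        for j in range(i):
            if abs(poles[i] - poles[j]) < 1e-6 * scale:
                poles[i] = poles[i] + 1e-6 * scale * (i - j)
    lead = den[0]
    for i, p in enumerate(poles):
        others = np.delete(poles, i)
        r = np.polyval(num, p) / (lead * np.prod(p - others))
        ep = np.exp(p * dt)
        b = r * dt if abs(p) * dt < 1e-12 else r * (ep - 1.0) / p
        # ZOH: y[k+1] = e^{p dt} y[k] + b u[k]  -> numerator carries z^{-1}
        y += signal.lfilter(np.array([0.0, b]), np.array([1.0, -ep]), u.astype(complex))
    return np.real(y)


def slowest_decay_time(tfn: TF) -> float:
    """1/|Re(p)| of the slowest strictly stable pole; 0.0 if none."""
    poles = np.roots(tfn[1])
    rates = -poles.real
    rates = rates[rates > 1e-9]
    if rates.size == 0:
        return 0.0
    return float(1.0 / rates.min())


def delay_shift(y: np.ndarray, t: np.ndarray, tau: float) -> np.ndarray:
    """Delay a sampled signal by ``tau`` seconds via linear interpolation.

    The pre-history is taken as the initial sample value (signals are assumed
    at rest before the record starts). Fractional delays are supported, which
    keeps objective functions smooth in the delay parameter.
    """
    if tau == 0.0:
        return np.asarray(y, float).copy()
    return np.interp(t - tau, t, y, left=float(y[0]))
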