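"""Shared FIR design and two-pass zero-phase filtering helpers.

All band filtering in this package uses linear-phase (symmetric) FIR
kernels applied twice, which yields a zero-phase filter with magnitude
response |H(f)|^2.  Signals are reflect-padded by one kernel length
before filtering so that epoch edges are free of onset transients.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

__all__ = ["fir_order", "design_fir", "two_pass_filter", "analytic_amplitude"]


def fir_order(sampling_rate: float, transition_hz: float, n_samples: int | None = None,
              factor: float = 3.0) -> int:
    """Number of taps for a two-pass FIR given the lower transition edge.

    order = factor * (sampling_rate / transition_hz), forced odd so the
    kernel is symmetric about an integer delay.  When ``n_samples`` is
    given the order is capped so the kernel fits the signal.
    """
    if transition_hz <= 0:
        raise ValueError("transition edge must be positive")
    ntaps = int(round(factor * sampling_rate / transition_hz))
    if n_samples is not None:
        ntaps = min(ntaps, max(3, n_samples // 3))
    ntaps = max(ntaps, 3)
    if ntaps % 2 == 0:
        ntaps += 1
    return ntaps


def design_fir(sampling_rate: float, kind: str, edges, ntaps: int) -> np.ndarray:
    """Design a windowed-sinc FIR kernel.

    kind: 'lowpass' (edges = cutoff), 'bandpass' or 'bandstop'
    (edges = (lo, hi)).  Edges must lie strictly inside (0, Nyquist).
    """
    nyq = sampling_rate / 2.0
    if kind == "lowpass":
        cutoff = float(np.atleast_1d(edges)[0])
        if not 0 < cutoff < nyq:
            raise ValueError(f"cutoff {cutoff} Hz outside (0, {nyq}) Hz")
        return signal.firwin(ntaps, cutoff, fs=sampling_rate)
    lo, hi = (float(e) for e in edges)
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band edges ({lo}, {hi}) Hz outside (0, {nyq}) Hz")
    if kind == "bandpass":
        return signal.firwin(ntaps, [lo, hi], pass_zero=False, fs=sampling_rate)
    if kind == "bandstop":
        return signal.firwin(ntaps, [lo, hi], pass_zero=True, fs=sampling_rate)
    raise ValueError(f"unknown filter kind {kind!r}")


def two_pass_filter(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel twice along the last axis (zero phase).

    The input is reflect-padded by one kernel length on each side before
    filtering; the padding is removed afterwards.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    pad = min(len(h), n - 1)
    if pad > 0:
        width = [(0, 0)] * (x.ndim - 1) + [(pad, pad)]
        xp = np.pad(x, width, mode="reflect")
    else:
        xp = x
    h_nd = h.reshape((1,) * (x.ndim - 1) + (-1,))
    y = signal.fftconvolve(xp, h_nd, mode="same", axes=-1)
    y = signal.fftconvolve(y, h_nd, mode="same", axes=-1)
    if pad > 0:
        y = y[..., pad:-pad]
    return y


def analytic_amplitude(x: np.ndarray) -> np.ndarray:
    """|Hilbert analytic signal| along the last axis (FFT-size padded)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    nfft = int(next_fast_len(n))
    analytic = signal.hilbert(x, N=nfft, axis=-1)[..., :n]
    return np.abs(analytic)
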