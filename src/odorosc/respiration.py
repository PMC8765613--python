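"""Breath-feature detection and instantaneous respiratory phase.

Phase convention (fixed throughout the package): for a cosine-shaped
breath the inhale peak sits at phase 0, the inhale->exhale transition at
+pi/2, the exhale trough near +-pi, and the inhale onset (rising zero
crossing) at -pi/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len
from scipy.ndimage import uniform_filter1d

__all__ = ["BreathFeatures", "detect_breaths", "respiratory_phase"]


@dataclass
class BreathFeatures:
    """Per-breath landmark times (s) and extremum values (a.u.).

    Events interleave strictly in time:
    inhale_onset < peak < exhale_onset < trough < next inhale_onset.
    """

    inhale_onsets: np.ndarray
    exhale_onsets: np.ndarray
    peak_times: np.ndarray
    trough_times: np.ndarray
    peak_volumes: np.ndarray
    trough_volumes: np.ndarray

    @property
    def n_breaths(self) -> int:
        return len(self.inhale_onsets)


def _crossings(x: np.ndarray, rising: bool, min_gap: int) -> np.ndarray:
    if rising:
        idx = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0)) + 1
    else:
        idx = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1
    if len(idx) == 0:
        return idx
    kept = [idx[0]]
    for i in idx[1:]:
        if i - kept[-1] >= min_gap:
            kept.append(i)
    return np.asarray(kept)


def detect_breaths(airflow: np.ndarray, sampling_rate: float, t0: float = 0.0,
                   smooth: float = 0.1, min_period: float = 0.5) -> BreathFeatures:
    """Detect inhale/exhale onsets and breath extrema from nasal airflow.

    The trace is mean-centered and smoothed with a ``smooth``-second
    moving average; inhale onsets are rising zero crossings, exhale
    onsets falling zero crossings, peaks/troughs the extrema in between.
    A flat trace yields an empty feature set with a warning.
    """
    x = np.asarray(airflow, dtype=float)
    x = x - x.mean()
    empty = BreathFeatures(*(np.array([]) for _ in range(6)))
    if x.size < 2 or x.std() == 0:
        warnings.warn("airflow trace is flat; no breath features detected")
        return empty
    kernel = max(1, int(round(smooth * sampling_rate)))
    xs = uniform_filter1d(x, kernel, mode="nearest")
    gap = int(round(min_period * sampling_rate))
    rise = _crossings(xs, rising=True, min_gap=gap)
    fall = _crossings(xs, rising=False, min_gap=gap)
    if len(rise) == 0 or len(fall) == 0:
        warnings.warn("no zero crossings found; no breath features detected")
        return empty

    inhale, exhale, peaks, troughs = [], [], [], []
    for j, i_on in enumerate(rise):
        after = fall[fall > i_on]
        if len(after) == 0:
            break
        e_on = after[0]
        nxt = rise[j + 1] if j + 1 < len(rise) else len(xs)
        if e_on >= nxt:
            continue
        peak = i_on + int(np.argmax(xs[i_on:e_on])) if e_on > i_on else i_on
        trough = e_on + int(np.argmin(xs[e_on:nxt])) if nxt > e_on else e_on
        inhale.append(i_on)
        exhale.append(e_on)
        peaks.append(peak)
        troughs.append(trough)

    inhale = np.asarray(inhale, dtype=int)
    exhale = np.asarray(exhale, dtype=int)
    peaks = np.asarray(peaks, dtype=int)
    troughs = np.asarray(troughs, dtype=int)
    to_t = lambda i: t0 + i / sampling_rate
    return BreathFeatures(
        inhale_onsets=to_t(inhale),
        exhale_onsets=to_t(exhale),
        peak_times=to_t(peaks),
        trough_times=to_t(troughs),
        peak_volumes=xs[peaks] if len(peaks) else np.array([]),
        trough_volumes=xs[troughs] if len(troughs) else np.array([]),
    )


def respiratory_phase(airflow: np.ndarray) -> np.ndarray:
    """Instantaneous respiratory phase in (-pi, pi] via the Hilbert method.

    The trace is mean-centered first; for a cosine-shaped breath the
    returned phase is 0 at the inhale peak and +pi/2 a quarter cycle
    later (the inhale->exhale transition).
    """
    x = np.asarray(airflow, dtype=float)
    x = x - x.mean()
    n = x.shape[-1]
    nfft = int(next_fast_len(n))
    return np.angle(signal.hilbert(x, N=nfft, axis=-1)[..., :n])
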