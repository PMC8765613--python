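"""Continuous-recording cleanup: low-pass, line-noise notch, resampling,
and common-average re-referencing.

The chain mirrors a standard clinical iEEG preparation: two-pass
zero-phase FIR low-pass at 235 Hz, band-stop at 60 Hz and its harmonics
(4 Hz stop width), resampling to 500 Hz, then common-average reference.
Event times are kept in absolute seconds so they survive resampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from ._fir import design_fir, fir_order, two_pass_filter

__all__ = [
    "ContinuousRecording",
    "lowpass_filter",
    "notch_harmonics",
    "harmonic_frequencies",
    "downsample",
    "common_average_reference",
    "preprocess_chain",
]


@dataclass
class ContinuousRecording:
    """Multichannel voltage trace on a uniform clock.

    samples: (n_channels, n_samples) array, a.u.
    sampling_rate: Hz
    channel_labels: one label per channel
    start_time: absolute time (s) of the first sample
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, sampling_rate: float | None = None) -> "ContinuousRecording":
        return dataclasses.replace(
            self, samples=samples,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
        )


def lowpass_filter(rec: ContinuousRecording, cutoff: float = 235.0) -> ContinuousRecording:
    """Two-pass zero-phase FIR low-pass; same length as the input."""
    nyq = rec.sampling_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz)")
    # transition edge shrinks near Nyquist so the filter stays meaningful
    ntaps = fir_order(rec.sampling_rate, min(cutoff, nyq - cutoff), rec.n_samples)
    h = design_fir(rec.sampling_rate, "lowpass", cutoff, ntaps)
    return rec.with_samples(two_pass_filter(rec.samples, h))


def harmonic_frequencies(base: float, limit: float) -> list[float]:
    """Line-noise harmonics strictly below ``limit`` (e.g. the low-pass cutoff)."""
    freqs = []
    f = base
    while f < limit:
        freqs.append(f)
        f += base
    return freqs


def notch_harmonics(rec: ContinuousRecording, base: float = 60.0, bandwidth: float = 4.0,
                    max_freq: float = 235.0) -> ContinuousRecording:
    """Band-stop at ``base`` and every harmonic below min(max_freq, Nyquist).

    Each stop band spans +-bandwidth/2 around the harmonic.  The filter
    order is set from the half-bandwidth so the notch is actually narrow.
    """
    nyq = rec.sampling_rate / 2.0
    if base >= nyq:
        raise ValueError(f"base frequency {base} Hz must be below Nyquist ({nyq} Hz)")
    out = rec.samples
    for f in harmonic_frequencies(base, min(max_freq, nyq - bandwidth)):
        # long kernel: the transition shoulders must stay well inside the
        # +-bandwidth/2 stop band to spare the neighbouring spectrum
        ntaps = fir_order(rec.sampling_rate, bandwidth / 2.0, rec.n_samples,
                          factor=12.0)
        h = design_fir(rec.sampling_rate, "bandstop",
                       (f - bandwidth / 2.0, f + bandwidth / 2.0), ntaps)
        out = two_pass_filter(out, h)
    return rec.with_samples(out)


def downsample(rec: ContinuousRecording, target: float = 500.0) -> ContinuousRecording:
    """Resample to ``target`` Hz (polyphase, with internal anti-aliasing).

    Non-integer rate ratios are handled by rational resampling.  Event
    times are absolute seconds and therefore unaffected.
    """
    if target > rec.sampling_rate:
        raise ValueError("target rate above original rate")
    if target == rec.sampling_rate:
        return rec.with_samples(rec.samples.copy())
    frac = Fraction(target / rec.sampling_rate).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return rec.with_samples(out, sampling_rate=target)


def common_average_reference(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    out = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return rec.with_samples(out)


def preprocess_chain(rec: ContinuousRecording, lowpass_cutoff: float = 235.0,
                     notch_base: float = 60.0, notch_bandwidth: float = 4.0,
                     target_rate: float = 500.0, car: bool = True) -> ContinuousRecording:
    """Low-pass -> notch harmonics -> downsample -> common average."""
    cutoff = min(lowpass_cutoff, 0.95 * rec.sampling_rate / 2.0)
    out = lowpass_filter(rec, cutoff)
    out = notch_harmonics(out, notch_base, notch_bandwidth, max_freq=cutoff)
    out = downsample(out, min(target_rate, rec.sampling_rate))
    if cutoff < out.sampling_rate / 2.0:
        # second, sharper pass on the downsampled grid clears the residual
        # transition-band content, making the chain idempotent
        out = lowpass_filter(out, cutoff)
    if car and out.n_channels >= 2:
        out = common_average_reference(out)
    return out
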