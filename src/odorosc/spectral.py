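"""Filter-bank spectrograms and permutation-normalized z-maps.

The filter bank has 100 logarithmically spaced center frequencies from
1 to 200 Hz with bandwidths logarithmically spaced from 2 to 50 Hz; the
first 95 bands (about 1-153 Hz) are retained for analysis.  Per band the
signal is band-passed (two-pass zero-phase FIR), Hilbert-transformed,
rectified, and smoothed with a 10 ms moving average.

Two permutation nulls are provided:

* circular_shift_zmap - all event times shifted by one common random
  offset (wrapping, preserving inter-event spacing), epochs re-cut, and
  the baseline-corrected trial average recomputed; z is the observed
  average normalized by the per-point null standard deviation.
* condition_difference_zmap - condition labels shuffled across pooled
  trials; the null difference-of-means distribution is summarized by a
  per-point Gaussian fit.

Both maps are FDR-corrected (Benjamini-Hochberg) across all
time-frequency points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from ._fir import analytic_amplitude, design_fir, fir_order, two_pass_filter

__all__ = [
    "FilterBank",
    "AmplitudeStack",
    "TrialTensor",
    "ZMap",
    "build_filter_bank",
    "amplitude_stack",
    "bandpass_amplitude",
    "epoch",
    "baseline_correct",
    "circular_shift_zmap",
    "condition_difference_zmap",
    "decompose_evoked_induced",
]


@dataclass(frozen=True)
class FilterBank:
    """Log-spaced center frequencies and bandwidths; first n_kept retained."""

    centers: np.ndarray
    widths: np.ndarray
    n_kept: int = 95

    @property
    def kept_centers(self) -> np.ndarray:
        return self.centers[: self.n_kept]

    @property
    def kept_widths(self) -> np.ndarray:
        return self.widths[: self.n_kept]

    def pac_band_indices(self, min_hz: float = 13.0) -> np.ndarray:
        """Indices (into the kept bands) of amplitude bands above min_hz."""
        return np.flatnonzero(self.kept_centers > min_hz)


def build_filter_bank(n_bands: int = 100, f_lo: float = 1.0, f_hi: float = 200.0,
                      w_lo: float = 2.0, w_hi: float = 50.0, n_kept: int = 95) -> FilterBank:
    """100 log-spaced centers 1->200 Hz, widths 2->50 Hz, first 95 kept.

    c_k = f_lo * (f_hi/f_lo)**((k-1)/(n-1)); widths analogous.  With the
    defaults, band 49 is the lowest kept band above 13 Hz (13.05 Hz) and
    band 95 the highest kept band (153.04 Hz).
    """
    k = np.arange(n_bands)
    centers = f_lo * (f_hi / f_lo) ** (k / (n_bands - 1))
    widths = w_lo * (w_hi / w_lo) ** (k / (n_bands - 1))
    return FilterBank(centers=centers, widths=widths, n_kept=n_kept)


@dataclass
class AmplitudeStack:
    """Band x time analytic amplitudes of a single channel."""

    amplitudes: np.ndarray   # (n_bands, n_samples), >= 0
    band_centers: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def bandpass_amplitude(x: np.ndarray, sampling_rate: float, center: float, width: float,
                       smooth: float = 0.010) -> np.ndarray | None:
    """Analytic amplitude of one filter-bank band, or None if unfilterable.

    Bands whose lower edge touches 0 Hz are realized as low-pass filters;
    bands whose upper edge reaches Nyquist are skipped.
    """
    nyq = sampling_rate / 2.0
    lo = center - width / 2.0
    hi = center + width / 2.0
    n = x.shape[-1]
    if hi >= nyq:
        return None
    if lo <= 0.05:
        ntaps = fir_order(sampling_rate, center, n)
        h = design_fir(sampling_rate, "lowpass", hi, ntaps)
    else:
        ntaps = fir_order(sampling_rate, lo, n)
        h = design_fir(sampling_rate, "bandpass", (lo, hi), ntaps)
    amp = analytic_amplitude(two_pass_filter(x, h))
    kernel = max(1, int(round(smooth * sampling_rate)))
    return uniform_filter1d(amp, kernel, axis=-1, mode="nearest")


def amplitude_stack(x: np.ndarray, sampling_rate: float, bank: FilterBank,
                    band_indices: np.ndarray | None = None, smooth: float = 0.010,
                    start_time: float = 0.0) -> AmplitudeStack:
    """Hilbert filter-bank amplitudes for the kept bands (or a subset).

    band_indices indexes into the kept bands; bands whose upper edge
    reaches Nyquist are skipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("amplitude_stack expects a single channel")
    centers = bank.kept_centers
    widths = bank.kept_widths
    if band_indices is not None:
        centers = centers[band_indices]
        widths = widths[band_indices]
    rows, used = [], []
    for c, w in zip(centers, widths):
        amp = bandpass_amplitude(x, sampling_rate, c, w, smooth)
        if amp is None:
            warnings.warn(f"band at {c:.2f} Hz exceeds Nyquist; skipped")
            continue
        rows.append(amp)
        used.append(c)
    return AmplitudeStack(
        amplitudes=np.asarray(rows), band_centers=np.asarray(used),
        sampling_rate=sampling_rate, start_time=start_time,
    )


@dataclass
class TrialTensor:
    """Sniff-aligned trial x band x time amplitude epochs plus metadata."""

    amplitudes: np.ndarray          # (n_trials, n_bands, n_times)
    times: np.ndarray               # seconds relative to alignment event
    band_centers: np.ndarray
    meta: pd.DataFrame | None = None
    baseline_means: np.ndarray | None = None    # (n_trials, n_bands)
    baseline_sd: np.ndarray | None = None       # (n_bands,) pooled across trials
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    def select(self, mask: np.ndarray) -> "TrialTensor":
        meta = self.meta.loc[mask].reset_index(drop=True) if self.meta is not None else None
        bl = self.baseline_means[mask] if self.baseline_means is not None else None
        return replace(self, amplitudes=self.amplitudes[mask], meta=meta, baseline_means=bl)


def _cut_epochs(stack_amp: np.ndarray, sampling_rate: float, start_time: float,
                event_times: np.ndarray, window: tuple[float, float]):
    """Half-open [window) epoch slices; returns (tensor, kept_mask)."""
    n = stack_amp.shape[-1]
    n_t = int(round((window[1] - window[0]) * sampling_rate))
    starts = np.round((np.asarray(event_times) + window[0] - start_time) * sampling_rate).astype(int)
    keep = (starts >= 0) & (starts + n_t <= n)
    idx = starts[keep, None] + np.arange(n_t)[None, :]
    cut = stack_amp[:, idx]                       # (bands, trials, time)
    return np.moveaxis(cut, 0, 1), keep           # -> (trials, bands, time)


def epoch(stack: AmplitudeStack, event_times: np.ndarray,
          window: tuple[float, float] = (-2.0, 4.0),
          meta: pd.DataFrame | None = None) -> TrialTensor:
    """Cut event-aligned epochs; out-of-bounds events are dropped with a warning."""
    tensor, keep = _cut_epochs(stack.amplitudes, stack.sampling_rate, stack.start_time,
                               event_times, window)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} event(s) outside the recording")
    n_t = tensor.shape[-1]
    times = window[0] + np.arange(n_t) / stack.sampling_rate
    if meta is not None:
        meta = meta.loc[keep].reset_index(drop=True)
    return TrialTensor(amplitudes=tensor, times=times, band_centers=stack.band_centers,
                       meta=meta, n_dropped=n_dropped)


def baseline_correct(trials: TrialTensor, stack: AmplitudeStack, cue_times: np.ndarray,
                     window: tuple[float, float] = (-0.55, -0.05)) -> TrialTensor:
    """Subtract each trial's pre-cue mean amplitude, per band.

    The baseline window is cut from the continuous stack relative to cue
    onset (which generally lies outside the sniff-aligned epoch).  Trials
    with missing cue times or baselines outside the recording are dropped
    with a warning.  Per-trial baseline means and the pooled per-band
    baseline standard deviation are retained for percent-change and
    z-normalization use.
    """
    cue_times = np.asarray(cue_times, dtype=float)
    if len(cue_times) != trials.n_trials:
        raise ValueError("one cue time per trial required")
    valid = np.isfinite(cue_times)
    if not valid.all():
        warnings.warn(f"excluded {int((~valid).sum())} trial(s) with missing cue times")
    base, keep = _cut_epochs(stack.amplitudes, stack.sampling_rate, stack.start_time,
                             np.where(valid, cue_times, -1e9), window)
    if not keep.all():
        warnings.warn(f"excluded {int((~keep).sum())} trial(s) without a valid baseline")
    sub = trials.select(keep)
    bmeans = base.mean(axis=-1)                          # (n_kept_trials, n_bands)
    bsd = base.std(axis=(0, 2), ddof=1) if base.shape[0] > 1 else base.std(axis=(0, 2))
    corrected = sub.amplitudes - bmeans[:, :, None]
    return replace(sub, amplitudes=corrected, baseline_means=bmeans, baseline_sd=bsd,
                   n_dropped=trials.n_dropped + int((~keep).sum()))


@dataclass
class ZMap:
    """Band x time z-scores with FDR significance mask and null summary."""

    z: np.ndarray
    significance_mask: np.ndarray
    p_adjusted: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_permutations: int
    q: float
    band_centers: np.ndarray
    times: np.ndarray


def _fdr_mask(z: np.ndarray, q: float):
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = stats.false_discovery_control(p.ravel(), method="bh").reshape(p.shape)
    return p_adj, p_adj < q


def circular_shift_zmap(stack: AmplitudeStack, sniff_times: np.ndarray,
                        cue_times: np.ndarray, window: tuple[float, float] = (-2.0, 4.0),
                        baseline_window: tuple[float, float] = (-0.55, -0.05),
                        n_perm: int = 10_000, q: float = 0.05,
                        seed: int | None = None) -> ZMap:
    """z-map of the baseline-corrected trial-average spectrogram against a
    circular-shift null.

    Per permutation all sniff onsets (with their cue offsets) are shifted
    by one common random offset, wrapping inside the valid range of the
    recording so that the relative distances between events are
    maintained; epochs are re-cut and the baseline-corrected average
    recomputed.  z = (observed - null mean) / null sd per point, two-sided
    p, Benjamini-Hochberg FDR across all time-frequency points.
    """
    sniff_times = np.asarray(sniff_times, dtype=float)
    cue_times = np.asarray(cue_times, dtype=float)
    if len(sniff_times) < 2:
        raise ValueError("at least 2 events required")
    fs = stack.sampling_rate
    t0 = stack.start_time
    t_end = t0 + stack.duration
    delays = sniff_times - cue_times
    if np.any(delays < 0):
        raise ValueError("cue times must precede sniff times")
    pre_need = max(-window[0], float(np.max(delays)) - baseline_window[0])
    lo = t0 + pre_need + 1.0 / fs
    hi = t_end - window[1]
    span = hi - lo
    if span <= window[1] - window[0]:
        raise ValueError("recording too short for circular-shift permutations")

    def corrected_mean(sniffs):
        ep, keep = _cut_epochs(stack.amplitudes, fs, t0, sniffs, window)
        bl, keepb = _cut_epochs(stack.amplitudes, fs, t0, sniffs - delays, baseline_window)
        if not (keep.all() and keepb.all()):
            raise RuntimeError("event fell outside recording during permutation")
        return (ep - bl.mean(axis=-1, keepdims=True)).mean(axis=0)  # (bands, time)

    observed = corrected_mean(sniff_times)

    rng = np.random.default_rng(seed)
    s = np.zeros_like(observed)
    s2 = np.zeros_like(observed)
    for _ in range(n_perm):
        delta = rng.uniform(0.0, span)
        shifted = lo + np.mod(sniff_times - lo + delta, span)
        m = corrected_mean(shifted)
        s += m
        s2 += m * m
    null_mean = s / n_perm
    var = s2 / n_perm - null_mean**2
    null_sd = np.sqrt(np.maximum(var, 0.0) * n_perm / max(n_perm - 1, 1))
    null_sd[null_sd == 0] = np.inf
    z = (observed - null_mean) / null_sd
    p_adj, mask = _fdr_mask(z, q)
    n_t = observed.shape[-1]
    times = window[0] + np.arange(n_t) / fs
    return ZMap(z=z, significance_mask=mask, p_adjusted=p_adj, null_mean=null_mean,
                null_sd=null_sd, n_permutations=n_perm, q=q,
                band_centers=stack.band_centers, times=times)


def condition_difference_zmap(trials_a: TrialTensor, trials_b: TrialTensor,
                              n_perm: int = 10_000, q: float = 0.05,
                              seed: int | None = None) -> ZMap:
    """z-map of the difference of baseline-corrected trial means (A - B)
    against a condition-label-shuffle null.

    The null distribution at each point is summarized by a Gaussian
    maximum-likelihood fit (mean and sd of the permuted differences).
    """
    if trials_a.n_trials == 0 or trials_b.n_trials == 0:
        raise ValueError("both conditions must contain trials")
    if trials_a.amplitudes.shape[1:] != trials_b.amplitudes.shape[1:]:
        raise ValueError("tensors must share band and time axes")
    a, b = trials_a.amplitudes, trials_b.amplitudes
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    n_tot = pooled.shape[0]
    observed = a.mean(axis=0) - b.mean(axis=0)

    rng = np.random.default_rng(seed)
    s = np.zeros_like(observed)
    s2 = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        d = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)
        s += d
        s2 += d * d
    null_mean = s / n_perm
    var = s2 / n_perm - null_mean**2
    null_sd = np.sqrt(np.maximum(var, 0.0) * n_perm / max(n_perm - 1, 1))
    null_sd[null_sd == 0] = np.inf
    z = (observed - null_mean) / null_sd
    p_adj, mask = _fdr_mask(z, q)
    return ZMap(z=z, significance_mask=mask, p_adjusted=p_adj, null_mean=null_mean,
                null_sd=null_sd, n_permutations=n_perm, q=q,
                band_centers=trials_a.band_centers, times=trials_a.times)


def decompose_evoked_induced(voltage_epochs: np.ndarray, sampling_rate: float,
                             bank: FilterBank, band_indices: np.ndarray | None = None,
                             times: np.ndarray | None = None,
                             baseline_window: tuple[float, float] | None = None,
                             smooth: float = 0.010):
    """Split voltage epochs into phase-locked (evoked) and non-phase-locked
    (induced) spectrograms.

    The ERP is the trial mean of the voltage epochs.  The induced path is
    the filter-bank amplitude of each (trial - ERP) residual; the evoked
    path is the (optionally baseline-corrected) filter-bank amplitude of
    the ERP itself.  Returns (evoked band x time array, induced
    TrialTensor, band centers).
    """
    x = np.asarray(voltage_epochs, dtype=float)
    if x.ndim != 2:
        raise ValueError("voltage_epochs must be (n_trials, n_times)")
    if x.shape[0] < 5:
        warnings.warn("fewer than 5 trials: the ERP estimate is unstable")
    erp = x.mean(axis=0)

    centers = bank.kept_centers
    widths = bank.kept_widths
    if band_indices is not None:
        centers, widths = centers[band_indices], widths[band_indices]

    evoked_rows, induced_rows, used = [], [], []
    residual = x - erp[None, :]
    for c, w in zip(centers, widths):
        amp_e = bandpass_amplitude(erp, sampling_rate, c, w, smooth)
        amp_i = bandpass_amplitude(residual, sampling_rate, c, w, smooth)
        if amp_e is None or amp_i is None:
            warnings.warn(f"band at {c:.2f} Hz exceeds Nyquist; skipped")
            continue
        evoked_rows.append(amp_e)
        induced_rows.append(amp_i)
        used.append(c)
    evoked = np.asarray(evoked_rows)                       # (bands, time)
    induced = np.stack(induced_rows, axis=1)               # (trials, bands, time)
    used = np.asarray(used)
    if times is None:
        times = np.arange(x.shape[1]) / sampling_rate
    if baseline_window is not None:
        sel = (times >= baseline_window[0]) & (times < baseline_window[1])
        if sel.any():
            evoked = evoked - evoked[:, sel].mean(axis=1, keepdims=True)
    tensor = TrialTensor(amplitudes=induced, times=np.asarray(times), band_centers=used)
    return evoked, tensor, used
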