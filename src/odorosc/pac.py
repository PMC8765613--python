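"""Phase-amplitude coupling: KL-based modulation index of theta phase vs
the 47 log-spaced amplitude bands (13.05-153.04 Hz).

MI = [log N + sum_j P_j log P_j] / log N where P_j is the normalized mean
amplitude in each of N equal phase bins over (-pi, pi]; MI is 0 for a
uniform phase-amplitude distribution and 1 when all amplitude falls in a
single bin.  Two permutation nulls normalize the raw MI: a circular shift
of the concatenated amplitude series, and a shuffle of the trial order of
the phase epochs (a control for evoked-potential slope artifacts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from ._fir import design_fir, fir_order, two_pass_filter
from .spectral import FilterBank, amplitude_stack, build_filter_bank

__all__ = [
    "PACResult",
    "theta_phase_epochs",
    "modulation_index",
    "pac_epochs",
    "mi_spectrum",
    "mi_null_circular_shift",
    "mi_null_trial_shuffle",
]


@dataclass
class PACResult:
    """Per-amplitude-band modulation index with permutation normalization."""

    amp_band_centers: np.ndarray
    mi_raw: np.ndarray
    mi_z: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    fdr_mask: np.ndarray
    null_kind: str
    n_permutations: int
    n_bins: int
    excluded: np.ndarray | None = None


def theta_phase_epochs(x: np.ndarray, sampling_rate: float, sniff_times: np.ndarray,
                       window: tuple[float, float] = (0.0, 1.0),
                       band: tuple[float, float] = (4.0, 8.0),
                       start_time: float = 0.0) -> tuple[np.ndarray, int, int]:
    """Concatenated theta phase over per-sniff windows.

    Band-pass 4-8 Hz (two-pass FIR), Hilbert phase, cut [window) per
    sniff, concatenate preserving trial order.  Returns (phase series,
    n_trials kept, samples per trial).  Out-of-range sniffs are dropped.
    """
    x = np.asarray(x, dtype=float)
    ntaps = fir_order(sampling_rate, band[0], x.size)
    h = design_fir(sampling_rate, "bandpass", band, ntaps)
    filtered = two_pass_filter(x, h)
    n = filtered.size
    phase = np.angle(hilbert(filtered, N=int(next_fast_len(n)))[:n])
    n_t = int(round((window[1] - window[0]) * sampling_rate))
    starts = np.round((np.asarray(sniff_times) + window[0] - start_time) * sampling_rate).astype(int)
    keep = (starts >= 0) & (starts + n_t <= n)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} sniff(s) outside the recording")
    idx = starts[keep, None] + np.arange(n_t)[None, :]
    return phase[idx].ravel(), int(keep.sum()), n_t


def modulation_index(phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18) -> float:
    """KL-based modulation index in [0, 1].

    Phases are binned into n_bins equal bins over (-pi, pi]; P_j is the
    mean amplitude per bin normalized to sum 1; MI = KL(P || uniform) /
    log(n_bins).  Empty bins contribute P_j = 0 (with a warning); an
    all-zero amplitude is an error.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    total = amplitude.sum()
    if total <= 0:
        raise ValueError("amplitude sums to zero; MI undefined")
    bins = _phase_bins(phase, n_bins)
    p = _bin_distribution(bins, amplitude, n_bins, warn_empty=True)
    return _mi_from_distribution(p, n_bins)


def _phase_bins(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal phase bins over (-pi, pi]; bin j covers (-pi + j*w, -pi + (j+1)*w]."""
    w = 2.0 * np.pi / n_bins
    bins = np.ceil((phase + np.pi) / w).astype(int) - 1
    return np.clip(bins, 0, n_bins - 1)


def _bin_distribution(bins: np.ndarray, amplitude: np.ndarray, n_bins: int,
                      warn_empty: bool = False) -> np.ndarray:
    sums = np.bincount(bins, weights=amplitude, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    means = np.zeros(n_bins)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    if warn_empty and not nz.all():
        warnings.warn(f"{int((~nz).sum())} empty phase bin(s); treated as P=0")
    s = means.sum()
    return means / s if s > 0 else means


def _mi_from_distribution(p: np.ndarray, n_bins: int) -> float:
    nz = p > 0
    entropy_term = float((p[nz] * np.log(p[nz])).sum())
    mi = (np.log(n_bins) + entropy_term) / np.log(n_bins)
    return float(np.clip(mi, 0.0, 1.0))


def pac_epochs(x: np.ndarray, sampling_rate: float, sniff_times: np.ndarray,
               window: tuple[float, float] = (0.0, 1.0),
               bank: FilterBank | None = None, start_time: float = 0.0):
    """Concatenated (theta phase, 47-band amplitudes) over sniff windows.

    The amplitude bands are the kept filter-bank bands with centers above
    13 Hz, extracted with the same filter chain as the spectrograms and
    concatenated identically to the phase data.  Returns
    (phase (L,), amps (47, L), centers, n_trials, samples_per_trial).
    """
    if bank is None:
        bank = build_filter_bank()
    phase, n_kept, n_t = theta_phase_epochs(x, sampling_rate, sniff_times, window,
                                            start_time=start_time)
    pac_idx = bank.pac_band_indices()
    stack = amplitude_stack(np.asarray(x, dtype=float), sampling_rate, bank,
                            band_indices=pac_idx, start_time=start_time)
    starts = np.round((np.asarray(sniff_times) + window[0] - start_time)
                      * sampling_rate).astype(int)
    keep = (starts >= 0) & (starts + n_t <= stack.n_samples)
    idx = starts[keep, None] + np.arange(n_t)[None, :]
    amps = stack.amplitudes[:, idx].reshape(stack.amplitudes.shape[0], -1)
    return phase, amps, stack.band_centers, n_kept, n_t


def mi_spectrum(phase: np.ndarray, amps: np.ndarray, n_bins: int = 18) -> np.ndarray:
    """Raw MI per amplitude band against a common phase series."""
    bins = _phase_bins(phase, n_bins)
    out = np.empty(amps.shape[0])
    for b in range(amps.shape[0]):
        p = _bin_distribution(bins, amps[b], n_bins)
        out[b] = _mi_from_distribution(p, n_bins)
    return out


def _normalize_and_mask(centers, mi_raw, null, null_kind, n_bins, q):
    null_mean = null.mean(axis=1)
    null_sd = null.std(axis=1, ddof=1)
    excluded = null_sd == 0
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} band(s) with degenerate null excluded from FDR")
    sd = np.where(excluded, np.inf, null_sd)
    z = (mi_raw - null_mean) / sd
    p = stats.norm.sf(z)
    ok = ~excluded
    p_adj = np.ones_like(p)
    if ok.any():
        p_adj[ok] = stats.false_discovery_control(p[ok], method="bh")
    mask = (p_adj < q) & ok
    return PACResult(amp_band_centers=centers, mi_raw=mi_raw, mi_z=z, p=p,
                     p_adjusted=p_adj, fdr_mask=mask, null_kind=null_kind,
                     n_permutations=null.shape[1], n_bins=n_bins,
                     excluded=excluded)


def mi_null_circular_shift(phase: np.ndarray, amps: np.ndarray, n_perm: int = 1000,
                           q: float = 0.05, n_bins: int = 18,
                           seed: int | None = None,
                           centers: np.ndarray | None = None) -> PACResult:
    """Normalize MI against circularly shifted amplitude series.

    Per band and permutation the concatenated amplitude is circularly
    shifted by a uniform random offset in [1, L-1] (identity excluded)
    and MI recomputed; z = (MI_raw - null mean) / null sd, one-sided p,
    FDR across bands.
    """
    rng = np.random.default_rng(seed)
    bins = _phase_bins(phase, n_bins)
    n_bands, length = amps.shape
    mi_raw = mi_spectrum(phase, amps, n_bins)
    null = np.empty((n_bands, n_perm))
    for b in range(n_bands):
        a = amps[b]
        for i in range(n_perm):
            shift = int(rng.integers(1, length))
            p = _bin_distribution(bins, np.roll(a, shift), n_bins)
            null[b, i] = _mi_from_distribution(p, n_bins)
    if centers is None:
        centers = np.arange(n_bands, dtype=float)
    return _normalize_and_mask(centers, mi_raw, null, "circular_shift", n_bins, q)


def mi_null_trial_shuffle(phase: np.ndarray, amps: np.ndarray, n_trials: int,
                          n_perm: int = 1000, q: float = 0.05, n_bins: int = 18,
                          seed: int | None = None,
                          centers: np.ndarray | None = None) -> PACResult:
    """Normalize MI against a trial-order shuffle of the phase epochs.

    The concatenated phase is split back into its per-trial blocks, the
    block order permuted (within-trial samples intact), and MI recomputed
    against the unshuffled amplitudes.  Controls for coupling induced by
    a steep evoked slope occurring at the same within-trial time on every
    trial.
    """
    if n_trials < 5:
        raise ValueError("need at least 5 trials for the trial-order shuffle")
    rng = np.random.default_rng(seed)
    length = phase.size
    if length % n_trials:
        raise ValueError("phase length is not a multiple of n_trials")
    n_t = length // n_trials
    bins = _phase_bins(phase, n_bins).reshape(n_trials, n_t)
    mi_raw = mi_spectrum(phase, amps, n_bins)
    n_bands = amps.shape[0]
    null = np.empty((n_bands, n_perm))
    for i in range(n_perm):
        order = rng.permutation(n_trials)
        shuffled = bins[order].ravel()
        for b in range(n_bands):
            p = _bin_distribution(shuffled, amps[b], n_bins)
            null[b, i] = _mi_from_distribution(p, n_bins)
    if centers is None:
        centers = np.arange(n_bands, dtype=float)
    return _normalize_and_mask(centers, mi_raw, null, "trial_shuffle", n_bins, q)
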