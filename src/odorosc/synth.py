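"""Synthetic sniff-locked LFP generator with ground truth.

Produces a continuous multichannel recording (one burst-carrying channel
of interest plus decoy noise channels), a quasi-periodic nasal-airflow
trace, an event table (odor / no-odor trials with cue times and
correct/incorrect flags), and the injected ground truth needed for
parameter-recovery tests.

Statistical structure injected by the defaults:

* theta burst (4.72 Hz) starting 126 ms before sniff onset,
* beta burst (18.98 Hz) starting 144 ms after sniff onset, long,
* gamma burst (84.94 Hz) starting 116 ms after sniff onset whose
  envelope is locked to theta phase with depth ``pac_depth``
  (a(t) = A * (1 + kappa * cos(phi_theta(t)))),
* on correct trials, beta/gamma amplitudes scaled by ``accuracy_gain``,
* 1/f background noise with controlled spectral slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .preprocess import ContinuousRecording

__all__ = [
    "BurstSpec",
    "SynthConfig",
    "BreathTruth",
    "GroundTruth",
    "default_band_specs",
    "generate_respiration",
    "generate_recording",
    "power_law_noise",
]


@dataclass(frozen=True)
class BurstSpec:
    """One oscillatory burst injected per odor trial.

    respiratory_lock: 'none' or 'theta_phase'; when 'theta_phase' the
    burst envelope is multiplied by (1 + pac_depth * cos(theta phase)).
    """

    name: str
    center_freq: float
    onset_latency: float
    duration: float
    amplitude: float
    respiratory_lock: str = "none"
    carrier_bandwidth: float = 0.0   # 0 = pure tone; >0 = narrowband noise carrier

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.carrier_bandwidth < 0:
            raise ValueError("carrier_bandwidth must be >= 0")
        if self.respiratory_lock not in ("none", "theta_phase"):
            raise ValueError("respiratory_lock must be 'none' or 'theta_phase'")


def default_band_specs() -> tuple[BurstSpec, ...]:
    """Theta / beta / gamma bursts with the default latencies and peaks."""
    return (
        BurstSpec("theta", 4.72, -0.126, 1.2, 1.0),
        BurstSpec("beta", 18.98, 0.144, 3.8, 0.6),
        BurstSpec("gamma", 84.94, 0.116, 2.5, 0.12, respiratory_lock="theta_phase",
                  carrier_bandwidth=20.0),
    )


@dataclass
class SynthConfig:
    """Parameters of the synthetic task recording.

    intertrial_interval / breath_period are (mean, sd) in seconds;
    cue_to_sniff_delay is a uniform (lo, hi) range in seconds.
    accuracy_gain maps burst names to the multiplicative amplitude
    factor applied on correct trials.
    """

    sampling_rate: float = 500.0
    n_trials: int = 40
    n_channels: int = 3
    intertrial_interval: tuple[float, float] = (21.3, 2.0)
    breath_period: tuple[float, float] = (4.0, 0.3)
    inhale_fraction: float = 0.4
    cue_to_sniff_delay: tuple[float, float] = (3.0, 7.0)
    band_specs: tuple[BurstSpec, ...] = field(default_factory=default_band_specs)
    pac_depth: float = 0.8
    noise_exponent: float = 1.0
    noise_scale: float = 0.05
    amplitude_jitter: float = 0.25
    evoked_amplitude: float = 0.0
    p_correct: float = 0.75
    accuracy_gain: dict[str, float] = field(default_factory=lambda: {"beta": 1.5, "gamma": 1.5})
    random_burst_phase: bool = True
    epoch_window: tuple[float, float] = (-2.0, 4.0)
    baseline_window: tuple[float, float] = (-0.55, -0.05)
    lead_in: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth must be in [0, 1]")
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must be in [0, 1]")
        if self.sampling_rate <= 0 or self.n_trials <= 0 or self.n_channels < 1:
            raise ValueError("sampling_rate, n_trials, n_channels must be positive")
        if self.breath_period[0] <= 0 or self.breath_period[1] < 0:
            raise ValueError("breath_period mean must be > 0 and sd >= 0")
        if self.intertrial_interval[0] <= 0 or self.intertrial_interval[1] < 0:
            raise ValueError("intertrial interval mean must be > 0 and sd >= 0")
        if not 0 < self.inhale_fraction < 1:
            raise ValueError("inhale_fraction must be in (0, 1)")
        lo, hi = self.cue_to_sniff_delay
        if not 0 < lo <= hi:
            raise ValueError("cue_to_sniff_delay range must be positive and ordered")
        nyq = self.sampling_rate / 2.0
        for spec in self.band_specs:
            if spec.center_freq >= nyq:
                raise ValueError(f"burst {spec.name!r}: center_freq >= Nyquist")


@dataclass
class BreathTruth:
    """Drawn (not detected) breath landmarks of a synthetic airflow trace."""

    inhale_onsets: np.ndarray
    exhale_onsets: np.ndarray
    peak_times: np.ndarray
    trough_times: np.ndarray
    periods: np.ndarray


@dataclass
class GroundTruth:
    """Injected per-trial structure of a synthetic recording."""

    band_names: list[str]
    trial_amplitudes: np.ndarray        # (n_trials, n_bands)
    burst_windows: np.ndarray           # (n_trials, n_bands, 2) seconds
    coupling_depth: dict[str, float]
    correct: np.ndarray                 # bool (n_trials,)
    sniff_times: np.ndarray
    cue_times: np.ndarray
    theta_phase_offsets: np.ndarray
    breaths: BreathTruth


def power_law_noise(shape: tuple[int, ...], exponent: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent.

    Generated by spectral shaping of white Gaussian noise, which gives
    exact slope control.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_respiration(config: SynthConfig, duration: float | None = None,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, BreathTruth]:
    """Zero-mean quasi-periodic airflow with drawn breath landmarks.

    Each breath is an asymmetric pair of raised-half-cosine lobes (the
    inhale lobe shorter than the exhale lobe); the exhale depth is scaled
    so each breath integrates to zero, keeping the rising zero crossings
    exactly at the drawn inhale onsets.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean_p, sd_p = config.breath_period
    if duration is None:
        iti_mean, iti_sd = config.intertrial_interval
        duration = 2 * config.lead_in + config.n_trials * (iti_mean + 3 * iti_sd) + 4 * mean_p

    fs = config.sampling_rate
    n = int(round(duration * fs))
    trace = np.zeros(n)
    inhale, exhale, peaks, troughs, periods = [], [], [], [], []
    t = 1.0
    while True:
        p = rng.normal(mean_p, sd_p) if sd_p > 0 else mean_p
        p = float(np.clip(p, 0.3 * mean_p, 3.0 * mean_p))
        if t + p >= duration - 1.0 / fs:
            break
        t_in = config.inhale_fraction * p
        t_ex = p - t_in
        i0 = int(round(t * fs))
        i1 = int(round((t + t_in) * fs))
        i2 = int(round((t + p) * fs))
        seg_in = np.arange(i0, i1) / fs - t
        seg_ex = np.arange(i1, i2) / fs - (t + t_in)
        trace[i0:i1] += np.sin(np.pi * seg_in / t_in)
        trace[i1:i2] -= (t_in / t_ex) * np.sin(np.pi * seg_ex / t_ex)
        inhale.append(t)
        exhale.append(t + t_in)
        peaks.append(t + t_in / 2.0)
        troughs.append(t + t_in + t_ex / 2.0)
        periods.append(p)
        t += p
    trace -= trace.mean()
    truth = BreathTruth(
        inhale_onsets=np.asarray(inhale),
        exhale_onsets=np.asarray(exhale),
        peak_times=np.asarray(peaks),
        trough_times=np.asarray(troughs),
        periods=np.asarray(periods),
    )
    return trace, truth


def _narrowband_carrier(n_seg: int, fs: float, center: float, bandwidth: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise carrier, RMS-matched to a unit tone.

    Spectral shaping in the frequency domain keeps the carrier strictly
    inside [center - bw/2, center + bw/2].
    """
    white = rng.standard_normal(n_seg)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_seg, d=1.0 / fs)
    keep = (freqs >= center - bandwidth / 2.0) & (freqs <= center + bandwidth / 2.0)
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n=n_seg)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return np.zeros(n_seg)
    return x * (1.0 / np.sqrt(2.0)) / rms


def _schedule_sniffs(config: SynthConfig, onsets: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Pick odor-trial sniff times from available inhale onsets.

    Draws are clipped from below at the minimal non-overlapping spacing
    (cue delay + baseline extent + epoch tail); a mean intertrial
    interval shorter than that is rejected outright.
    """
    iti_mean, iti_sd = config.intertrial_interval
    min_gap = (config.cue_to_sniff_delay[1] - config.baseline_window[0]
               + config.epoch_window[1] + 0.1)
    if iti_mean < min_gap:
        raise ValueError(
            f"intertrial interval mean {iti_mean} s is shorter than the trial "
            f"span ({min_gap:.2f} s): trial windows would overlap")
    sniffs = []
    prev = config.lead_in
    for i in range(config.n_trials):
        iti = rng.normal(iti_mean, iti_sd) if iti_sd > 0 else iti_mean
        iti = float(np.clip(iti, min_gap, 3.0 * iti_mean))
        target = prev + iti if sniffs else prev
        candidates = onsets[onsets >= target]
        if len(candidates) == 0:
            raise RuntimeError(
                f"ran out of breaths after {i} trials; increase recording duration")
        sniffs.append(float(candidates[0]))
        prev = sniffs[-1]
    return np.asarray(sniffs)


def generate_recording(config: SynthConfig):
    """Generate (ContinuousRecording, events DataFrame, GroundTruth).

    Channel 0 of the recording carries the injected bursts; the remaining
    channels are pure 1/f noise (decoys for common-average referencing).
    The airflow trace, on the same clock, is attached to the returned
    recording as the ``airflow`` attribute.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    epoch_pre, epoch_post = config.epoch_window

    airflow, breaths = generate_respiration(config, rng=rng)
    n = len(airflow)
    duration = n / fs

    sniffs = _schedule_sniffs(config, breaths.inhale_onsets, rng)
    lo, hi = config.cue_to_sniff_delay
    delays = rng.uniform(lo, hi, size=config.n_trials)
    cues = sniffs - delays

    # trial span: [cue + baseline start, sniff + epoch end]
    span_start = np.minimum(cues + config.baseline_window[0], sniffs + epoch_pre)
    span_end = sniffs + epoch_post
    if span_start[0] < 0.5:
        raise ValueError("first trial window precedes the recording start; "
                         "increase lead_in")
    if np.any(span_start[1:] <= span_end[:-1]):
        raise ValueError("trial windows overlap: intertrial interval shorter "
                         "than the epoch span")
    if span_end[-1] > duration - 0.5:
        raise RuntimeError("last trial window exceeds the recording")

    correct = rng.random(config.n_trials) < config.p_correct
    phase_off = (rng.uniform(0.0, 2 * np.pi, size=config.n_trials)
                 if config.random_burst_phase else np.zeros(config.n_trials))

    theta_specs = [s for s in config.band_specs if s.name == "theta"]
    if not theta_specs:
        theta_specs = [s for s in config.band_specs if 4.0 <= s.center_freq <= 8.0]
    theta_freq = theta_specs[0].center_freq if theta_specs else 5.0

    n_bands = len(config.band_specs)
    amps = np.zeros((config.n_trials, n_bands))
    windows = np.zeros((config.n_trials, n_bands, 2))
    coupling = {s.name: (config.pac_depth if s.respiratory_lock == "theta_phase" else 0.0)
                for s in config.band_specs}

    data = config.noise_scale * power_law_noise((config.n_channels, n), config.noise_exponent, rng)
    sig = data[0]

    for i, sniff in enumerate(sniffs):
        for b, spec in enumerate(config.band_specs):
            a = spec.amplitude
            if config.amplitude_jitter > 0:
                a *= math.exp(rng.normal(0.0, config.amplitude_jitter))
            if correct[i]:
                a *= config.accuracy_gain.get(spec.name, 1.0)
            t_start = sniff + spec.onset_latency
            i0 = int(round(t_start * fs))
            n_seg = int(round(spec.duration * fs))
            i1 = min(i0 + n_seg, n)
            i0c = max(i0, 0)
            seg_t = np.arange(i0c, i1) / fs
            env = a * hann(n_seg)[i0c - i0: i0c - i0 + (i1 - i0c)]
            if spec.respiratory_lock == "theta_phase" and config.pac_depth > 0:
                phi_theta = 2 * np.pi * theta_freq * (seg_t - sniff) + phase_off[i]
                env = env * (1.0 + config.pac_depth * np.cos(phi_theta))
            if spec.name == "theta":
                carrier = np.cos(2 * np.pi * spec.center_freq * (seg_t - sniff) + phase_off[i])
            elif spec.carrier_bandwidth > 0:
                carrier = _narrowband_carrier(len(seg_t), fs, spec.center_freq,
                                              spec.carrier_bandwidth, rng)
            else:
                psi = rng.uniform(0.0, 2 * np.pi) if config.random_burst_phase else 0.0
                carrier = np.cos(2 * np.pi * spec.center_freq * (seg_t - t_start) + psi)
            sig[i0c:i1] += env * carrier
            amps[i, b] = a
            windows[i, b] = (t_start, t_start + spec.duration)
        if config.evoked_amplitude > 0:
            i0 = int(round(sniff * fs))
            n_seg = int(round(0.4 * fs))
            i1 = min(i0 + n_seg, n)
            seg_t = np.arange(i0, i1) / fs
            sig[i0:i1] += (config.evoked_amplitude * hann(n_seg)[: i1 - i0]
                           * np.cos(2 * np.pi * 4.0 * (seg_t - sniff)))

    rec = ContinuousRecording(
        samples=data, sampling_rate=fs,
        channel_labels=["pc"] + [f"decoy{i}" for i in range(1, config.n_channels)],
    )
    rec.airflow = airflow  # same clock as the LFP channels

    # no-odor events: inter-trial inhalations clear of every odor-trial span
    margin = 0.2
    free = []
    for o in breaths.inhale_onsets:
        if o + epoch_pre < 0.5 or o + epoch_post > duration - 0.5:
            continue
        clash = np.any((o + epoch_post >= span_start - margin)
                       & (o + epoch_pre <= span_end + margin))
        if not clash:
            free.append(o)
    free = np.asarray(free)
    n_no = min(config.n_trials, len(free))
    if n_no < len(free):
        free = np.sort(rng.choice(free, size=n_no, replace=False))
    mean_delay = 0.5 * (lo + hi)

    rows = []
    for i, sniff in enumerate(sniffs):
        rows.append((cues[i], sniff, "odor", int(correct[i])))
    for o in free:
        rows.append((o - mean_delay, o, "no_odor", 1))
    rows.sort(key=lambda r: r[1])
    events = pd.DataFrame(rows, columns=["cue_time_s", "sniff_time_s", "condition", "correct"])
    events.insert(0, "trial", np.arange(len(events)))

    truth = GroundTruth(
        band_names=[s.name for s in config.band_specs],
        trial_amplitudes=amps,
        burst_windows=windows,
        coupling_depth=coupling,
        correct=correct,
        sniff_times=sniffs,
        cue_times=cues,
        theta_phase_offsets=phase_off,
        breaths=breaths,
    )
    return rec, events, truth
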