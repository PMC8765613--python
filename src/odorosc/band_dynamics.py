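"""Band-averaged time courses, timing statistics, and circular statistics.

Covers: unweighted band averages over filter-bank centers, per-trial
percent change, pointwise paired condition tests with FDR correction and
onset/offset latencies, bootstrap stability maps, cluster-mass
permutation statistics (initial clustering at p = 0.01, null built by
circularly shifting a random subset of trials, cluster significant above
the 95th percentile of the null max-cluster-mass distribution), and the
respiratory phase of bootstrapped amplitude peaks summarized by PLV and
the Rayleigh test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .respiration import respiratory_phase
from .spectral import TrialTensor

__all__ = [
    "BandDefinition",
    "THETA",
    "BETA",
    "GAMMA",
    "DEFAULT_BANDS",
    "band_average",
    "percent_change",
    "znormalize",
    "PointwiseResult",
    "pointwise_condition_test",
    "bootstrap_band_map",
    "Cluster",
    "ClusterResult",
    "cluster_mass_test",
    "PhaseStats",
    "phase_stats",
    "peak_phase_bootstrap",
    "plv",
    "rayleigh_test",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band lo must be below hi")


THETA = BandDefinition("theta", 4.0, 8.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 150.0)
DEFAULT_BANDS = (THETA, BETA, GAMMA)


def band_average(trials: TrialTensor, band: BandDefinition) -> np.ndarray:
    """Unweighted mean over filter-bank centers with lo <= center <= hi.

    Returns a (n_trials, n_times) series.
    """
    sel = (trials.band_centers >= band.lo) & (trials.band_centers <= band.hi)
    if not sel.any():
        raise ValueError(f"no filter-bank centers inside {band.name} "
                         f"({band.lo}-{band.hi} Hz)")
    return trials.amplitudes[:, sel, :].mean(axis=1)


def band_baseline(trials: TrialTensor, band: BandDefinition):
    """(per-trial baseline means, pooled baseline sd) averaged over the band."""
    if trials.baseline_means is None:
        raise ValueError("trials carry no baseline; run baseline_correct first")
    sel = (trials.band_centers >= band.lo) & (trials.band_centers <= band.hi)
    if not sel.any():
        raise ValueError("no filter-bank centers inside band")
    bmeans = trials.baseline_means[:, sel].mean(axis=1)
    bsd = float(trials.baseline_sd[sel].mean()) if trials.baseline_sd is not None else None
    return bmeans, bsd


def percent_change(series: np.ndarray, baseline_means: np.ndarray) -> np.ndarray:
    """(amplitude - baseline) / baseline, per trial.

    ``series`` holds baseline-corrected amplitudes (trial x time), so the
    formula reduces to series / baseline.  Trials with baseline <= 0 are
    invalid and raise.
    """
    baseline_means = np.asarray(baseline_means, dtype=float)
    if np.any(baseline_means <= 0):
        raise ValueError("baseline means must be positive for percent change")
    return series / baseline_means[:, None]


def znormalize(series: np.ndarray, baseline_sd: float) -> np.ndarray:
    """Scale baseline-corrected series by the pooled baseline sd.

    A shared normalization constant (rather than per-trial sd) preserves
    amplitude differences between trials.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline sd must be positive")
    return series / baseline_sd


@dataclass
class PointwiseResult:
    t: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    mask: np.ndarray
    onset: float | None
    offset: float | None


def pointwise_condition_test(series_a: np.ndarray, series_b: np.ndarray,
                             times: np.ndarray, q: float = 0.05) -> PointwiseResult:
    """Paired t test at each time point, FDR-corrected across time.

    Trials must be paired (equal counts, matched order).  Returns the
    FDR mask and the first/last significant time (onset/offset latency).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have identical shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 trial pairs")
    t, p = stats.ttest_rel(a, b, axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    p_adj = stats.false_discovery_control(p, method="bh")
    mask = p_adj < q
    sig = np.flatnonzero(mask)
    onset = float(times[sig[0]]) if sig.size else None
    offset = float(times[sig[-1]]) if sig.size else None
    return PointwiseResult(t=t, p=p, p_adjusted=p_adj, mask=mask, onset=onset, offset=offset)


def bootstrap_band_map(series: np.ndarray, reps: int = 2000,
                       seed: int | None = None) -> np.ndarray:
    """Repetition x time matrix of trial means over bootstrap resamples."""
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 trials to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    return x[idx].mean(axis=1)


@dataclass
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p: float
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold_p: float
    t_values: np.ndarray
    n_permutations: int
    null_max_mass: np.ndarray

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _tstat(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return x.mean(axis=0) / (sd / np.sqrt(n))


def _extract_clusters(t: np.ndarray, tcrit: float):
    """Contiguous supra-threshold runs (same-sign), as (i0, i1, mass)."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t > tcrit
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        d = np.diff(padded.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for i0, i1 in zip(starts, ends):
            out.append((int(i0), int(i1), float(t[i0:i1].sum())))
    out.sort(key=lambda c: c[0])
    return out


def cluster_mass_test(series: np.ndarray, times: np.ndarray, p_cluster: float = 0.01,
                      n_perm: int = 10_000, seed: int | None = None,
                      random_subset: bool = False) -> ClusterResult:
    """One-sample cluster-mass permutation test against zero.

    t vs 0 at each time point; contiguous runs above the two-sided
    p_cluster threshold form clusters with mass = sum of t.  Null: per
    permutation every trial is circularly shifted by its own random
    offset and the maximal absolute cluster mass recorded.  A cluster is
    significant when its |mass| exceeds the 95th percentile of the null.

    ``random_subset=True`` shifts only a random number of trials
    (k ~ Uniform{1..n}) per permutation instead of all of them; that
    variant is markedly conservative (the null shares its unshifted
    trials with the observed statistic) and is kept only as an option.
    """
    x = np.asarray(series, dtype=float)
    n, n_t = x.shape
    if n < 10:
        raise ValueError("need at least 10 trials")
    tcrit = float(stats.t.ppf(1.0 - p_cluster / 2.0, n - 1))
    tobs = _tstat(x)
    raw = _extract_clusters(tobs, tcrit)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    cols = np.arange(n_t)
    for i in range(n_perm):
        if random_subset:
            k = int(rng.integers(1, n + 1))
            rows = rng.choice(n, size=k, replace=False)
        else:
            rows = np.arange(n)
        shifts = rng.integers(1, n_t, size=len(rows))
        xp = x.copy()
        xp[rows] = x[rows[:, None], (cols[None, :] - shifts[:, None]) % n_t]
        tp = _tstat(xp)
        cl = _extract_clusters(tp, tcrit)
        if cl:
            null_max[i] = max(abs(c[2]) for c in cl)
    cutoff = float(np.percentile(null_max, 95)) if n_perm else np.inf

    clusters = []
    for i0, i1, mass in raw:
        p = (1.0 + float(np.sum(null_max >= abs(mass)))) / (n_perm + 1.0)
        clusters.append(Cluster(start_s=float(times[i0]), end_s=float(times[i1 - 1]),
                                mass=mass, p=p, significant=abs(mass) > cutoff))
    return ClusterResult(clusters=clusters, threshold_p=p_cluster, t_values=tobs,
                         n_permutations=n_perm, null_max_mass=null_max)


@dataclass
class PhaseStats:
    """Circular summary of a set of angles (rad)."""

    angles: np.ndarray
    mean_angle: float
    plv: float
    rayleigh_z: float
    rayleigh_p: float


def plv(angles: np.ndarray) -> float:
    """Phase-locking value: modulus of the mean resultant vector."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle set")
    return float(np.abs(np.exp(1j * angles).mean()))


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: z = n * PLV**2 and its p.

    p uses the standard approximation
    exp(sqrt(1 + 4n + 4(n**2 - R**2)) - (1 + 2n)) with R = n * PLV.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n == 0:
        raise ValueError("empty angle set")
    r = plv(angles)
    big_r = n * r
    z = big_r**2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))


def phase_stats(angles: np.ndarray) -> PhaseStats:
    angles = np.asarray(angles, dtype=float)
    mean_angle = float(np.angle(np.exp(1j * angles).mean()))
    z, p = rayleigh_test(angles)
    return PhaseStats(angles=angles, mean_angle=mean_angle, plv=plv(angles),
                      rayleigh_z=z, rayleigh_p=p)


def peak_phase_bootstrap(band_series: np.ndarray, resp_epochs: np.ndarray,
                         times: np.ndarray, sampling_rate: float, reps: int = 1000,
                         smooth: float = 0.050, window: tuple[float, float] = (0.0, 4.0),
                         seed: int | None = None) -> PhaseStats:
    """Respiratory phase of bootstrapped amplitude peaks.

    Per repetition: resample trials with replacement (keeping the
    pairwise LFP/respiration relationship), average both signals, smooth
    the amplitude with a ``smooth``-second moving average, locate the
    amplitude peak inside ``window`` (ties broken by earliest time), and
    read the Hilbert respiratory phase of the averaged breathing signal
    at that time.
    """
    x = np.asarray(band_series, dtype=float)
    r = np.asarray(resp_epochs, dtype=float)
    if x.shape != r.shape:
        raise ValueError("LFP and respiration epochs must be paired (same shape)")
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    kernel = max(1, int(round(smooth * sampling_rate)))
    sel = (times >= window[0]) & (times <= window[1])
    sel_idx = np.flatnonzero(sel)
    angles = []
    skipped = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        avg = x[idx].mean(axis=0)
        resp = r[idx].mean(axis=0)
        smoothed = uniform_filter1d(avg, kernel, mode="nearest")
        win = smoothed[sel_idx]
        if np.ptp(win) == 0:
            skipped += 1
            continue
        peak = sel_idx[int(np.argmax(win))]
        phase = respiratory_phase(resp)
        angles.append(phase[peak])
    if skipped:
        warnings.warn(f"skipped {skipped} flat bootstrap repetition(s)")
    return phase_stats(np.asarray(angles))
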