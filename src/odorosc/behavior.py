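"""Linking band amplitudes to identification accuracy.

Three analyses: (1) balanced resampling of correct/incorrect trials and
the distribution of amplitude differences; (2) bootstrap correlation
between resampled-set accuracy and mean band amplitude during inhale /
exhale (split at respiratory phase pi/2 of the averaged breathing
signal); (3) linear-SVM separability of correct vs incorrect bootstrap
averages in the (inhale mean, exhale mean) plane, with 5-fold
cross-validated ROC/AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .respiration import respiratory_phase

__all__ = [
    "OutcomeDifference",
    "balanced_outcome_difference",
    "AccuracyCorrelation",
    "bootstrap_accuracy_correlation",
    "fisher_z",
    "inhale_exhale_split",
    "window_means",
    "ClassifierEval",
    "svm_separability",
    "fit_linear_classifier",
]


@dataclass
class OutcomeDifference:
    """Distribution of balanced correct-incorrect amplitude differences.

    ``t``/``p`` are the one-sample t test of the bootstrap replicates
    against 0 (note: its effective power grows with the repetition count,
    so it flags any nonzero sample difference); ``ci_low``/``ci_high``
    are the 2.5/97.5 percentiles of the bootstrap distribution, the
    calibrated way to call a difference significant.
    """

    band_names: list[str]
    differences: np.ndarray        # (n_bands, reps)
    t: np.ndarray                  # one-sample t vs 0, per band
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    paired_t: dict[tuple[str, str], tuple[float, float]]

    def significant_positive(self, name: str) -> bool:
        """True when the bootstrap 95% CI of the difference excludes 0 from above."""
        return bool(self.ci_low[self.band_names.index(name)] > 0)

    def significant(self, name: str) -> bool:
        i = self.band_names.index(name)
        return bool(self.ci_low[i] > 0 or self.ci_high[i] < 0)


def balanced_outcome_difference(band_series: dict[str, np.ndarray], correct: np.ndarray,
                                n_each: int = 71, reps: int = 200,
                                seed: int | None = None) -> OutcomeDifference:
    """Resample equal numbers of correct and incorrect trials (with
    replacement) and collect per-band mean-amplitude differences.

    band_series maps band name -> (n_trials, n_times) z-normalized
    series; per repetition and band the mean over the full window is
    taken per outcome and the difference (correct - incorrect) recorded.
    """
    correct = np.asarray(correct, dtype=bool)
    idx_c = np.flatnonzero(correct)
    idx_i = np.flatnonzero(~correct)
    if idx_c.size == 0 or idx_i.size == 0:
        raise ValueError("need at least one trial per outcome; lower n_each or "
                         "check the correct flags")
    names = list(band_series)
    trial_means = np.stack([np.asarray(band_series[k], dtype=float).mean(axis=1)
                            for k in names])                    # (B, n_trials)
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
    # each class's resampling stream is keyed by its trial set (not its
    # role), so swapping the outcome labels exactly negates the result
    picks = {}
    for pool in (idx_c, idx_i):
        rng = np.random.default_rng([int(seed), int(pool[0]), int(pool.size)])
        picks[pool.tobytes()] = pool[rng.integers(0, pool.size, size=(reps, n_each))]
    mean_c = trial_means[:, picks[idx_c.tobytes()]].mean(axis=2)  # (B, reps)
    mean_i = trial_means[:, picks[idx_i.tobytes()]].mean(axis=2)
    diffs = mean_c - mean_i
    t, p = stats.ttest_1samp(diffs, 0.0, axis=1)
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5], axis=1)
    paired = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            tt, pp = stats.ttest_rel(diffs[i], diffs[j])
            paired[(names[i], names[j])] = (float(tt), float(pp))
    return OutcomeDifference(band_names=names, differences=diffs, t=t, p=p,
                             ci_low=ci_low, ci_high=ci_high, paired_t=paired)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform, monotone on (-1, 1)."""
    r = np.asarray(r, dtype=float)
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def inhale_exhale_split(resp_epochs: np.ndarray, times: np.ndarray) -> float:
    """Inhale->exhale transition time of the averaged breathing signal.

    Defined as the first post-onset time at which the Hilbert respiratory
    phase of the trial-averaged airflow crosses +pi/2.
    """
    avg = np.asarray(resp_epochs, dtype=float).mean(axis=0)
    phase = respiratory_phase(avg)
    post = np.flatnonzero((times[:-1] >= 0) & (phase[:-1] < np.pi / 2) & (phase[1:] >= np.pi / 2))
    if post.size == 0:
        raise ValueError("no pi/2 phase crossing after onset in averaged respiration")
    return float(times[post[0] + 1])


def window_means(series: np.ndarray, times: np.ndarray,
                 window: tuple[float, float]) -> np.ndarray:
    """Per-trial mean over a time window (half-open [lo, hi))."""
    sel = (times >= window[0]) & (times < window[1])
    if not sel.any():
        raise ValueError("empty time window")
    return np.asarray(series, dtype=float)[:, sel].mean(axis=1)


@dataclass
class AccuracyCorrelation:
    """Bootstrap accuracy-amplitude correlation distributions."""

    band_names: list[str]
    window_names: tuple[str, str]
    r: np.ndarray                  # (n_bands, 2, outer)
    t: np.ndarray                  # t vs 0 per band x window
    p: np.ndarray
    n_skipped: int = 0


def bootstrap_accuracy_correlation(band_window_means: dict[str, np.ndarray],
                                   correct: np.ndarray, inner: int = 1000,
                                   outer: int = 50, seed: int | None = None
                                   ) -> AccuracyCorrelation:
    """Correlate resampled-set accuracy with mean band amplitudes.

    band_window_means maps band name -> (n_trials, 2) per-trial mean
    amplitudes in the (inhale, exhale) windows.  Inner loop: resample the
    trial set with replacement, compute its accuracy (fraction correct,
    duplicates counted) and its mean amplitudes, giving ``inner``
    (accuracy, amplitude) points; Pearson r per band x window.  Outer
    loop repeats to yield a distribution of r values.  Repetitions with
    degenerate (constant) accuracy are skipped.
    """
    correct = np.asarray(correct, dtype=float)
    n = correct.size
    names = list(band_window_means)
    feats = np.stack([np.asarray(band_window_means[k], dtype=float) for k in names])  # (B, n, 2)
    rng = np.random.default_rng(seed)
    r_out = np.full((len(names), 2, outer), np.nan)
    skipped = 0
    for o in range(outer):
        idx = rng.integers(0, n, size=(inner, n))
        acc = correct[idx].mean(axis=1)
        if np.ptp(acc) == 0:
            skipped += 1
            continue
        amp = feats[:, idx, :].mean(axis=2)          # (B, inner, 2)
        acc_c = acc - acc.mean()
        denom_a = np.sqrt((acc_c**2).sum())
        for b in range(len(names)):
            for w in range(2):
                v = amp[b, :, w]
                v_c = v - v.mean()
                denom_v = np.sqrt((v_c**2).sum())
                if denom_v == 0:
                    continue
                r_out[b, w, o] = (acc_c * v_c).sum() / (denom_a * denom_v)
    if skipped:
        warnings.warn(f"skipped {skipped} outer repetition(s) with degenerate accuracy")
    t = np.zeros((len(names), 2))
    p = np.ones((len(names), 2))
    for b in range(len(names)):
        for w in range(2):
            vals = r_out[b, w][np.isfinite(r_out[b, w])]
            if vals.size > 1:
                t[b, w], p[b, w] = stats.ttest_1samp(vals, 0.0)
    return AccuracyCorrelation(band_names=names, window_names=("inhale", "exhale"),
                               r=r_out, t=t, p=p, n_skipped=skipped)


@dataclass
class ClassifierEval:
    """ROC of a linear maximum-margin classifier on bootstrap features."""

    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    optimized_accuracy: float
    cv_folds: int = 5
    n_dropped: int = 0
    features: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)


def _bootstrap_features(series: np.ndarray, baseline_means: np.ndarray,
                        times: np.ndarray, pick: np.ndarray, inhale, exhale):
    """Percent-change (inhale mean, exhale mean) of one bootstrap average."""
    win_i = window_means(series, times, inhale)
    win_e = window_means(series, times, exhale)
    base = baseline_means[pick].mean()
    if base <= 0:
        return None
    return np.array([win_i[pick].mean() / base, win_e[pick].mean() / base])


def svm_separability(series: np.ndarray, baseline_means: np.ndarray, times: np.ndarray,
                     correct: np.ndarray, n_each: int = 30, reps: int = 500,
                     inhale: tuple[float, float] = (0.0, 1.5),
                     exhale: tuple[float, float] = (1.5, 3.0),
                     folds: int = 5, c_penalty: float = 1.0,
                     seed: int | None = None) -> ClassifierEval:
    """Separability of correct vs incorrect bootstrap averages.

    ``series`` is the baseline-corrected (n_trials, n_times) band series;
    per repetition and class, ``n_each`` trials are resampled with
    replacement, the trial-averaged percent-change series is reduced to
    (inhale mean, exhale mean), and the resulting 2 x reps points are fed
    to a linear SVM with ``folds``-fold cross-validation.
    """
    correct = np.asarray(correct, dtype=bool)
    idx_c = np.flatnonzero(correct)
    idx_i = np.flatnonzero(~correct)
    if idx_c.size == 0 or idx_i.size == 0:
        raise ValueError("both outcome classes must be present")
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    dropped = 0
    for klass, pool in ((1, idx_c), (0, idx_i)):
        for _ in range(reps):
            pick = rng.choice(pool, size=n_each, replace=True)
            f = _bootstrap_features(series, baseline_means, times, pick, inhale, exhale)
            if f is None or not np.all(np.isfinite(f)):
                dropped += 1
                continue
            feats.append(f)
            labels.append(klass)
    if dropped:
        warnings.warn(f"dropped {dropped} repetition(s) with non-finite features")
    x = np.asarray(feats)
    y = np.asarray(labels)
    ev = fit_linear_classifier(x, y, folds=folds, c_penalty=c_penalty, seed=seed)
    ev.n_dropped = dropped
    return ev


def fit_linear_classifier(x: np.ndarray, y: np.ndarray, folds: int = 5,
                          c_penalty: float = 1.0, seed: int | None = None) -> ClassifierEval:
    """Linear SVM with cross-validated decision scores -> ROC, AUC, and the
    accuracy at the Youden-optimal ROC point."""
    clf = SVC(kernel="linear", C=c_penalty)
    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=None if seed is None else int(seed) % (2**32))
    scores = cross_val_predict(clf, x, y, cv=cv, method="decision_function")
    fpr, tpr, thresholds = roc_curve(y, scores)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    youden = int(np.argmax(tpr - fpr))
    thr = thresholds[youden]
    acc = float(np.mean((scores >= thr) == y.astype(bool)))
    return ClassifierEval(roc_fpr=fpr, roc_tpr=tpr, auc=roc_auc,
                          optimized_accuracy=acc, cv_folds=folds,
                          features=x, labels=y)
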