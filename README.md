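# odorosc

Sniff-aligned analysis of odor-driven oscillations in intracranial LFP
recordings, packaged as a tested, reusable pipeline with a bundled
synthetic data generator.

The pipeline covers:

- **synth** — sniff-locked synthetic LFP recordings with ground truth:
  asymmetric quasi-periodic nasal airflow, 1/f background noise,
  per-trial theta/beta/gamma bursts with configurable latencies,
  theta-phase-locked gamma envelopes (cross-frequency coupling depth
  `pac_depth`), and correct/incorrect trial amplitude gains.
- **preprocess** — two-pass zero-phase FIR low-pass (235 Hz), band-stop
  at 60 Hz and harmonics (4 Hz width), resampling to 500 Hz, common
  average reference.
- **respiration** — breath feature detection (inhale/exhale onsets,
  peaks, troughs) and Hilbert respiratory phase (inhale peak = 0,
  inhale→exhale transition = +pi/2).
- **spectral** — 100-band log-spaced Hilbert filter bank (1–200 Hz,
  first 95 kept), sniff-aligned epochs ([−2, 4] s), pre-cue baseline
  correction ([−0.55, −0.05] s), circular-shift permutation z-maps,
  condition-label permutation difference maps, evoked/induced
  decomposition.
- **band_dynamics** — theta/beta/gamma band averages, percent change,
  pointwise paired tests with FDR and onset/offset latencies, bootstrap
  stability maps, cluster-mass permutation timing statistics, and
  respiratory phase of bootstrapped amplitude peaks (PLV, Rayleigh test).
- **behavior** — balanced correct/incorrect resampling differences,
  bootstrap accuracy–amplitude correlations (inhale/exhale split at
  respiratory phase pi/2), linear-SVM separability with 5-fold
  cross-validated ROC/AUC.
- **pac** — KL-based modulation index of theta phase vs 47 amplitude
  bands (13.05–153.04 Hz), normalized by circular-shift and
  trial-order-shuffle permutation nulls with FDR across bands.

## CLI

```sh
odorosc synth generate --out-dir data --seed 7
odorosc preprocess run --in data/recording.npz --out data/clean.npz --target-rate 500
odorosc respiration detect --in airflow.tsv --out breaths.tsv
odorosc spectral zmap --rec data/clean.npz --events data/events.tsv --condition odor --n-perm 10000 --seed 7
odorosc dynamics clusters --rec data/clean.npz --events data/events.tsv --band beta --n-perm 10000 --seed 7
odorosc behavior svm --rec data/clean.npz --events data/events.tsv --seed 7
odorosc pac mi --rec data/clean.npz --events data/events.tsv --null circular-shift --n-perm 1000 --seed 7
odorosc run --config cfg.json --out-dir out --seed 7
```

Continuous recordings travel as `.npz` array containers (arrays:
`samples`, `sampling_rate`, `start_time`, `channel_labels`, optional
`airflow`); events as TSV with columns `trial, cue_time_s, sniff_time_s,
condition, correct`; results as TSV/JSON. All timestamps are absolute
seconds on the recording clock and every random procedure takes an
explicit seed, so reruns are byte-identical.

`odorosc run` executes the whole pipeline from a single JSON config
(see `odorosc.pipeline.PipelineConfig` for the keys); CLI flags override
the file, and the resolved config plus a run report are written next to
the outputs.

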