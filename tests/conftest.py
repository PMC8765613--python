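import numpy as np
import pytest

from odorosc import spectral, synth


def desk_config(seed: int = 0, **kwargs) -> synth.SynthConfig:
    """Desk-scale synthetic config: short intertrial intervals and cue
    delays so recordings stay small; burst structure left at defaults."""
    defaults = dict(
        n_trials=40,
        intertrial_interval=(9.0, 0.8),
        cue_to_sniff_delay=(2.0, 3.0),
        lead_in=8.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return synth.SynthConfig(**defaults)


@pytest.fixture(scope="session")
def bank() -> spectral.FilterBank:
    return spectral.build_filter_bank()


@pytest.fixture(scope="session")
def small_recording():
    """One small synthetic recording shared across tests (read-only)."""
    cfg = desk_config(seed=11, n_trials=20)
    rec, events, truth = synth.generate_recording(cfg)
    return cfg, rec, events, truth


@pytest.fixture(scope="session")
def odor_trials(small_recording, bank):
    """Baseline-corrected trial tensor over theta/beta/gamma-relevant bands."""
    cfg, rec, events, truth = small_recording
    sel = np.flatnonzero(((bank.kept_centers >= 4) & (bank.kept_centers <= 8))
                         | (bank.kept_centers > 13))
    stack = spectral.amplitude_stack(rec.samples[0], rec.sampling_rate, bank,
                                     band_indices=sel)
    odor = events[events["condition"] == "odor"].reset_index(drop=True)
    trials = spectral.epoch(stack, odor["sniff_time_s"].to_numpy(),
                            cfg.epoch_window, meta=odor)
    trials = spectral.baseline_correct(trials, stack,
                                       trials.meta["cue_time_s"].to_numpy(),
                                       cfg.baseline_window)
    return cfg, stack, trials, truth
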