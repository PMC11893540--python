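"""Shared fixtures: small rendered sessions reused across test modules."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import gammasleep as gs
from gammasleep.preprocess import (epoch_and_label, preprocess_recording,
                                   reject_epochs)

logging.disable(logging.WARNING)


def quiet_config(**over) -> gs.SimulationConfig:
    """Config with artifacts off unless a test turns them on."""
    over.setdefault("artifact_rates", {"emg": 0, "ocular": 0, "movement": 0})
    return gs.SimulationConfig(**over)


@pytest.fixture(scope="session")
def control_night():
    """One short covered-LED control night, processed to an EpochSet."""
    stages = ["W"] * 4 + ["N2"] * 10 + ["N3"] * 8 + ["REM"] * 8
    cfg = quiet_config(night_duration=30.0 * len(stages),
                       condition="control", rng_seed=42)
    hyp = gs.hypnogram_from_stages(stages, cfg)
    rec, hyp, stim, truth = gs.render_night(cfg, hypnogram=hyp)
    proc = preprocess_recording(rec)
    es = reject_epochs(epoch_and_label(proc, hyp, stim, "control", 2))
    return {"config": cfg, "recording": rec, "processed": proc,
            "hypnogram": hyp, "stim": stim, "truth": truth, "epochs": es}


@pytest.fixture(scope="session")
def experimental_night():
    """Short stimulated night (reduced fade-in so full illuminance is
    reached quickly), processed to an EpochSet."""
    stages = ["W"] * 2 + ["N3"] * 16 + ["N2"] * 12 + ["REM"] * 10
    cfg = quiet_config(night_duration=30.0 * len(stages),
                       condition="experimental", fade_in_duration=60.0,
                       rng_seed=43)
    hyp = gs.hypnogram_from_stages(stages, cfg)
    rec, hyp, stim, truth = gs.render_night(cfg, hypnogram=hyp)
    proc = preprocess_recording(rec)
    es = reject_epochs(epoch_and_label(proc, hyp, stim, "experimental", 3))
    return {"config": cfg, "recording": rec, "processed": proc,
            "hypnogram": hyp, "stim": stim, "truth": truth, "epochs": es}


def toy_epochset(sampling_rate: float = 600.0, n_epochs: int = 20,
                 condition: str = "experimental") -> gs.EpochSet:
    """Hand-built clean EpochSet (flat small-noise epochs, full metadata)."""
    rng = np.random.default_rng(0)
    spe = int(round(30 * sampling_rate))
    data = rng.standard_normal((n_epochs, spe))
    meta = pd.DataFrame({
        "epoch_index": np.arange(n_epochs),
        "stage": "N2",
        "certainty": 0.95,
        "condition": condition,
        "session": 3,
        "stim_seconds": 30.0,
    })
    return gs.EpochSet(data, sampling_rate, meta)
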