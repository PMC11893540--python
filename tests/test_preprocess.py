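"""Filtering, channel/epoch rejection, ROI referencing and bin assignment."""
import numpy as np
import pandas as pd
import pytest

import gammasleep as gs
from gammasleep.preprocess import (assign_condition_bins, bandpass_filter,
                                   epoch_and_label, reject_bad_channels,
                                   reject_epochs,
                                   roi_average_and_rereference)
from gammasleep.types import ALL_CHANNELS, MASTOIDS, ROI_CHANNELS

from conftest import quiet_config, toy_epochset

FS = 1000.0


def _rec(data, labels, fs=FS):
    return gs.Recording(np.asarray(data, dtype=float), fs, labels)


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

def test_bandpass_preserves_40hz_and_removes_dc():
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * 40 * t) + 100.0
    out = bandpass_filter(_rec(x, ("Oz",))).samples[0]
    mid = slice(int(2 * FS), int(8 * FS))
    amp = (out[mid].max() - out[mid].min()) / 2
    assert amp == pytest.approx(1.0, rel=0.02)      # < 2 % attenuation
    assert abs(out[mid].mean()) < 1.0               # 100 uV offset removed


def test_bandpass_attenuates_350hz_by_20db():
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * 350 * t)
    out = bandpass_filter(_rec(x, ("Oz",))).samples[0]
    # lock-in projection isolates the 350 Hz component from the slow
    # high-pass edge transient
    mid = slice(int(2 * FS), int(8 * FS))
    amp = 2 * np.abs(np.mean(out[mid]
                             * np.exp(-2j * np.pi * 350 * t[mid])))
    atten_db = -20 * np.log10(amp + 1e-30)
    assert atten_db > 20
    # cross-check against the designed frequency response itself
    from scipy import signal as sps
    sos = sps.butter(4, [0.16, 300.0], btype="bandpass", output="sos", fs=FS)
    _, h = sps.sosfreqz(sos, worN=[350.0], fs=FS)
    assert -20 * np.log10(np.abs(h[0]) ** 2) > 20   # forward-backward gain


def test_bandpass_low_fs_drops_lowpass_with_warning(caplog):
    x = np.random.default_rng(0).standard_normal(int(10 * 600))
    import logging
    logging.disable(logging.NOTSET)
    with caplog.at_level("WARNING", logger="gammasleep.preprocess"):
        bandpass_filter(_rec(x, ("Oz",), fs=600.0))
    logging.disable(logging.WARNING)
    assert any("Nyquist" in r.message for r in caplog.records)
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_filter(_rec(x, ("Oz",), fs=600.0), allow_clip=False)


def test_bandpass_validates_edges():
    x = np.zeros(1000)
    with pytest.raises(ValueError):
        bandpass_filter(_rec(x, ("Oz",)), low=300.0, high=0.16)


# ---------------------------------------------------------------------------
# bad channels
# ---------------------------------------------------------------------------

def _eeg_recording(rng, scale_map=None):
    data = rng.standard_normal((8, 4000)) * 10.0
    labels = ROI_CHANNELS + MASTOIDS
    if scale_map:
        for lab, s in scale_map.items():
            data[labels.index(lab)] *= s
    return _rec(data, labels)


def test_flat_channel_is_flagged():
    rng = np.random.default_rng(0)
    rec = _eeg_recording(rng, {"O1": 0.0})
    _, flagged = reject_bad_channels(rec)
    assert flagged == ["O1"]


def test_iid_channels_none_flagged():
    rng = np.random.default_rng(1)
    _, flagged = reject_bad_channels(_eeg_recording(rng))
    assert flagged == []


def test_high_variance_outlier_flagged_matches_robust_z_oracle():
    rng = np.random.default_rng(2)
    rec = _eeg_recording(rng, {"POz": 20.0})
    _, flagged = reject_bad_channels(rec)
    assert flagged == ["POz"]
    # oracle: robust z of log-variance computed directly
    logv = np.log([rec.channel(c).var() for c in ROI_CHANNELS])
    med = np.median(logv)
    mad = max(np.median(np.abs(logv - med)), 0.05)
    z = (logv - med) / (1.4826 * mad)
    assert abs(z[ROI_CHANNELS.index("POz")]) > 5


def test_all_roi_flagged_raises():
    data = np.zeros((8, 4000))
    data[6:] = np.random.default_rng(0).standard_normal((2, 4000))
    rec = _rec(data, ROI_CHANNELS + MASTOIDS)
    with pytest.raises(ValueError, match="manual review"):
        reject_bad_channels(rec)


# ---------------------------------------------------------------------------
# ROI average and re-reference
# ---------------------------------------------------------------------------

def test_roi_average_identity_and_negated_mastoid():
    n = 1000
    s = np.sin(np.linspace(0, 10, n))
    data = np.zeros((8, n))
    labels = ROI_CHANNELS + MASTOIDS
    for c in ROI_CHANNELS:
        data[labels.index(c)] = s
    out = roi_average_and_rereference(_rec(data, labels))
    assert np.allclose(out.samples[0], s)
    data2 = np.zeros((8, n))
    for c in MASTOIDS:
        data2[labels.index(c)] = s
    out2 = roi_average_and_rereference(_rec(data2, labels))
    assert np.allclose(out2.samples[0], -s)


def test_roi_average_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    labels = ROI_CHANNELS + MASTOIDS
    data = rng.standard_normal((8, 2000))
    out = roi_average_and_rereference(_rec(data, labels))
    expected = np.zeros(2000)
    for i in range(2000):                      # deliberate per-sample loop
        roi = sum(data[labels.index(c), i] for c in ROI_CHANNELS) / 6.0
        mast = (data[labels.index("A1"), i]
                + data[labels.index("A2"), i]) / 2.0
        expected[i] = roi - mast
    assert np.allclose(out.samples[0], expected, atol=1e-12)


def test_missing_mastoid_raises():
    labels = ROI_CHANNELS + ("A1",)
    data = np.zeros((7, 100))
    with pytest.raises(ValueError, match="mastoid"):
        roi_average_and_rereference(_rec(data, labels))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def test_epoch_count_and_stim_overlap():
    fs = 600.0
    n = int(300 * fs)
    rec = gs.Recording(np.zeros((1, n)), fs, ("ROI",))
    hyp = gs.hypnogram_from_stages(["N2"] * 10, certainty=[0.9] * 10)
    illum = np.zeros(n, np.float32)
    illum[:int(80 * fs)] = 1.0          # visible 0-80 s: epochs 0-1 full,
    vis = illum > 0                     # epoch 2 gets 20 s
    stim = gs.StimLog(fs, illum, vis, np.ones(n, bool))
    es = epoch_and_label(rec, hyp, stim, "experimental", 3)
    assert es.n_epochs == 10
    assert np.allclose(es.meta["stim_seconds"][:4], [30, 30, 20, 0])


def test_short_recording_yields_empty_epochset_with_warning():
    rec = gs.Recording(np.zeros((1, 100)), 600.0, ("ROI",))
    hyp = gs.hypnogram_from_stages(["N2"] * 4, certainty=[0.9] * 4)
    with pytest.warns(UserWarning, match="shorter"):
        es = epoch_and_label(rec, hyp, None, "control", 2)
    assert es.n_epochs == 0


# ---------------------------------------------------------------------------
# epoch rejection
# ---------------------------------------------------------------------------

def test_rejection_rules_and_reason_codes():
    es = toy_epochset()
    es.data[3, 100] = 700.0
    es.data[3, 200] = -700.0                     # p2p 1.4 mV
    es.meta.loc[7, "certainty"] = 0.49
    es.meta.loc[11, "stim_seconds"] = 24.0
    out = reject_epochs(es)
    rejected = out.meta.loc[out.meta["rejected"]]
    assert set(rejected["epoch_index"]) == {3, 7, 11}
    reasons = dict(zip(rejected["epoch_index"],
                       rejected["reject_reasons"]))
    assert reasons[3] == "amplitude"
    assert reasons[7] == "certainty"
    assert reasons[11] == "stim_duration"


def test_stim_duration_rule_vacuous_for_control():
    es = toy_epochset(condition="control")
    es.meta.loc[5, "stim_seconds"] = 0.0         # LEDs covered: no rule
    out = reject_epochs(es)
    assert not out.meta["rejected"].any()


def test_rejection_is_idempotent():
    es = toy_epochset()
    es.data[0, 10] = 1500.0
    once = reject_epochs(es)
    twice = reject_epochs(once)
    pd.testing.assert_frame_equal(once.meta, twice.meta)


def test_boundary_p2p_exactly_1mv_is_kept():
    es = toy_epochset()
    es.data[2] = 0.0
    es.data[2, 0], es.data[2, 1] = 500.0, -500.0     # exactly 1 mV
    out = reject_epochs(es)
    assert not out.meta.loc[2, "rejected"]


# ---------------------------------------------------------------------------
# condition x stage bins
# ---------------------------------------------------------------------------

def _session_epochs(stages, condition, session):
    n = len(stages)
    data = np.zeros((n, int(30 * 600)))
    meta = pd.DataFrame({
        "epoch_index": np.arange(n), "stage": stages, "certainty": 0.9,
        "condition": condition, "session": session, "stim_seconds": 30.0,
    })
    return gs.EpochSet(data, 600.0, meta)


def test_bin_assignment_follows_session_routing():
    sessions = {
        1: _session_epochs(["W", "W", "N1"], "experimental", 1),
        2: _session_epochs(["W", "N2", "N3", "REM", "N1"], "control", 2),
        3: _session_epochs(["W", "N2", "N3", "REM"], "experimental", 3),
    }
    bins = assign_condition_bins(sessions)
    assert bins[("experimental", "W")].n_epochs == 2       # session 1 only
    assert ("experimental", "W") in bins
    # session 3 W epochs appear in no experimental bin
    for key, es in bins.items():
        if key[0] == "experimental" and key[1] != "W":
            assert (es.meta["session"] == 3).all()
    assert bins[("control", "REM")].meta["session"].eq(2).all()
    # N1 excluded everywhere
    for es in bins.values():
        assert not (es.meta["stage"] == "N1").any()


def test_bins_form_a_partition_of_analysis_epochs():
    sessions = {
        1: _session_epochs(["W"] * 3, "experimental", 1),
        2: _session_epochs(["W", "N2", "N2", "N3", "REM"], "control", 2),
        3: _session_epochs(["N2", "N3", "REM", "W"], "experimental", 3),
    }
    bins = assign_condition_bins(sessions)
    seen = set()
    for (cond, stage), es in bins.items():
        for _, row in es.meta.iterrows():
            key = (row["session"], row["epoch_index"])
            assert key not in seen          # no epoch in two bins
            seen.add(key)
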