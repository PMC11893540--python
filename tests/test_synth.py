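"""Synthetic-night generator: hypnogram dynamics, stimulation schedule,
signal rendering and ground-truth plumbing."""
import numpy as np
import pytest

import gammasleep as gs
from gammasleep.synth import SimulationConfig, build_stim_schedule, \
    build_wake_schedule, generate_hypnogram, hypnogram_from_stages, \
    render_night
from gammasleep.types import EPOCH_SECONDS, ROI_CHANNELS, STAGES

from conftest import quiet_config


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(sampling_rate=441.0),            # not a multiple of 40
    dict(duty_cycle=0.0),
    dict(duty_cycle=1.0),
    dict(night_duration=100.0),           # not a multiple of 30
    dict(stage_ssvep_amplitude={"W": -1.0}),
    dict(condition="sham"),
])
def test_config_rejects_invalid_values(bad):
    with pytest.raises(ValueError):
        SimulationConfig(**bad)


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def test_absorbing_transition_matrix_keeps_initial_stage():
    cfg = SimulationConfig(night_duration=600.0, rng_seed=0)
    hyp = generate_hypnogram(cfg, transition_matrix=np.eye(5),
                             initial_stage="W")
    assert (hyp.stages == "W").all()
    assert np.all((hyp.certainty >= 0) & (hyp.certainty <= 1))


def test_hypnogram_deterministic_under_seed():
    cfg = SimulationConfig(night_duration=7200.0, rng_seed=5)
    h1 = generate_hypnogram(cfg)
    h2 = generate_hypnogram(cfg)
    assert (h1.stages == h2.stages).all()
    assert np.array_equal(h1.certainty, h2.certainty)


def test_default_nights_have_n3_and_healthy_n2_share():
    """Over 50 seeded nights, %N2 of sleep time is near the healthy-young
    profile (~53 %, within +-10 percentage points) and every night contains
    at least one N3 bout so the stimulation trigger can fire."""
    shares = []
    for seed in range(50):
        cfg = SimulationConfig(night_duration=28800.0, rng_seed=seed)
        hyp = generate_hypnogram(cfg)
        assert "N3" in hyp.stages
        sleep = np.isin(hyp.stages, ("N1", "N2", "N3", "REM")).sum()
        shares.append(100.0 * np.sum(hyp.stages == "N2") / sleep)
    assert abs(np.mean(shares) - 53.0) <= 10.0


def test_hypnogram_rejects_tiny_nights():
    with pytest.raises(ValueError):
        generate_hypnogram(SimulationConfig(night_duration=90.0))


# ---------------------------------------------------------------------------
# stimulation schedule
# ---------------------------------------------------------------------------

def _spe(cfg):
    return int(round(EPOCH_SECONDS * cfg.sampling_rate))


def test_uninterrupted_n3_night_ramps_once():
    cfg = SimulationConfig(night_duration=600.0, rng_seed=0)
    hyp = hypnogram_from_stages(["N3"] * 20, cfg)
    stim = build_stim_schedule(hyp, cfg)
    fs = cfg.sampling_rate
    illum = np.asarray(stim.illuminance, dtype=float)
    assert illum[0] == 0.0
    # raised-cosine midpoint: half the target at t = 150 s
    assert illum[int(150 * fs)] == pytest.approx(0.5, abs=1e-6)
    # ramp complete at t = 300 s, constant target afterwards
    assert np.all(illum[int(300 * fs):] == pytest.approx(1.0))
    assert not stim.never_triggered
    # monotone ramp: no interruption anywhere in the fade-in
    assert np.all(np.diff(illum[:int(300 * fs)]) >= -1e-9)


def test_arousal_fades_out_and_resumes_after_six_clean_epochs():
    cfg = SimulationConfig(night_duration=30.0 * 29, rng_seed=0)
    hyp = hypnogram_from_stages(["N3"] * 12 + ["W"] + ["N2"] * 6
                                + ["N3"] * 10, cfg)
    stim = build_stim_schedule(hyp, cfg)
    fs = cfg.sampling_rate
    illum = np.asarray(stim.illuminance, dtype=float)
    # full illuminance just before the W epoch (ramp done at 300 s < 360 s)
    assert illum[int(360 * fs) - 1] == pytest.approx(1.0)
    # 5 s cosine fade-out within the W epoch, then dark
    assert illum[int(362.5 * fs)] == pytest.approx(0.5, abs=0.01)
    assert np.all(illum[int(365 * fs):int(570 * fs)] == 0.0)
    # restart at the start of the 7th epoch after W (six clean epochs seen)
    restart = int(570 * fs)
    assert illum[restart - 1] == 0.0
    assert illum[restart + 1] > 0.0
    # and it restarts with a fresh fade-in, not at full level
    assert illum[restart + int(150 * fs)] == pytest.approx(0.5, abs=1e-6)


def test_wake_and_n1_epochs_are_dark_after_fade_tail():
    cfg = SimulationConfig(night_duration=30.0 * 40, rng_seed=3)
    hyp = generate_hypnogram(cfg)
    stim = build_stim_schedule(hyp, cfg)
    fs, spe = cfg.sampling_rate, _spe(cfg)
    fade = int(cfg.fade_out_duration * fs)
    illum = np.asarray(stim.illuminance, dtype=float)
    for k, stage in enumerate(hyp.stages):
        if stage in ("W", "N1"):
            seg = illum[k * spe + fade:(k + 1) * spe]
            assert np.all(seg == 0.0)


def test_no_n3_night_is_flagged_not_an_error():
    cfg = SimulationConfig(night_duration=600.0, rng_seed=0)
    hyp = hypnogram_from_stages(["W"] * 10 + ["N2"] * 10, cfg)
    with pytest.warns(UserWarning, match="no N3"):
        stim = build_stim_schedule(hyp, cfg)
    assert stim.never_triggered
    assert np.all(np.asarray(stim.illuminance) == 0.0)


def test_control_schedule_runs_circuit_with_no_visible_light():
    cfg = SimulationConfig(night_duration=600.0, condition="control",
                           rng_seed=0)
    hyp = hypnogram_from_stages(["N3"] * 20, cfg)
    stim = build_stim_schedule(hyp, cfg)
    assert np.all(~stim.visible)
    assert np.all(stim.circuit)
    assert np.all(np.asarray(stim.illuminance) == 0.0)
    # electrical clock still produces 40 Hz LED-ON edges
    edges = stim.led_on_edges("circuit")
    assert edges.size == int(600 * 40)
    assert np.all(np.diff(edges) == stim.period_samples)


def test_led_clock_runs_at_40hz_during_stimulation():
    cfg = SimulationConfig(night_duration=600.0, rng_seed=0)
    stim = build_wake_schedule(cfg)
    led = stim.led_state()
    p = stim.period_samples
    # one ON block per 25 ms cycle, duty ~50 %
    cycles = led[:(len(led) // p) * p].reshape(-1, p)
    assert np.all(cycles.sum(axis=1) == stim.on_samples)
    assert abs(stim.on_samples / p - 0.5) <= 0.5 / p


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_noiseless_injection_is_periodic_with_exact_amplitude():
    """With all noise silenced, the ROI signal during full illuminance is
    exactly 25 ms periodic with the configured peak-to-trough amplitude."""
    A = 0.5
    cfg = quiet_config(night_duration=120.0, rng_seed=0,
                       background_rms_uv=0.0, white_noise_rms_uv=0.0,
                       stage_oscillations={s: [] for s in STAGES},
                       stage_ssvep_amplitude={s: A for s in STAGES})
    rec, hyp, stim, truth = render_night(cfg, wake_session=True)
    roi = rec.channel("Oz")
    p = stim.period_samples
    cycles = roi.reshape(-1, p)
    assert np.allclose(cycles, cycles[0], atol=1e-8)        # periodic
    assert cycles[0].max() - cycles[0].min() == pytest.approx(A, rel=1e-8)


def test_render_is_deterministic_and_control_mask_dark():
    cfg = quiet_config(night_duration=300.0, condition="control", rng_seed=9)
    r1, h1, s1, t1 = render_night(cfg)
    r2, h2, s2, t2 = render_night(cfg)
    assert np.array_equal(r1.samples, r2.samples)
    assert (h1.stages == h2.stages).all()
    assert not t1.stim_on_mask.any()     # no light visible in control


def test_noiseless_amplitude_doubling_doubles_recovered_amplitude():
    amps = {}
    for A in (0.3, 0.6):
        cfg = quiet_config(night_duration=120.0, rng_seed=0,
                           background_rms_uv=0.0, white_noise_rms_uv=0.0,
                           stage_oscillations={s: [] for s in STAGES},
                           stage_ssvep_amplitude={s: A for s in STAGES})
        rec, hyp, stim, _ = render_night(cfg, wake_session=True)
        from gammasleep.ssvep import average_ssvep, segment_at_led_on
        segs = segment_at_led_on(rec.channel("O1"), stim)
        amps[A] = average_ssvep(segs).ssvep_amp
    assert amps[0.6] == pytest.approx(2 * amps[0.3], rel=1e-9)


def test_control_led_artifact_average_matches_direct_summation_oracle():
    """With the LED electrical artifact on in a control night, the
    stimulus-locked average equals the direct sum of the injected template
    (nothing else is time-locked to the electrical clock)."""
    cfg = quiet_config(night_duration=300.0, condition="control",
                       rng_seed=21, led_artifact_amplitude=2.0)
    hyp = hypnogram_from_stages(["N2"] * 10, cfg)
    rec, hyp, stim, truth = render_night(cfg, hypnogram=hyp)

    # oracle: average the raw Oz signal over LED-ON edges by direct loop
    x = rec.channel("Oz")
    edges = stim.led_on_edges("circuit")
    L = stim.period_samples
    edges = edges[edges + L <= x.size]
    oracle = np.zeros(L)
    for e in edges:
        oracle += x[e:e + L]
    oracle /= edges.size

    from gammasleep.ssvep import average_ssvep, segment_at_led_on
    res = average_ssvep(segment_at_led_on(x, stim))
    assert np.allclose(res.waveform, oracle, atol=1e-9)
    # and it is non-flat: the artifact template survives averaging
    assert res.ssvep_amp > 20 * np.abs(np.diff(oracle)).mean() / L
    assert res.ssvep_amp > 1.0   # ~2 uV biphasic template


def test_ground_truth_tst_matches_sleep_summary_exactly():
    cfg = quiet_config(night_duration=3600.0, rng_seed=4)
    rec, hyp, stim, truth = render_night(cfg)
    from gammasleep.sleep_metrics import summarize_hypnogram
    summary = summarize_hypnogram(hyp)
    expected = 0.5 * np.isin(truth.hypnogram.stages,
                             ("N1", "N2", "N3", "REM")).sum()
    assert summary.tst == expected
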