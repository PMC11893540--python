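"""Synthetic polysomnography nights with 40 Hz flicker stimulation.

Generates full "nights" -- multi-channel EEG/EOG/EMG, a hypnogram with
scoring certainty, a sample-accurate stimulation log, and the ground truth
needed for parameter-recovery tests -- with the statistical structure the
downstream analysis assumes:

* aperiodic 1/f-shaped background EEG plus an instrument white-noise floor,
  with stage-dependent broadband scaling (wakefulness is noisier);
* stage-signature oscillations (posterior alpha in W, spindles and delta in
  N2, slow waves in N3, theta in N1/REM);
* a 40 Hz evoked steady-state response on the occipito-parietal channels
  during visible stimulation, scaled by the per-stage peak-to-trough
  amplitude and the instantaneous illuminance;
* ocular / muscular / gross-movement artifacts at configurable rates and an
  optional electrical LED artifact time-locked to every LED edge (present in
  the covered-LED control condition too);
* the closed-loop stimulation schedule: light on at the first N3 epoch with
  a 5 min raised-cosine fade-in, 5 s fade-out on any W/N1 epoch, restart
  after six consecutive epochs scored neither W nor N1.

Everything is deterministic under a fixed ``rng_seed``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .types import (ALL_CHANNELS, EPOCH_SECONDS, MASTOIDS, ROI_CHANNELS,
                    STAGES, Hypnogram, Recording, StimLog)

__all__ = [
    "SimulationConfig", "GroundTruth", "generate_hypnogram",
    "hypnogram_from_stages", "build_stim_schedule", "build_wake_schedule",
    "render_night", "save_night",
]


def _default_stage_amplitudes() -> dict:
    # Peak-to-trough (uV) of the injected evoked response per stage;
    # experimental medians of the study this emulates. N1 is never analysed.
    return {"W": 0.96, "N1": 0.05, "N2": 0.08, "N3": 0.07, "REM": 0.09}


def _default_broadband_scale() -> dict:
    # Multiplier on the aperiodic background per stage: wakefulness carries
    # muscle tone and alertness broadband power; deep sleep is cleanest.
    return {"W": 3.0, "N1": 1.4, "N2": 1.2, "N3": 1.05, "REM": 1.0}


def _default_oscillations() -> dict:
    # stage -> list of (frequency Hz, sinusoid amplitude uV) signature
    # rhythms, amplitude-modulated by a slow random envelope.  Amplitudes
    # are deliberately sub-physiological: within a 25 ms analysis segment
    # the variability must stay dominated by broadband noise (as it is in
    # real recordings, where myogenic/instrument noise is also larger), or
    # the shuffled-segment null would not sit near 1 in control data.
    return {
        "W": [(10.0, 4.0)],
        "N1": [(5.0, 2.0)],
        "N2": [(13.0, 1.0), (1.5, 6.0)],
        "N3": [(0.8, 10.0)],
        "REM": [(5.0, 2.0)],
    }


def _default_artifact_rates() -> dict:
    # events per minute
    return {"emg": 0.3, "ocular": 0.3, "movement": 0.004}


@dataclass
class SimulationConfig:
    """Parameters of one simulated recording session.

    Signal amplitudes are in uV, durations in seconds.  ``sampling_rate``
    must be an integer multiple of ``stim_frequency`` so that one flicker
    cycle (25 ms at 40 Hz) is an integer number of samples, and
    ``night_duration`` a multiple of the 30 s scoring epoch.
    """

    sampling_rate: float = 600.0
    night_duration: float = 28800.0
    stim_frequency: float = 40.0
    duty_cycle: float = 0.5
    fade_in_duration: float = 300.0
    fade_out_duration: float = 5.0
    resume_rule_epochs: int = 6
    stage_ssvep_amplitude: dict = field(
        default_factory=_default_stage_amplitudes)
    harmonic_ratio: float = 0.0
    background_1f_exponent: float = 1.8
    background_rms_uv: float = 2.0
    white_noise_rms_uv: float = 1.3
    stage_broadband_scale: dict = field(
        default_factory=_default_broadband_scale)
    stage_oscillations: dict = field(default_factory=_default_oscillations)
    artifact_rates: dict = field(default_factory=_default_artifact_rates)
    led_artifact_amplitude: float = 0.0
    led_artifact_width_ms: float = 2.0
    condition: str = "experimental"
    rng_seed: int = 0
    certainty_beta: tuple = (10.0, 2.0)

    def __post_init__(self) -> None:
        period = self.sampling_rate / self.stim_frequency
        if abs(period - round(period)) > 1e-9:
            raise ValueError("sampling_rate must be a multiple of the "
                             "stimulation frequency")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.night_duration % EPOCH_SECONDS:
            raise ValueError("night_duration must be a multiple of 30 s")
        if self.condition not in ("control", "experimental"):
            raise ValueError("condition must be 'control' or 'experimental'")
        for stage, amp in self.stage_ssvep_amplitude.items():
            if amp < 0:
                raise ValueError(f"negative SSVEP amplitude for {stage}")
        if self.background_rms_uv < 0 or self.white_noise_rms_uv < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def n_epochs(self) -> int:
        return int(round(self.night_duration / EPOCH_SECONDS))

    @property
    def n_samples(self) -> int:
        return int(round(self.night_duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """What was actually injected -- the oracle for recovery tests."""

    stage_amplitudes: dict
    hypnogram: Hypnogram
    stim_on_mask: np.ndarray
    artifact_times: dict
    led_artifact_amplitude: float
    condition: str

    def to_json(self) -> str:
        d = {
            "stage_amplitudes": self.stage_amplitudes,
            "stages": self.hypnogram.stages.tolist(),
            "certainty": self.hypnogram.certainty.tolist(),
            "stim_on_seconds": float(self.stim_on_mask.sum()),
            "artifact_times": {k: list(map(float, v))
                               for k, v in self.artifact_times.items()},
            "led_artifact_amplitude": self.led_artifact_amplitude,
            "condition": self.condition,
        }
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

# Semi-Markov night dynamics: per-stage (minimum bout, mean bout) in epochs
# and a jump matrix between distinct stages.  Tuned for a healthy young
# sleeper profile: roughly 8 % N1, 53 % N2, 17 % N3, 21 % REM as a fraction
# of total sleep time, with ~12 % of the night awake.
_BOUTS = {"W": (1, 3.8), "N1": (1, 2.0), "N2": (4, 12.5),
          "N3": (4, 13.0), "REM": (4, 13.5)}
_JUMP = {
    "W": {"N1": 0.70, "N2": 0.30},
    "N1": {"N2": 0.70, "W": 0.22, "REM": 0.08},
    "N2": {"N3": 0.33, "REM": 0.26, "N1": 0.16, "W": 0.25},
    "N3": {"N2": 0.52, "W": 0.29, "N1": 0.19},
    "REM": {"W": 0.44, "N1": 0.28, "N2": 0.28},
}


def _certainty(rng: np.random.Generator, n: int,
               beta: tuple) -> np.ndarray:
    return rng.beta(beta[0], beta[1], size=n)


def hypnogram_from_stages(stages, config: SimulationConfig | None = None,
                          rng: np.random.Generator | None = None,
                          certainty=None) -> Hypnogram:
    """Build a hypnogram from an explicit stage sequence.

    Certainty is drawn from the configured Beta distribution unless given.
    """
    stages = np.asarray(stages, dtype="<U3")
    if certainty is None:
        beta = (config.certainty_beta if config is not None else (10.0, 2.0))
        if rng is None:
            rng = np.random.default_rng(
                config.rng_seed if config is not None else 0)
        certainty = _certainty(rng, stages.size, beta)
    return Hypnogram(stages, np.asarray(certainty, dtype=float))


def generate_hypnogram(config: SimulationConfig, *,
                       transition_matrix: np.ndarray | None = None,
                       initial_stage: str = "W",
                       rng: np.random.Generator | None = None) -> Hypnogram:
    """Simulate a night's stage sequence plus scoring certainty.

    Default dynamics are semi-Markov (stage-specific minimum bout lengths
    with geometric tails); the night is redrawn, deterministically, in the
    rare event that no N3 bout occurs, so the stimulation trigger always has
    something to fire on.  Passing ``transition_matrix`` (rows/cols ordered
    as W, N1, N2, N3, REM) switches to a plain first-order Markov chain with
    one step per epoch -- and disables the N3 redraw, since the caller has
    taken control of the dynamics.
    """
    n = config.n_epochs
    if config.night_duration < 120:
        raise ValueError("night_duration must be at least 120 s")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    if transition_matrix is not None:
        P = np.asarray(transition_matrix, dtype=float)
        if P.shape != (5, 5) or np.any(P < 0) or \
                not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition_matrix must be 5x5 row-stochastic")
        seq = np.empty(n, dtype="<U3")
        cur = STAGES.index(initial_stage)
        for k in range(n):
            seq[k] = STAGES[cur]
            cur = rng.choice(5, p=P[cur])
        return Hypnogram(seq, _certainty(rng, n, config.certainty_beta))

    for _ in range(50):
        seq = _semi_markov_night(n, initial_stage, rng)
        if "N3" in seq:
            break
    return Hypnogram(np.asarray(seq, dtype="<U3"),
                     _certainty(rng, n, config.certainty_beta))


def _semi_markov_night(n: int, initial_stage: str,
                       rng: np.random.Generator) -> list:
    seq: list[str] = []
    stage = initial_stage
    while len(seq) < n:
        mn, mean = _BOUTS[stage]
        extra_mean = max(mean - mn, 1e-9)
        dwell = mn + rng.geometric(1.0 / (extra_mean + 1.0)) - 1
        seq.extend([stage] * int(dwell))
        nxt, probs = zip(*_JUMP[stage].items())
        stage = nxt[rng.choice(len(nxt), p=np.asarray(probs))]
    return seq[:n]


# ---------------------------------------------------------------------------
# stimulation schedule
# ---------------------------------------------------------------------------

def _raised_cosine_up(t: np.ndarray, ramp: float) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(t, 0, ramp) / ramp))


def build_stim_schedule(hypnogram: Hypnogram,
                        config: SimulationConfig) -> StimLog:
    """Closed-loop stimulation schedule for one night.

    Experimental condition: stimulation starts at the first N3 epoch with a
    raised-cosine illuminance ramp (``fade_in_duration``); any W or N1 epoch
    triggers a cosine fade-out (``fade_out_duration``) from the current
    level, and the light stays off until ``resume_rule_epochs`` consecutive
    epochs scored neither W nor N1 have elapsed, after which it restarts
    with a fresh fade-in.  The LED circuit is active whenever illuminance is
    nonzero.  A hypnogram without N3 yields an all-off schedule with
    ``never_triggered=True`` (flagged, not an error).

    Control condition: the mask is electrically on for the whole recording
    with the LEDs covered -- the 40 Hz circuit clock runs throughout, but
    illuminance is zero and nothing is visible.
    """
    if hypnogram.n_epochs == 0:
        raise ValueError("hypnogram is empty")
    fs = config.sampling_rate
    n = int(round(hypnogram.n_epochs * EPOCH_SECONDS * fs))

    if config.condition == "control":
        return StimLog(fs, np.zeros(n, np.float32), np.zeros(n, bool),
                       np.ones(n, bool), config.stim_frequency,
                       config.duty_cycle)

    spe = int(round(EPOCH_SECONDS * fs))
    ramp_n = int(round(config.fade_in_duration * fs))
    fade_n = int(round(config.fade_out_duration * fs))
    illum = np.zeros(n, dtype=np.float64)

    is_wake = np.isin(hypnogram.stages, ("W", "N1"))
    state = "off"            # off -> waiting/on
    consec = 0
    start = None             # sample index where current interval began
    intervals = []           # (start_sample, end_sample or None)
    ever_on = False

    for k in range(hypnogram.n_epochs):
        if state == "off":
            if not ever_on:
                if hypnogram.stages[k] == "N3":
                    state, start, ever_on = "on", k * spe, True
                    intervals.append([start, None])
            else:
                if is_wake[k]:
                    consec = 0
                else:
                    consec += 1
                    if consec >= config.resume_rule_epochs:
                        state, start = "on", (k + 1) * spe
                        intervals.append([start, None])
                        consec = 0
        elif state == "on" and is_wake[k]:
            intervals[-1][1] = k * spe      # fade begins at this epoch
            state, consec = "off", 0

    for start, fade_at in intervals:
        if start >= n:
            continue
        end = n if fade_at is None else min(fade_at + fade_n, n)
        t = (np.arange(start, end) - start) / fs
        seg = _raised_cosine_up(t, config.fade_in_duration) \
            if ramp_n > 0 else np.ones(end - start)
        if fade_at is not None and fade_at < n:
            level = seg[fade_at - start - 1] if fade_at > start else 0.0
            tt = (np.arange(fade_at, end) - fade_at) / fs
            seg = seg.copy()
            seg[fade_at - start:] = level * 0.5 * (
                1.0 + np.cos(np.pi * np.clip(tt / config.fade_out_duration,
                                             0, 1)))
        illum[start:end] = np.maximum(illum[start:end], seg)

    visible = illum > 0
    # the LED drive runs in whole 25 ms cycles: the circuit is active for
    # every flicker cycle that contains any visible illuminance
    p = int(round(fs / config.stim_frequency))
    circuit = np.repeat(visible.reshape(-1, p).any(axis=1), p)
    log = StimLog(fs, illum.astype(np.float32), visible, circuit,
                  config.stim_frequency, config.duty_cycle,
                  never_triggered=not ever_on)
    if not ever_on:
        warnings.warn("hypnogram contains no N3 epoch; stimulation never "
                      "triggered", stacklevel=2)
    return log


def build_wake_schedule(config: SimulationConfig,
                        duration: float | None = None) -> StimLog:
    """Continuous full-illuminance stimulation (the awake session).

    The target level is applied from the first sample, as in seated
    wake blocks recorded at the target illuminance.
    """
    fs = config.sampling_rate
    n = int(round((duration or config.night_duration) * fs))
    on = config.condition == "experimental"
    return StimLog(fs, np.full(n, 1.0 if on else 0.0, np.float32),
                   np.full(n, on, bool), np.ones(n, bool),
                   config.stim_frequency, config.duty_cycle)


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, rms: float,
                      f_floor: float = 0.16) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-normalised to
    the requested rms.  The shape is flattened below ``f_floor`` (matching
    the high-pass edge of the acquisition chain) to keep the variance finite.
    """
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.empty_like(f)
    f_eff = np.maximum(f, f_floor)
    shape = f_eff ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    x *= rms / max(x.std(), 1e-30)
    return x


def _slow_envelope(rng: np.random.Generator, n: int, fs: float,
                   cutoff_s: float = 20.0) -> np.ndarray:
    """Positive slow amplitude envelope, mean ~1, built on a coarse grid."""
    grid = max(int(n / fs / cutoff_s) + 2, 4)
    coarse = np.abs(1.0 + 0.5 * rng.standard_normal(grid))
    return np.interp(np.arange(n), np.linspace(0, n - 1, grid), coarse)


def _evoked_waveform_norm(period: int, harmonic_ratio: float) -> float:
    """Peak-to-trough of the unit base waveform on the sampled cycle grid.

    The injected response is scaled by this so that the *sampled*
    peak-to-trough equals the configured stage amplitude exactly.
    """
    ph = 2 * np.pi * np.arange(period) / period
    w = np.sin(ph) + harmonic_ratio * np.sin(2 * ph)
    return float(w.max() - w.min())


def render_night(config: SimulationConfig, *,
                 hypnogram: Hypnogram | None = None,
                 stim: StimLog | None = None,
                 wake_session: bool = False,
                 ) -> tuple[Recording, Hypnogram, StimLog, GroundTruth]:
    """Render one full session: Recording + Hypnogram + StimLog + truth.

    ``hypnogram`` / ``stim`` may be supplied to pin the night structure
    (recovery tests do this); otherwise they are generated from the config.
    ``wake_session=True`` renders an awake block with continuous
    full-illuminance stimulation instead of the closed-loop night schedule.
    """
    fs = config.sampling_rate
    ss = np.random.SeedSequence(config.rng_seed)
    r_hyp, r_noise, r_osc, r_art, r_cert = [
        np.random.default_rng(s) for s in ss.spawn(5)]

    if hypnogram is None:
        if wake_session:
            hypnogram = hypnogram_from_stages(
                ["W"] * config.n_epochs, config, rng=r_cert)
        else:
            hypnogram = generate_hypnogram(config, rng=r_hyp)
    if stim is None:
        stim = (build_wake_schedule(config) if wake_session
                else build_stim_schedule(hypnogram, config))

    n = int(round(hypnogram.n_epochs * EPOCH_SECONDS * fs))
    if stim.n_samples != n:
        raise ValueError("stimulation log length does not match hypnogram")
    spe = int(round(EPOCH_SECONDS * fs))
    stage_idx = np.repeat([STAGES.index(s) for s in hypnogram.stages], spe)

    # per-sample broadband scale and evoked amplitude from the hypnogram
    bb = np.array([config.stage_broadband_scale.get(s, 1.0) for s in STAGES])
    amp = np.array([config.stage_ssvep_amplitude.get(s, 0.0) for s in STAGES])
    bb_scale = bb[stage_idx]
    amp_per_sample = amp[stage_idx]

    n_ch = len(ALL_CHANNELS)
    data = np.zeros((n_ch, n))

    # aperiodic background + white instrument floor, independent per channel
    for c in range(n_ch):
        x = _one_over_f_noise(r_noise, n, fs, config.background_1f_exponent,
                              config.background_rms_uv)
        if config.white_noise_rms_uv:
            x += config.white_noise_rms_uv * r_noise.standard_normal(n)
        x *= bb_scale           # stage scale applies to the whole broadband
        data[c] = x

    # shared stage-signature oscillations (per-channel-group gain)
    osc = np.zeros(n)
    t = np.arange(n) / fs
    for s_i, stage in enumerate(STAGES):
        mask = stage_idx == s_i
        if not mask.any():
            continue
        for freq, a in config.stage_oscillations.get(stage, []):
            phase = r_osc.uniform(0, 2 * np.pi)
            env = _slow_envelope(r_osc, n, fs)
            osc[mask] += (a * env[mask]
                          * np.sin(2 * np.pi * freq * t[mask] + phase))
    gains = {lab: 1.0 for lab in ROI_CHANNELS}
    gains.update({lab: 0.35 for lab in MASTOIDS})
    gains.update({"LEOG": 0.5, "REOG": 0.5, "LEMG": 0.1, "REMG": 0.1})
    for c, lab in enumerate(ALL_CHANNELS):
        data[c] += gains[lab] * osc

    # evoked steady-state response on ROI channels
    period = stim.period_samples
    norm = _evoked_waveform_norm(period, config.harmonic_ratio)
    ph = 2 * np.pi * config.stim_frequency * t
    base = np.sin(ph) + config.harmonic_ratio * np.sin(2 * ph)
    evoked = (amp_per_sample / norm) * stim.illuminance.astype(np.float64) \
        * stim.visible * base
    for lab in ROI_CHANNELS:
        data[ALL_CHANNELS.index(lab)] += evoked
    del base, ph

    # artifacts
    artifact_times = _insert_artifacts(data, fs, config, r_art)

    # electrical LED artifact at every on/off edge while the circuit is live.
    # Coupling is heterogeneous across electrodes (lead proximity and
    # impedance differ), so the artifact does NOT cancel under mastoid
    # re-referencing -- which is exactly why the covered-LED control and the
    # interpolation step exist.
    if config.led_artifact_amplitude > 0:
        w = max(int(round(config.led_artifact_width_ms * fs / 1000.0)), 2)
        tmpl = config.led_artifact_amplitude * np.sin(
            2 * np.pi * (np.arange(w) + 0.5) / w)
        base_gain = {}
        base_gain.update({lab: 1.0 for lab in ROI_CHANNELS})
        base_gain.update({lab: 0.5 for lab in MASTOIDS})
        base_gain.update({"LEOG": 1.5, "REOG": 1.5, "LEMG": 1.2,
                          "REMG": 1.2})
        edges = stim.all_edges()
        edges = edges[edges + w <= n]
        idx = (edges[:, None] + np.arange(w)[None, :]).ravel()
        for c, lab in enumerate(ALL_CHANNELS):
            gain = base_gain[lab] * (1.0 + 0.1 * r_art.standard_normal())
            np.add.at(data[c], idx, np.tile(gain * tmpl, edges.size))

    rec = Recording(data, fs, ALL_CHANNELS)
    truth = GroundTruth(
        stage_amplitudes=dict(config.stage_ssvep_amplitude),
        hypnogram=hypnogram,
        stim_on_mask=(stim.illuminance > 0) & stim.visible,
        artifact_times=artifact_times,
        led_artifact_amplitude=config.led_artifact_amplitude,
        condition=config.condition,
    )
    return rec, hypnogram, stim, truth


def _insert_artifacts(data: np.ndarray, fs: float, config: SimulationConfig,
                      rng: np.random.Generator) -> dict:
    """Add EMG bursts, ocular deflections and rare gross movements in place."""
    n = data.shape[1]
    minutes = n / fs / 60.0
    times: dict[str, list] = {"emg": [], "ocular": [], "movement": []}
    roi_rows = [ALL_CHANNELS.index(c) for c in ROI_CHANNELS]
    eog_rows = [ALL_CHANNELS.index(c) for c in ("LEOG", "REOG")]
    emg_rows = [ALL_CHANNELS.index(c) for c in ("LEMG", "REMG")]

    for _ in range(rng.poisson(config.artifact_rates.get("emg", 0) * minutes)):
        dur = int(rng.uniform(0.5, 2.0) * fs)
        start = rng.integers(0, max(n - dur, 1))
        burst = rng.standard_normal(dur) * np.hanning(dur)
        for r in emg_rows:
            data[r, start:start + dur] += 30.0 * burst
        for r in roi_rows:
            data[r, start:start + dur] += 3.0 * burst
        times["emg"].append(start / fs)

    for _ in range(rng.poisson(
            config.artifact_rates.get("ocular", 0) * minutes)):
        dur = int(rng.uniform(0.5, 1.5) * fs)
        start = rng.integers(0, max(n - dur, 1))
        ph = np.linspace(0, 2 * np.pi, dur)
        pulse = np.sin(ph) * np.hanning(dur)
        sign = rng.choice([-1.0, 1.0])
        for r in eog_rows:
            data[r, start:start + dur] += sign * 120.0 * pulse
        for r in roi_rows:
            data[r, start:start + dur] += sign * 4.0 * pulse
        times["ocular"].append(start / fs)

    for _ in range(rng.poisson(
            config.artifact_rates.get("movement", 0) * minutes)):
        dur = int(rng.uniform(2.0, 5.0) * fs)
        start = rng.integers(0, max(n - dur, 1))
        burst = rng.standard_normal(dur) * np.hanning(dur)
        data[:, start:start + dur] += 800.0 * burst  # >1 mV p2p on all chans
        times["movement"].append(start / fs)
    return times


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def save_night(out_dir, rec: Recording, hyp: Hypnogram, stim: StimLog,
               truth: GroundTruth, *, stem: str = "night") -> dict:
    """Write one session to disk: EDF + hypnogram CSV + stim CSV + truth JSON.

    The per-sample stimulation CSV is intended for short demo recordings;
    full nights should be passed around in memory.
    """
    from .io import write_edf, write_hypnogram_csv, write_stimlog_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": out / f"{stem}.edf",
        "hypnogram": out / f"{stem}_hypnogram.csv",
        "stimlog": out / f"{stem}_stimlog.csv",
        "truth": out / f"{stem}_truth.json",
    }
    write_edf(rec, paths["edf"])
    write_hypnogram_csv(hyp, paths["hypnogram"])
    write_stimlog_csv(stim, paths["stimlog"])
    paths["truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in paths.items()}
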