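"""Time-domain SSVEP analysis: 25 ms stimulus-locked segments, amplitude
rejection, evoked averaging, the shuffled-segment SNR, and the LED-artifact
linear-interpolation control.

One segment is one flicker cycle (25 ms at 40 Hz), time-locked to the
LED-ON edge.  In the experimental condition segments are taken only at full
illuminance (fade-in/fade-out excluded); in the covered-LED control
condition they are locked to the electrical LED clock, which replicates the
artifact-detection logic: any electrical artifact is time-locked and
survives averaging, while brain activity not locked to the flicker averages
out.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EPOCH_SECONDS, EpochSet, Recording, SegmentSet, StimLog

__all__ = ["SsvepResult", "segment_at_led_on", "reject_segments",
           "average_ssvep", "shuffle_snr", "interpolate_led_artifact",
           "analyze_bin", "SEGMENT_P2P_REJECT_UV", "SHUFFLE_REPEATS"]

#: Segment rejection threshold: keep iff peak-to-trough <= 100 uV (strict >
#: rejects, so a segment spanning exactly 100 uV is kept).
SEGMENT_P2P_REJECT_UV = 100.0

#: Shuffle-null repeats for the SSVEP SNR.
SHUFFLE_REPEATS = 100


@dataclass
class SsvepResult:
    """Grand-average SSVEP waveform and its summary numbers."""

    waveform: np.ndarray     # L samples, uV
    ssvep_amp: float         # peak-to-trough, uV
    snr: float | None
    n_segments: int
    condition: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.ssvep_amp < 0:
            raise ValueError("ssvep_amp must be >= 0")


def _signal_1d(signal) -> np.ndarray:
    if isinstance(signal, Recording):
        if signal.n_channels != 1:
            raise ValueError("expected the processed single-channel signal")
        return signal.samples[0]
    x = np.asarray(signal, dtype=float).squeeze()
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    return x


def segment_at_led_on(signal, stim: StimLog, *,
                      epochs: EpochSet | None = None,
                      condition: str | None = None) -> SegmentSet:
    """Cut one 25 ms segment per eligible LED-ON edge.

    Experimental segments require full visible illuminance for the whole
    cycle; if the log contains no visible stimulation at all (covered-LED
    control), segments are locked to the electrical circuit clock instead.
    When ``epochs`` (a rejection-flagged EpochSet) is given, segments whose
    parent 30 s epoch was rejected are excluded -- segments inherit their
    epoch's rejection status.
    """
    x = _signal_1d(signal)
    if stim.n_samples != x.size:
        raise ValueError("stimulation log and signal have different lengths")
    L = stim.period_samples
    if abs(stim.sampling_rate * 0.025 - L) > 1e-9:
        raise ValueError("segment length is not an integer number of samples")

    has_visible = bool(np.any(stim.visible & (stim.illuminance > 0)))
    region = "full_visible" if has_visible else "circuit"
    edges = stim.led_on_edges(region)
    edges = edges[edges + L <= x.size]

    if condition is None:
        condition = "experimental" if has_visible else "control"

    spe = int(round(EPOCH_SECONDS * stim.sampling_rate))
    epoch_idx = edges // spe
    if epochs is not None:
        n_ep = epochs.n_epochs
        keep = epoch_idx < n_ep
        if "rejected" in epochs.meta.columns:
            rejected = epochs.meta["rejected"].to_numpy()
            keep &= ~rejected[np.minimum(epoch_idx, n_ep - 1)]
        edges, epoch_idx = edges[keep], epoch_idx[keep]
        stages = epochs.meta["stage"].to_numpy()[epoch_idx] \
            if edges.size else np.empty(0, dtype="<U3")
    else:
        stages = np.full(edges.size, "W", dtype="<U3")

    if edges.size == 0:
        warnings.warn("no eligible stimulation cycles; empty segment set",
                      stacklevel=2)
        return SegmentSet(np.empty((0, L)), stim.sampling_rate,
                          np.empty(0, dtype="<U3"),
                          np.empty(0, dtype=np.int64), condition)

    segments = x[edges[:, None] + np.arange(L)[None, :]]
    return SegmentSet(segments, stim.sampling_rate, stages, epoch_idx,
                      condition)


def reject_segments(ss: SegmentSet,
                    threshold_uv: float = SEGMENT_P2P_REJECT_UV
                    ) -> SegmentSet:
    """Keep segments whose peak-to-trough range is <= ``threshold_uv``."""
    if ss.n_segments == 0:
        raise ValueError("segment set is empty")
    p2p = ss.segments.max(axis=1) - ss.segments.min(axis=1)
    keep = p2p <= threshold_uv
    return SegmentSet(ss.segments[keep], ss.sampling_rate, ss.stage[keep],
                      ss.epoch_index[keep], ss.condition)


def average_ssvep(ss: SegmentSet, stage: str = "") -> SsvepResult:
    """Per-sample mean across segments; amplitude = max - min of the mean.

    Activity not time-locked to the flicker (ocular, muscular, background
    oscillations) averages towards zero as the segment count grows; only
    flicker-locked components survive.
    """
    if ss.n_segments == 0:
        raise ValueError("cannot average an empty segment set")
    waveform = ss.segments.mean(axis=0)
    return SsvepResult(waveform, float(waveform.max() - waveform.min()),
                       None, ss.n_segments, ss.condition, stage)


def shuffle_snr(ss: SegmentSet, n_repeats: int = SHUFFLE_REPEATS,
                seed: int | None = 0) -> float:
    """Shuffled-segment null SNR.

    For each repeat the sample order *within every segment* is permuted
    independently (fresh permutations each repeat), the permuted segments
    are averaged, and the peak-to-trough amplitude of that "random" SSVEP
    is taken.  The SNR is the true averaged amplitude divided by the mean
    of the ``n_repeats`` random amplitudes.  Values near 1 mean the
    averaged signal has no temporal structure beyond exchangeable noise.
    """
    if ss.n_segments < 2:
        raise ValueError("need at least two segments")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    segs = ss.segments
    n, L = segs.shape
    true_amp = average_ssvep(ss).ssvep_amp

    rand_amps = np.empty(n_repeats)
    rows = np.arange(n)[:, None]
    for r in range(n_repeats):
        order = np.argsort(rng.random((n, L)), axis=1)
        avg = segs[rows, order].mean(axis=0)
        rand_amps[r] = avg.max() - avg.min()
    mean_rand = rand_amps.mean()
    if mean_rand == 0:
        raise ValueError("degenerate null: all segments constant, random "
                         "SSVEP amplitudes are all zero")
    return float(true_amp / mean_rand)


def interpolate_led_artifact(signal, stim: StimLog,
                             window_ms: float = 2.0):
    """Replace samples around every LED on/off edge by linear interpolation.

    Samples strictly inside ``edge +/- window_ms/2`` are replaced by the
    straight line between the two boundary samples.  This removes any
    electrical transient time-locked to the LED switching while leaving the
    rest of the cycle -- in particular the SSVEP extrema at the quarter
    phases -- untouched.  The window must stay below a half flicker cycle
    (12.5 ms) so neighbouring edge windows cannot overlap.
    """
    x = _signal_1d(signal).copy()
    fs = stim.sampling_rate
    half_cycle_ms = 1000.0 / stim.stim_frequency / 2.0
    if window_ms >= half_cycle_ms:
        raise ValueError(f"window {window_ms} ms >= half cycle "
                         f"{half_cycle_ms} ms: edge windows would overlap")
    hw = int(round(window_ms / 2.0 * fs / 1000.0))
    if hw < 1:
        return x if not isinstance(signal, Recording) else \
            Recording(x, fs, signal.channel_labels, signal.start_time)
    edges = stim.all_edges()
    edges = edges[(edges - hw >= 0) & (edges + hw < x.size)]
    if edges.size:
        left = x[edges - hw]
        right = x[edges + hw]
        offsets = np.arange(1, 2 * hw)           # interior samples only
        frac = offsets / (2.0 * hw)
        x[(edges[:, None] + (offsets - hw)[None, :])] = (
            left[:, None] * (1 - frac)[None, :]
            + right[:, None] * frac[None, :])
    if isinstance(signal, Recording):
        return Recording(x, fs, signal.channel_labels, signal.start_time)
    return x


def analyze_bin(ss: SegmentSet, stage: str, *, n_repeats: int =
                SHUFFLE_REPEATS, seed: int | None = 0) -> SsvepResult:
    """Rejection -> averaging -> shuffle SNR for one condition x stage bin."""
    surv = reject_segments(ss)
    res = average_ssvep(surv, stage)
    res.snr = shuffle_snr(surv, n_repeats=n_repeats, seed=seed)
    return res


def waveform_to_frame(res: SsvepResult, sampling_rate: float
                      ) -> pd.DataFrame:
    idx = np.arange(res.waveform.size)
    return pd.DataFrame({
        "sample_index": idx,
        "time_ms": idx / sampling_rate * 1000.0,
        "mean_uv": res.waveform,
    })


def results_to_frame(results) -> pd.DataFrame:
    """Tidy table: condition, stage, n_segments, ssvep_amp_uv, snr."""
    return pd.DataFrame([{
        "condition": r.condition, "stage": r.stage,
        "n_segments": r.n_segments, "ssvep_amp_uv": r.ssvep_amp,
        "snr": r.snr} for r in results])
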