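"""Preprocessing chain: band-pass filter, bad-channel rejection, ROI
averaging with mastoid re-referencing, 30 s epoching, epoch rejection and
condition x stage bin assignment.

The chain mirrors a standard evoked-potential PSG workflow: 0.16-300 Hz
zero-phase band-pass; flag flat or variance-outlier channels; average the
occipito-parietal region of interest and re-reference to the mastoid mean;
cut consecutive 30 s epochs carrying stage, scoring certainty and visible-
stimulation overlap; reject epochs by peak-to-peak amplitude (> 1 mV),
scoring certainty (< 50 %) or -- experimental condition only -- visible
stimulation under 25 s.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (ANALYSIS_STAGES, EPOCH_SECONDS, MASTOIDS, ROI_CHANNELS,
                    EpochSet, Hypnogram, Recording, StimLog)

__all__ = ["bandpass_filter", "reject_bad_channels",
           "roi_average_and_rereference", "epoch_and_label", "reject_epochs",
           "assign_condition_bins", "preprocess_recording",
           "P2P_REJECT_UV", "MIN_CERTAINTY", "MIN_STIM_SECONDS"]

logger = logging.getLogger(__name__)

#: Epoch rejection thresholds.
P2P_REJECT_UV = 1000.0     # > 1 mV peak-to-peak
MIN_CERTAINTY = 0.5        # < 50 % scoring certainty
MIN_STIM_SECONDS = 25.0    # < 25 s visible stimulation (experimental only)

#: Bad-channel thresholds (criteria are conservative and logged).
FLAT_VARIANCE_UV2 = 0.01
ROBUST_Z_THRESHOLD = 5.0


def bandpass_filter(rec: Recording, low: float = 0.16, high: float = 300.0,
                    *, order: int = 4, allow_clip: bool = True) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, order ``order``).

    When the sampling rate is too low for the nominal 300 Hz upper edge
    (fs <= 600), the low-pass branch is at/above Nyquist and is dropped
    with a logged warning, leaving the high-pass alone; with
    ``allow_clip=False`` that situation raises instead.
    """
    fs = rec.sampling_rate
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= 0.999 * nyq:
        if not allow_clip:
            raise ValueError(
                f"high edge {high} Hz >= Nyquist {nyq} Hz and clipping "
                "not permitted")
        # the low-pass edge is at/above Nyquist, so that branch is vacuous:
        # apply the high-pass alone rather than an ill-conditioned band-pass
        logger.warning("band-pass high edge %.3g Hz >= Nyquist %.3g Hz; "
                       "applying the %.3g Hz high-pass only (fs=%.3g)",
                       high, nyq, low, fs)
        sos = sps.butter(order, low, btype="highpass", output="sos", fs=fs)
    else:
        sos = sps.butter(order, [low, high], btype="bandpass", output="sos",
                         fs=fs)
    out = np.empty_like(rec.samples)
    for c in range(rec.n_channels):        # channel loop keeps peak memory low
        out[c] = sps.sosfiltfilt(sos, rec.samples[c])
    return Recording(out, fs, rec.channel_labels, rec.start_time)


def reject_bad_channels(rec: Recording,
                        *, consider=None) -> tuple[Recording, list]:
    """Flag flat or variance-outlier channels and drop them.

    A channel is flat when its variance is below ``FLAT_VARIANCE_UV2``; an
    outlier when the robust z-score of its log-variance (median/MAD over the
    considered channels) exceeds ``ROBUST_Z_THRESHOLD`` in magnitude.  Only
    EEG channels (ROI + mastoids) are considered by default; EOG/EMG carry
    legitimately different variance.  Raises if every ROI channel would be
    flagged.
    """
    if consider is None:
        consider = [c for c in rec.channel_labels
                    if c in ROI_CHANNELS or c in MASTOIDS]
    present_roi = [c for c in rec.channel_labels if c in ROI_CHANNELS]
    if len(present_roi) < 2:
        raise ValueError("need at least two ROI channels")

    variances = {lab: float(np.var(rec.channel(lab))) for lab in consider}
    flagged = [lab for lab, v in variances.items() if v < FLAT_VARIANCE_UV2]

    # Variance-outlier screen within the ROI group only: the reference and
    # periocular channels have legitimately different variance scales, and a
    # median/MAD over mixed groups would flag them spuriously.  The MAD is
    # floored (in log-variance units) so that near-identical channel
    # variances do not make the z-score hypersensitive.
    alive = {lab: v for lab, v in variances.items()
             if lab not in flagged and lab in ROI_CHANNELS}
    if len(alive) >= 3:
        logv = np.log(np.array(list(alive.values())))
        med = np.median(logv)
        mad = max(np.median(np.abs(logv - med)), 0.05)
        z = (logv - med) / (1.4826 * mad)
        flagged += [lab for lab, zz in zip(alive, z)
                    if abs(zz) > ROBUST_Z_THRESHOLD]

    if set(present_roi) <= set(flagged):
        raise ValueError("all ROI channels flagged bad -- manual review "
                         "required")
    if flagged:
        logger.info("rejected bad channels: %s", flagged)
    keep = [lab for lab in rec.channel_labels if lab not in flagged]
    return rec.pick(keep), flagged


def roi_average_and_rereference(rec: Recording) -> Recording:
    """mean(ROI channels) - mean(A1, A2), as a single-channel Recording."""
    roi = [c for c in ROI_CHANNELS if c in rec.channel_labels]
    if not roi:
        raise ValueError("no surviving ROI channel")
    missing = [m for m in MASTOIDS if m not in rec.channel_labels]
    if missing:
        raise ValueError(f"missing mastoid channel(s): {missing}")
    roi_mean = np.mean([rec.channel(c) for c in roi], axis=0)
    mast_mean = np.mean([rec.channel(c) for c in MASTOIDS], axis=0)
    return Recording(roi_mean - mast_mean, rec.sampling_rate, ("ROI",),
                     rec.start_time)


def preprocess_recording(rec: Recording, *, low: float = 0.16,
                         high: float = 300.0) -> Recording:
    """Filter -> bad-channel rejection -> ROI average & re-reference."""
    filtered = bandpass_filter(rec, low, high)
    cleaned, _ = reject_bad_channels(filtered)
    return roi_average_and_rereference(cleaned)


def epoch_and_label(rec: Recording, hyp: Hypnogram,
                    stim: StimLog | None, condition: str,
                    session: int) -> EpochSet:
    """Cut the processed single-channel signal into labelled 30 s epochs.

    Epochs are half-open ``[k*30 s, (k+1)*30 s)`` with 0-based indexing;
    only whole epochs covered by both recording and hypnogram are kept.
    ``stim_seconds`` is the visible-stimulation overlap with each epoch.
    """
    if rec.n_channels != 1:
        raise ValueError("epoching expects the processed single-channel "
                         "signal")
    spe = int(round(EPOCH_SECONDS * rec.sampling_rate))
    n_full = rec.n_samples // spe
    n_epochs = min(n_full, hyp.n_epochs)
    if n_epochs == 0:
        warnings.warn("recording shorter than one 30 s epoch; empty epoch "
                      "set", stacklevel=2)
    data = rec.samples[0, :n_epochs * spe].reshape(n_epochs, spe)
    stim_seconds = (stim.stim_seconds_per_epoch(n_epochs)
                    if stim is not None else np.zeros(n_epochs))
    meta = pd.DataFrame({
        "epoch_index": np.arange(n_epochs),
        "stage": hyp.stages[:n_epochs],
        "certainty": hyp.certainty[:n_epochs],
        "condition": condition,
        "session": session,
        "stim_seconds": stim_seconds,
    })
    return EpochSet(data.copy(), rec.sampling_rate, meta)


def reject_epochs(es: EpochSet, context: str = "spectral") -> EpochSet:
    """Flag bad epochs; reasons are recorded, data rows are kept.

    An epoch is rejected iff its peak-to-peak amplitude exceeds 1 mV, OR its
    scoring certainty is below 50 %, OR (experimental condition only) its
    visible-stimulation overlap is under 25 s.  Each criterion depends only
    on the epoch's own data/metadata, so the operation is idempotent.
    ``context`` ('spectral' or 'ssvep') is bookkeeping: the same rules apply
    in both analysis paths, and segments later inherit their parent epoch's
    flag.
    """
    if context not in ("spectral", "ssvep"):
        raise ValueError("context must be 'spectral' or 'ssvep'")
    meta = es.meta.copy()
    if es.n_epochs == 0:
        meta["rejected"] = pd.Series(dtype=bool)
        meta["reject_reasons"] = pd.Series(dtype=str)
        return EpochSet(es.data, es.sampling_rate, meta)

    p2p = es.data.max(axis=1) - es.data.min(axis=1)
    amp_bad = p2p > P2P_REJECT_UV
    cert_bad = meta["certainty"].to_numpy() < MIN_CERTAINTY
    exp = meta["condition"].to_numpy() == "experimental"
    stim_bad = exp & (meta["stim_seconds"].to_numpy() < MIN_STIM_SECONDS)

    reasons = []
    for a, c, s in zip(amp_bad, cert_bad, stim_bad):
        codes = ([["amplitude"], []][not a] + [["certainty"], []][not c]
                 + [["stim_duration"], []][not s])
        reasons.append(",".join(codes))
    meta["rejected"] = amp_bad | cert_bad | stim_bad
    meta["reject_reasons"] = reasons
    return EpochSet(es.data, es.sampling_rate, meta)


def assign_condition_bins(session_epochs: dict) -> dict:
    """Map per-session EpochSets into (condition, stage) analysis bins.

    Control bins (W, N2, N3, REM) come from session 2; the experimental W
    bin from session 1 only; experimental N2/N3/REM from session 3.  N1
    epochs enter no bin.  Missing sessions simply contribute nothing.
    """
    routing = {
        ("control", "W"): (2, "W"), ("control", "N2"): (2, "N2"),
        ("control", "N3"): (2, "N3"), ("control", "REM"): (2, "REM"),
        ("experimental", "W"): (1, "W"), ("experimental", "N2"): (3, "N2"),
        ("experimental", "N3"): (3, "N3"),
        ("experimental", "REM"): (3, "REM"),
    }
    bins = {}
    for (condition, stage), (session, src_stage) in routing.items():
        es = session_epochs.get(session)
        if es is None or es.n_epochs == 0:
            continue
        mask = es.meta["stage"].to_numpy() == src_stage
        if mask.any():
            bins[(condition, stage)] = es.subset(mask)
    return bins
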