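"""Core data containers shared across the pipeline.

All signal values are kept in microvolts (uV) internally; decibel conversion
happens only inside the spectral module, relative to 1 V^2/Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sleep-stage labels in scoring order.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

#: Stages entering the condition x stage analysis bins (N1 is excluded).
ANALYSIS_STAGES: tuple[str, ...] = ("W", "N2", "N3", "REM")

#: Occipito-parietal region-of-interest channels.
ROI_CHANNELS: tuple[str, ...] = ("O1", "Oz", "O2", "PO3", "POz", "PO4")

#: Mastoid reference channels.
MASTOIDS: tuple[str, ...] = ("A1", "A2")

#: Full simulated montage: ROI + mastoids + EOG + chin EMG.
ALL_CHANNELS: tuple[str, ...] = ROI_CHANNELS + MASTOIDS + (
    "LEOG", "REOG", "LEMG", "REMG")

#: Scoring epoch length in seconds (PSG standard).
EPOCH_SECONDS: float = 30.0


@dataclass
class Recording:
    """Multi-channel time series in uV.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sampling_rate : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per channel.
    start_time : float
        Offset of the first sample in seconds (for alignment bookkeeping).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.channel_labels = tuple(self.channel_labels)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} labels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the sample row for one channel label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.samples[idx]

    def pick(self, labels) -> "Recording":
        """Sub-recording restricted to ``labels`` (order preserved)."""
        labels = tuple(labels)
        rows = [self.channel_labels.index(lab) for lab in labels]
        return Recording(self.samples[rows], self.sampling_rate, labels,
                         self.start_time)


@dataclass
class Hypnogram:
    """Per-30 s-epoch stage labels with scoring certainty in [0, 1]."""

    stages: np.ndarray
    certainty: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U3")
        self.certainty = np.asarray(self.certainty, dtype=np.float64)
        if self.stages.shape != self.certainty.shape or self.stages.ndim != 1:
            raise ValueError("stages and certainty must be equal-length 1-D")
        bad = set(np.unique(self.stages)) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if np.any((self.certainty < 0) | (self.certainty > 1)):
            raise ValueError("certainty values must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return self.stages.size

    @property
    def duration(self) -> float:
        """Covered time in seconds (epochs x 30 s)."""
        return self.n_epochs * EPOCH_SECONDS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_index": np.arange(self.n_epochs),
            "stage": self.stages,
            "certainty": self.certainty,
        })


@dataclass
class StimLog:
    """Sample-accurate stimulation log.

    The LED drive is a 40 Hz square wave (50 % duty cycle by default) that is
    phase-locked to the sample clock: cycle k spans samples
    ``[k * period, (k + 1) * period)`` with the LED on for the first
    ``round(duty * period)`` samples.  ``illuminance`` is the relative light
    output in [0, 1] (1 = the 80 lux target); it is zero wherever no light
    reaches the eyes.  ``visible`` marks samples where subjects can see the
    light (always False for the covered-LED control condition).  ``circuit``
    marks samples where the LED circuit is electrically active -- the source
    of any electrical artifact, which exists even with covered LEDs.
    """

    sampling_rate: float
    illuminance: np.ndarray
    visible: np.ndarray
    circuit: np.ndarray
    stim_frequency: float = 40.0
    duty_cycle: float = 0.5
    never_triggered: bool = False

    def __post_init__(self) -> None:
        self.illuminance = np.asarray(self.illuminance, dtype=np.float32)
        self.visible = np.asarray(self.visible, dtype=bool)
        self.circuit = np.asarray(self.circuit, dtype=bool)
        n = self.illuminance.size
        if self.visible.size != n or self.circuit.size != n:
            raise ValueError("illuminance/visible/circuit length mismatch")
        period = self.sampling_rate / self.stim_frequency
        if abs(period - round(period)) > 1e-9:
            raise ValueError(
                "sampling_rate must be an integer multiple of the flicker "
                f"frequency (fs={self.sampling_rate}, f={self.stim_frequency})")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.illuminance.size

    @property
    def period_samples(self) -> int:
        """Samples per flicker cycle (integer by construction)."""
        return int(round(self.sampling_rate / self.stim_frequency))

    @property
    def on_samples(self) -> int:
        """LED-on samples per cycle."""
        return int(round(self.duty_cycle * self.period_samples))

    def led_state(self) -> np.ndarray:
        """Per-sample LED on/off state (0/1), zero where the circuit is off."""
        idx = np.arange(self.n_samples)
        square = (idx % self.period_samples) < self.on_samples
        return (square & self.circuit).astype(np.int8)

    def _cycle_starts(self) -> np.ndarray:
        p = self.period_samples
        n_cycles = self.n_samples // p
        return np.arange(n_cycles) * p

    def led_on_edges(self, region: str = "full_visible") -> np.ndarray:
        """Sample indices of LED-ON edges whose full cycle lies in ``region``.

        region='full_visible': cycles at full illuminance visible to the
        subject (fade-in/out excluded) -- the experimental segmentation.
        region='circuit': cycles with the LED circuit active -- the control
        segmentation on the electrical clock (LEDs covered).
        """
        starts = self._cycle_starts()
        p = self.period_samples
        if region == "full_visible":
            ok = (self.visible[starts]
                  & (self.illuminance[starts] >= 1.0 - 1e-6)
                  & (self.illuminance[np.minimum(starts + p - 1,
                                                 self.n_samples - 1)]
                     >= 1.0 - 1e-6))
        elif region == "circuit":
            ok = self.circuit[starts] & self.circuit[
                np.minimum(starts + p - 1, self.n_samples - 1)]
        else:
            raise ValueError(f"unknown region {region!r}")
        return starts[ok]

    def all_edges(self) -> np.ndarray:
        """On *and* off edge sample indices while the circuit is active."""
        on = self.led_on_edges("circuit")
        off = on + self.on_samples
        edges = np.concatenate([on, off])
        edges.sort()
        return edges

    def stim_seconds_per_epoch(self, n_epochs: int) -> np.ndarray:
        """Seconds of visible stimulation overlapping each 30 s epoch."""
        spe = int(round(EPOCH_SECONDS * self.sampling_rate))
        vis = (self.illuminance > 0) & self.visible
        out = np.zeros(n_epochs)
        for k in range(n_epochs):
            chunk = vis[k * spe:(k + 1) * spe]
            out[k] = chunk.sum() / self.sampling_rate
        return out

    def to_frame(self) -> pd.DataFrame:
        """Per-sample tidy table (intended for short demo recordings)."""
        return pd.DataFrame({
            "sample_index": np.arange(self.n_samples),
            "led_state": self.led_state(),
            "illuminance_fraction": self.illuminance.astype(np.float64),
            "visible": self.visible.astype(np.int8),
        })


@dataclass
class EpochSet:
    """Labelled 30 s epochs of the processed (ROI-averaged, re-referenced)
    single-channel signal.

    ``meta`` has one row per epoch with columns ``epoch_index``, ``stage``,
    ``certainty``, ``condition``, ``session``, ``stim_seconds``, and -- after
    :func:`gammasleep.preprocess.reject_epochs` -- ``rejected`` and
    ``reject_reasons``.
    """

    data: np.ndarray
    sampling_rate: float
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.shape[0] != len(self.meta):
            raise ValueError("data rows and meta rows differ")
        spe = int(round(EPOCH_SECONDS * self.sampling_rate))
        if self.data.shape[0] and self.data.shape[1] != spe:
            raise ValueError(
                f"epochs must have exactly {spe} samples, got "
                f"{self.data.shape[1]}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def subset(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.sampling_rate,
                        self.meta.iloc[mask].reset_index(drop=True))

    def kept(self) -> "EpochSet":
        """Epochs surviving rejection (all epochs if rejection not yet run)."""
        if "rejected" not in self.meta.columns:
            return self
        return self.subset(~self.meta["rejected"].to_numpy())


@dataclass
class SegmentSet:
    """25 ms stimulus-locked segments (one flicker cycle each)."""

    segments: np.ndarray
    sampling_rate: float
    stage: np.ndarray
    epoch_index: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(
            np.asarray(self.segments, dtype=np.float64))
        self.stage = np.asarray(self.stage, dtype="<U3")
        self.epoch_index = np.asarray(self.epoch_index, dtype=np.int64)
        L = int(round(self.sampling_rate * 0.025))
        if self.segments.size and self.segments.shape[1] != L:
            raise ValueError(
                f"segments must be {L} samples at fs={self.sampling_rate}")

    @property
    def n_segments(self) -> int:
        return 0 if self.segments.size == 0 else self.segments.shape[0]

    @property
    def segment_len(self) -> int:
        return int(round(self.sampling_rate * 0.025))

    def for_stage(self, stage: str) -> "SegmentSet":
        m = self.stage == stage
        return SegmentSet(self.segments[m], self.sampling_rate, self.stage[m],
                          self.epoch_index[m], self.condition)
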