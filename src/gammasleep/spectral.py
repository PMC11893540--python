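"""Epoch-level Hamming-window spectra, PSD40 and the neighbour-band SNR.

Each 30 s epoch gets a single-taper Hamming periodogram (density scaling,
1/30 Hz grid -- which contains a bin at exactly 40 Hz).  Powers are
expressed in dB relative to 1 V^2/Hz, with the uV signal converted to volts
before the logarithm; per-bin averaging across epochs happens on the linear
power scale, and only the averaged result is converted back to dB.

The neighbour-band SNR divides the *linear* power at 40 Hz by the mean
linear power over [38, 39.5] u [40.5, 42] Hz (bounds inclusive).  Dividing
the dB values themselves would invert the intended ordering for negative-dB
spectra and contradict the stated interpretation that SNR <= 1 means 40 Hz
activity is indistinguishable from its neighbours; the linear reading is
the one consistent with that interpretation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import EPOCH_SECONDS, EpochSet

__all__ = ["Spectrum", "Psd40Result", "epoch_psd", "average_psd",
           "extract_psd40", "psd_snr", "analyze_bin", "results_to_frame",
           "DB_FLOOR", "NEIGHBOR_BANDS"]

logger = logging.getLogger(__name__)

#: dB floor substituted for zero power (all-zero epochs), logged when hit.
DB_FLOOR = -400.0

#: Flanking bands for the spectral SNR, in Hz (bounds inclusive).
NEIGHBOR_BANDS = ((38.0, 39.5), (40.5, 42.0))

_UV_TO_V = 1e-6


@dataclass
class Spectrum:
    """One-sided power spectral density in dB re 1 V^2/Hz."""

    frequencies: np.ndarray
    power_db: np.ndarray
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.frequencies.shape != self.power_db.shape:
            raise ValueError("frequency grid and power mismatch")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def linear_power(self) -> np.ndarray:
        """Power in V^2/Hz (inverse of the dB transform)."""
        return 10.0 ** (self.power_db / 10.0)


@dataclass
class Psd40Result:
    """PSD40 (dB) and neighbour-band SNR for one condition x stage bin."""

    psd40_db: float
    snr: float
    condition: str
    stage: str
    n_epochs: int

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


def epoch_psd(epoch: np.ndarray, sampling_rate: float, *,
              epoch_seconds: float = EPOCH_SECONDS) -> Spectrum:
    """Single-taper Hamming periodogram of one epoch, in dB re 1 V^2/Hz.

    The epoch must contain exactly ``epoch_seconds`` of samples (30 s in the
    pipeline, which makes the grid spacing 1/30 Hz and places a bin at
    exactly 40 Hz).
    """
    epoch = np.asarray(epoch, dtype=float).squeeze()
    if epoch.ndim != 1:
        raise ValueError("epoch must be a 1-D signal")
    expected = int(round(epoch_seconds * sampling_rate))
    if epoch.size != expected:
        raise ValueError(f"epoch has {epoch.size} samples, expected "
                         f"{expected} ({epoch_seconds} s at "
                         f"{sampling_rate} Hz)")
    freqs, pxx = sps.periodogram(epoch * _UV_TO_V, fs=sampling_rate,
                                 window="hamming", scaling="density",
                                 detrend=False)
    return Spectrum(freqs, _to_db(pxx), n_epochs_averaged=1)


def _to_db(linear: np.ndarray) -> np.ndarray:
    linear = np.asarray(linear, dtype=float)
    zero = linear <= 0
    if np.any(zero):
        logger.info("%d spectral bins at zero power set to the %g dB floor",
                    int(zero.sum()), DB_FLOOR)
    out = np.full(linear.shape, DB_FLOOR)
    np.log10(linear, out=out, where=~zero)
    out[~zero] = 10.0 * out[~zero]
    return out


def average_psd(spectra) -> Spectrum:
    """Arithmetic mean of spectra on the linear power scale, then dB.

    Averaging the dB values instead would systematically bias the estimate
    low (Jensen); linear averaging is the standard multi-epoch estimator.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != grid.shape or \
                not np.allclose(s.frequencies, grid):
            raise ValueError("spectra have mismatched frequency grids")
    linear = np.mean([s.linear_power() for s in spectra], axis=0)
    n = sum(s.n_epochs_averaged for s in spectra)
    return Spectrum(grid, _to_db(linear), n_epochs_averaged=n)


def extract_psd40(spec: Spectrum, target: float = 40.0) -> float:
    """dB value of the bin at exactly ``target`` Hz; never interpolates."""
    hits = np.flatnonzero(np.isclose(spec.frequencies, target, atol=1e-6,
                                     rtol=0.0))
    if hits.size == 0:
        raise ValueError(
            f"frequency grid (spacing {spec.df:.6g} Hz) has no bin at "
            f"exactly {target} Hz")
    return float(spec.power_db[hits[0]])


def psd_snr(spec: Spectrum, target: float = 40.0,
            bands=NEIGHBOR_BANDS) -> float:
    """Linear power at 40 Hz over the mean linear power of the flanks.

    SNR ~ 1 means 40 Hz activity is indistinguishable from its neighbours.
    """
    f = spec.frequencies
    tol = 1e-6
    neighbor = np.zeros(f.shape, dtype=bool)
    for lo, hi in bands:
        neighbor |= (f >= lo - tol) & (f <= hi + tol)
    if not neighbor.any():
        raise ValueError("no frequency bins inside the neighbour bands")
    linear = spec.linear_power()
    p40 = linear[np.flatnonzero(
        np.isclose(f, target, atol=1e-6, rtol=0.0))]
    if p40.size == 0:
        raise ValueError(f"no bin at exactly {target} Hz")
    return float(p40[0] / linear[neighbor].mean())


def analyze_bin(es: EpochSet, condition: str, stage: str) -> Psd40Result:
    """Full spectral path for one bin: per-epoch PSDs of the *kept* epochs,
    linear averaging, PSD40 and neighbour-band SNR."""
    kept = es.kept()
    if kept.n_epochs == 0:
        raise ValueError(f"no surviving epochs in bin {condition}/{stage}")
    spectra = [epoch_psd(row, es.sampling_rate) for row in kept.data]
    avg = average_psd(spectra)
    return Psd40Result(extract_psd40(avg), psd_snr(avg), condition, stage,
                       kept.n_epochs)


def results_to_frame(results) -> pd.DataFrame:
    """Tidy table: condition, stage, n_epochs, psd40_db, snr."""
    return pd.DataFrame([{
        "condition": r.condition, "stage": r.stage, "n_epochs": r.n_epochs,
        "psd40_db": r.psd40_db, "snr": r.snr} for r in results])
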