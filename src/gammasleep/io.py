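"""Standard-format I/O: EDF recordings, hypnogram / stimulation-log CSVs.

EDF is written directly (the format is a fixed-layout ASCII header plus
16-bit little-endian data records) and read back through MNE's EDF reader,
so the writer and reader are independent implementations.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EPOCH_SECONDS, Hypnogram, Recording, StimLog

__all__ = ["read_edf", "write_edf", "EdfParseError",
           "write_hypnogram_csv", "read_hypnogram_csv",
           "write_stimlog_csv", "read_stimlog_csv"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfParseError(ValueError):
    """Raised when an EDF file cannot be parsed; names the offending field."""


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    """Format a float into a fixed-width EDF numeric field."""
    for fmt in (f"{{:.{width - 2}g}}", "{:.6g}", "{:.4g}", "{:.2g}"):
        s = fmt.format(float(value))
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot fit {value} into {width} chars")


def write_edf(rec: Recording, path) -> None:
    """Write a Recording to 16-bit EDF with physical units uV.

    The record duration is 1 s; the recording is zero-padded to a whole
    number of seconds if needed.  Physical min/max are set per channel from
    the data, so the quantisation step is (max - min) / 65535.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    labels = rec.channel_labels
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in recording")

    n_rec = -(-rec.n_samples // fs)          # ceil: records of 1 s
    data = np.zeros((rec.n_channels, n_rec * fs))
    data[:, :rec.n_samples] = rec.samples

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None]
                       + _DIG_MIN).astype("<i2")

    ns = rec.n_channels
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(ns, 4),
    ])
    sig = b"".join([
        b"".join(_ascii(lab, 16) for lab in labels),
        b"".join(_ascii("AgAgCl electrode", 80) for _ in labels),
        b"".join(_ascii("uV", 8) for _ in labels),
        b"".join(_num(lo, 8) for lo in pmin),
        b"".join(_num(hi, 8) for hi in pmax),
        b"".join(_num(_DIG_MIN, 8) for _ in labels),
        b"".join(_num(_DIG_MAX, 8) for _ in labels),
        b"".join(_ascii("", 80) for _ in labels),
        b"".join(_ascii(fs, 8) for _ in labels),
        b"".join(_ascii("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # data records: all samples of channel 1, then channel 2, ... per 1 s
        recs = digital.reshape(ns, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(recs).tobytes())


def _read_edf_header_labels(path) -> list[str]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EdfParseError("file too short for an EDF header "
                                "(field: fixed header)")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError:
            raise EdfParseError(
                "cannot parse 'number of signals' header field") from None
        raw = fh.read(16 * ns)
        if len(raw) < 16 * ns:
            raise EdfParseError("truncated signal-label block "
                                "(field: channel labels)")
    return [raw[i * 16:(i + 1) * 16].decode("ascii", "replace").strip()
            for i in range(ns)]


def read_edf(path) -> Recording:
    """Read an EDF file into a Recording (uV).

    Uses MNE's EDF reader; duplicate channel labels and malformed headers
    raise :class:`EdfParseError` naming the problem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels = _read_edf_header_labels(path)
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise EdfParseError(
            f"duplicate channel label(s) in EDF header: {sorted(dupes)}")

    import mne
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed input
        raise EdfParseError(f"cannot parse EDF file: {exc}") from exc
    data_uv = raw.get_data() * 1e6   # mne scales uV-dimensioned data to V
    return Recording(data_uv, float(raw.info["sfreq"]),
                     tuple(raw.ch_names))


# ---------------------------------------------------------------------------
# CSV sidecars
# ---------------------------------------------------------------------------

def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    hyp.to_frame().to_csv(path, index=False)


def read_hypnogram_csv(path) -> Hypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "stage", "certainty"):
        if col not in df.columns:
            raise ValueError(f"hypnogram CSV missing column {col!r}")
    df = df.sort_values("epoch_index")
    return Hypnogram(df["stage"].to_numpy(dtype="<U3"),
                     df["certainty"].to_numpy(dtype=float))


def write_stimlog_csv(stim: StimLog, path) -> None:
    if stim.n_samples > 5_000_000:
        warnings.warn("per-sample stimulation CSV for a very long recording; "
                      "consider keeping the StimLog in memory", stacklevel=2)
    stim.to_frame().to_csv(path, index=False)


def read_stimlog_csv(path, sampling_rate: float,
                     stim_frequency: float = 40.0,
                     duty_cycle: float = 0.5) -> StimLog:
    """Rebuild a StimLog from its per-sample CSV.

    The electrically-active (circuit) mask is inferred per flicker cycle:
    a cycle is active if any sample in it has the LED on.
    """
    df = pd.read_csv(path)
    for col in ("sample_index", "led_state", "illuminance_fraction",
                "visible"):
        if col not in df.columns:
            raise ValueError(f"stimulation CSV missing column {col!r}")
    df = df.sort_values("sample_index")
    illum = df["illuminance_fraction"].to_numpy(dtype=np.float32)
    visible = df["visible"].to_numpy(dtype=bool)
    led = df["led_state"].to_numpy(dtype=bool)
    n = illum.size
    period = int(round(sampling_rate / stim_frequency))
    n_cycles = -(-n // period)
    padded = np.zeros(n_cycles * period, dtype=bool)
    padded[:n] = led
    active_cycle = padded.reshape(n_cycles, period).any(axis=1)
    circuit = np.repeat(active_cycle, period)[:n]
    return StimLog(sampling_rate, illum, visible, circuit,
                   stim_frequency, duty_cycle)
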