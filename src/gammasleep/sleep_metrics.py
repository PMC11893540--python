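"""Objective and subjective sleep-quality variables.

All durations are in minutes with the 30 s scoring epoch as the unit
(0.5 min).  WASO counts wake epochs strictly between the first and last
sleep epoch -- wake before sleep onset is sleep-onset latency, wake after
the final sleep epoch counts towards neither.  REM latency is referenced to
sleep onset (the first non-W epoch), the conventional definition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Hypnogram

__all__ = ["SleepSummary", "GsqsScore", "summarize_hypnogram", "gsqs_sum",
           "EPOCH_MINUTES"]

EPOCH_MINUTES = 0.5
_SLEEP_STAGES = ("N1", "N2", "N3", "REM")


@dataclass
class SleepSummary:
    """Macrostructure summary of one night."""

    tst: float                       # total sleep time, minutes
    waso: float                      # wake after sleep onset, minutes
    stage_pct: dict = field(default_factory=dict)  # % of TST per stage
    rem_latency: float | None = None  # minutes from sleep onset, None if no REM
    sol: float | None = None          # sleep-onset latency, None if no sleep

    def to_row(self) -> dict:
        row = {"tst_min": self.tst, "waso_min": self.waso,
               "rem_latency_min": self.rem_latency, "sol_min": self.sol}
        for s in _SLEEP_STAGES:
            row[f"pct_{s.lower()}"] = self.stage_pct.get(s, 0.0)
        return row


@dataclass
class GsqsScore:
    """Groningen Sleep Quality Scale sum: 0 (perfect) to 14 (poor)."""

    sum: int

    def __post_init__(self) -> None:
        if not 0 <= self.sum <= 14:
            raise ValueError("GSQS sum must lie in [0, 14]")


def summarize_hypnogram(hyp: Hypnogram) -> SleepSummary:
    """TST, WASO, stage percentages, REM latency and sleep-onset latency.

    TST = 0.5 min x count of N1/N2/N3/REM epochs.  An all-wake night yields
    TST = WASO = 0 with latencies flagged as None.
    """
    if hyp.n_epochs == 0:
        raise ValueError("hypnogram is empty")
    stages = hyp.stages
    asleep = np.isin(stages, _SLEEP_STAGES)
    tst = EPOCH_MINUTES * int(asleep.sum())

    if not asleep.any():
        return SleepSummary(tst=0.0, waso=0.0, stage_pct={},
                            rem_latency=None, sol=None)

    sleep_idx = np.flatnonzero(asleep)
    first, last = int(sleep_idx[0]), int(sleep_idx[-1])
    inside = stages[first:last + 1]
    waso = EPOCH_MINUTES * int(np.sum(inside == "W"))

    stage_pct = {}
    if tst > 0:
        for s in _SLEEP_STAGES:
            stage_pct[s] = 100.0 * EPOCH_MINUTES * int(
                np.sum(stages == s)) / tst

    rem_idx = np.flatnonzero(stages == "REM")
    rem_latency = (EPOCH_MINUTES * (int(rem_idx[0]) - first)
                   if rem_idx.size else None)
    return SleepSummary(tst=tst, waso=waso, stage_pct=stage_pct,
                        rem_latency=rem_latency,
                        sol=EPOCH_MINUTES * first)


def gsqs_sum(items) -> GsqsScore:
    """Sum 14 already-keyed binary GSQS item responses.

    Items must be coded 0/1 after the instrument's standard keying (1 =
    poor-sleep answer); the item text itself is not embedded here.  Missing
    (None/NaN) items raise with their indices listed.
    """
    arr = pd.array(list(items))
    if len(arr) != 14:
        raise ValueError(f"GSQS has exactly 14 items, got {len(arr)}")
    missing = [i for i, v in enumerate(arr) if pd.isna(v)]
    if missing:
        raise ValueError(f"missing GSQS item responses at indices {missing}")
    vals = np.asarray(arr, dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("GSQS items must be binary 0/1 after keying")
    return GsqsScore(int(vals.sum()))
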