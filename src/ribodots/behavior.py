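"""Sleep-score bookkeeping and the behavioral exclusion screen.

Sleep behavior is visually scored in fixed-length intervals (5-min bins for
6-h experiments, 2-min bins for 3-h experiments).  Sleep-group animals that
spent more than 60% of the final 45 min of the experiment awake are excluded
from analysis; sleep-deprived animals are never excluded by this rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SleepRecord",
    "percent_sleep",
    "final_window_wake_fraction",
    "apply_exclusion",
    "SleepExclusionScreen",
]

_STATES = ("sleep", "wake")


@dataclass
class SleepRecord:
    """Contiguous, non-overlapping scored bins for one animal."""

    starts: np.ndarray   # bin start, minutes from experiment start
    lengths: np.ndarray  # bin length, minutes
    states: np.ndarray   # "sleep" | "wake"
    animal: str = ""
    group: str = "sleep"  # "sleep" or "SD"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.states = np.asarray(self.states, dtype=object)
        if not (len(self.starts) == len(self.lengths) == len(self.states)):
            raise ValueError("starts, lengths, states must have equal length")
        if len(self.starts) == 0:
            raise ValueError("record has no bins")
        if np.any(self.lengths <= 0):
            raise ValueError("bin lengths must be positive")
        ends = self.starts + self.lengths
        if not np.allclose(self.starts[1:], ends[:-1]):
            raise ValueError("bins must be contiguous and non-overlapping")
        bad = set(self.states) - set(_STATES)
        if bad:
            raise ValueError(f"unknown states {sorted(bad)}; expected {_STATES}")

    @property
    def duration_min(self) -> float:
        return float(self.lengths.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_min": self.starts,
                "length_min": self.lengths,
                "state": self.states,
                "animal": self.animal,
                "group": self.group,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SleepRecord":
        animal = str(df["animal"].iloc[0]) if "animal" in df else ""
        group = str(df["group"].iloc[0]) if "group" in df else "sleep"
        return cls(
            starts=df["start_min"].to_numpy(),
            lengths=df["length_min"].to_numpy(),
            states=df["state"].to_numpy(),
            animal=animal,
            group=group,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SleepRecord":
        return cls.from_frame(pd.read_csv(path))


def _bins_in_window(
    record: SleepRecord, window: tuple[float, float]
) -> tuple[np.ndarray, float]:
    """Boolean mask of bins fully inside [t0, t1] and their total minutes."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    if t0 < record.starts[0] - 1e-9 or t1 > record.starts[-1] + record.lengths[-1] + 1e-9:
        raise ValueError("window must lie within the record span")
    ends = record.starts + record.lengths
    inside = (record.starts >= t0 - 1e-9) & (ends <= t1 + 1e-9)
    return inside, float(record.lengths[inside].sum())


def percent_sleep(
    record: SleepRecord, window: tuple[float, float] | None = None
) -> float:
    """Percent of time scored asleep, over bins fully inside ``window``.

    ``window`` is a (start, end) pair in minutes; ``None`` means the full
    record.  ``percent_sleep + percent_wake = 100`` exactly.
    """
    if window is None:
        window = (float(record.starts[0]), float(record.starts[-1] + record.lengths[-1]))
    inside, total = _bins_in_window(record, window)
    if total == 0:
        raise ValueError("no whole bins inside the window")
    slept = float(record.lengths[inside & (record.states == "sleep")].sum())
    return 100.0 * slept / total


def final_window_wake_fraction(record: SleepRecord, window_min: float = 45.0) -> float:
    """Wake fraction over the trailing ``window_min`` minutes.

    Uses the maximal suffix of whole bins whose total length does not exceed
    the window (so 2-min bins cover 44 of a 45-min window).  Raises if the
    record is shorter than the window.
    """
    if window_min <= 0:
        raise ValueError("window must be positive")
    if record.duration_min < window_min - 1e-9:
        raise ValueError(
            f"record of {record.duration_min} min is shorter than the "
            f"{window_min} min window"
        )
    lengths = record.lengths[::-1]
    cum = np.cumsum(lengths)
    k = int(np.searchsorted(cum, window_min + 1e-9, side="right"))
    if k == 0:
        raise ValueError("no whole bin fits inside the window")
    tail_states = record.states[len(record.states) - k:]
    tail_lengths = record.lengths[len(record.lengths) - k:]
    wake = float(tail_lengths[tail_states == "wake"].sum())
    return wake / float(tail_lengths.sum())


def apply_exclusion(
    records: list[SleepRecord],
    threshold: float = 0.60,
    window_min: float = 45.0,
) -> tuple[list[SleepRecord], list[SleepRecord]]:
    """Split records into (kept, excluded) by the final-window wake screen.

    A sleep-group record is excluded iff its wake fraction over the final
    window strictly exceeds ``threshold`` (exactly 0.60 is kept).  Records of
    the sleep-deprived group are never excluded by this rule.
    """
    kept: list[SleepRecord] = []
    excluded: list[SleepRecord] = []
    for rec in records:
        if rec.group != "sleep":
            kept.append(rec)
            continue
        frac = final_window_wake_fraction(rec, window_min)
        (excluded if frac > threshold else kept).append(rec)
    return kept, excluded


class SleepExclusionScreen(BaseEstimator):
    """Estimator-style wrapper around the exclusion screen.

    ``predict`` returns a boolean keep-flag per record; ``transform`` returns
    the kept records.  There is nothing to learn: ``fit`` validates parameters
    and records the per-record wake fractions as ``wake_fraction_``.
    """

    def __init__(self, threshold: float = 0.60, window_min: float = 45.0):
        self.threshold = threshold
        self.window_min = window_min

    def fit(self, X: list[SleepRecord], y=None) -> "SleepExclusionScreen":
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.window_min <= 0:
            raise ValueError("window_min must be positive")
        self.wake_fraction_ = np.array(
            [final_window_wake_fraction(r, self.window_min) for r in X]
        )
        self.n_records_ = len(X)
        return self

    def predict(self, X: list[SleepRecord]) -> np.ndarray:
        keep = []
        for rec in X:
            if rec.group != "sleep":
                keep.append(True)
            else:
                frac = final_window_wake_fraction(rec, self.window_min)
                keep.append(not frac > self.threshold)
        return np.asarray(keep, dtype=bool)

    def transform(self, X: list[SleepRecord]) -> list[SleepRecord]:
        keep = self.predict(X)
        return [r for r, k in zip(X, keep) if k]

    def fit_predict(self, X: list[SleepRecord], y=None) -> np.ndarray:
        return self.fit(X).predict(X)
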