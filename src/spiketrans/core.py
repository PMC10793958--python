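"""Core data model: spike trains, epochs, stimulus events, sessions.

All times are seconds (double precision). Intervals are half-open
``[start, end)``; histogram bins are half-open on the left and closed on the
right, ``(low, high]``, so the bin "containing 2.0 ms" is (1.5, 2.0] ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CellClass",
    "SpikeTrain",
    "EpochSet",
    "StimulusEvents",
    "Session",
    "restrict_times",
]


class CellClass(str, Enum):
    """Putative cell type of a sorted unit."""

    PYR = "PYR"
    PV = "PV"
    OTHER = "OTHER"


def _as_sorted_times(times: Sequence[float], what: str) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError(f"{what}: times must be one-dimensional")
    if t.size and not np.all(np.isfinite(t)):
        raise ValueError(f"{what}: times contain NaN/inf")
    if t.size and np.any(t < 0):
        raise ValueError(f"{what}: negative times")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{what}: times not strictly increasing")
    return t


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's sorted spike times plus identity metadata.

    Parameters
    ----------
    unit_id:
        Unique unit label within a session.
    times:
        Strictly increasing spike times in seconds.
    cell_class:
        Putative cell class (PYR, PV or OTHER).
    shank:
        Recording shank index (≥ 1).
    """

    unit_id: str
    times: np.ndarray
    cell_class: CellClass = CellClass.OTHER
    shank: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "times", _as_sorted_times(self.times, f"unit {self.unit_id}")
        )
        object.__setattr__(self, "cell_class", CellClass(self.cell_class))
        if int(self.shank) < 1:
            raise ValueError(f"unit {self.unit_id}: shank must be >= 1")
        object.__setattr__(self, "shank", int(self.shank))

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def rate(self, duration_s: float) -> float:
        """Mean firing rate over ``duration_s`` seconds."""
        return self.n_spikes / float(duration_s)

    def restrict(self, intervals: Sequence[tuple[float, float]]) -> "SpikeTrain":
        """Keep spikes within the union of half-open intervals [a, b)."""
        return replace(self, times=restrict_times(self.times, intervals))


def restrict_times(
    times: np.ndarray, intervals: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Select times falling in the union of half-open intervals [a, b).

    Ordering is preserved; the operation is idempotent and never adds items.
    """
    t = np.asarray(times, dtype=float)
    keep = np.zeros(t.shape, dtype=bool)
    for a, b in intervals:
        if b < a:
            raise ValueError(f"invalid interval [{a}, {b})")
        keep |= (t >= a) & (t < b)
    return t[keep]


@dataclass(frozen=True)
class EpochSet:
    """Labeled, non-overlapping session intervals (Before/Experience/After...).

    Intervals are half-open ``[start, end)``. When the three canonical epochs
    are present, Before must precede Experience, which must precede After.
    """

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        iv = {str(k): (float(a), float(b)) for k, (a, b) in self.intervals.items()}
        for k, (a, b) in iv.items():
            if not (np.isfinite(a) and np.isfinite(b)) or b <= a:
                raise ValueError(f"epoch {k}: invalid interval [{a}, {b})")
        spans = sorted(iv.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("epochs overlap")
        order = [k for k in ("Before", "Experience", "After") if k in iv]
        starts = [iv[k][0] for k in order]
        if starts != sorted(starts):
            raise ValueError("epochs must be ordered Before < Experience < After")
        object.__setattr__(self, "intervals", iv)

    def __getitem__(self, label: str) -> tuple[float, float]:
        return self.intervals[label]

    def __contains__(self, label: str) -> bool:
        return label in self.intervals

    @property
    def labels(self) -> list[str]:
        return list(self.intervals)

    def duration(self, label: str) -> float:
        a, b = self.intervals[label]
        return b - a

    @property
    def end(self) -> float:
        return max(b for _, b in self.intervals.values())


@dataclass(frozen=True)
class StimulusEvents:
    """Stimulus onsets with a common duration and optional trigger metadata.

    Consecutive onsets must be separated by at least ``duration_s +
    dead_time_s`` (the controller blanks re-triggering for a dead time after
    each stimulus).
    """

    onsets: np.ndarray
    duration_s: float = 0.030
    dead_time_s: float = 0.020
    trigger_unit: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        onsets = _as_sorted_times(self.onsets, "events")
        object.__setattr__(self, "onsets", onsets)
        if self.duration_s <= 0:
            raise ValueError("stimulus duration must be positive")
        min_gap = self.duration_s + self.dead_time_s
        if onsets.size > 1:
            gaps = np.diff(onsets)
            bad = np.flatnonzero(gaps < min_gap - 1e-9)
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"events {i} and {i + 1}: onset gap {gaps[i]:.6f} s < "
                    f"duration + dead time = {min_gap:.6f} s"
                )
        if self.trigger_unit is not None:
            tu = tuple(self.trigger_unit)
            if len(tu) != onsets.size:
                raise ValueError("trigger_unit length must match onsets")
            object.__setattr__(self, "trigger_unit", tu)

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def intervals(self) -> list[tuple[float, float]]:
        """Nominal stimulus-on intervals [onset, onset + duration)."""
        return [(float(t), float(t) + self.duration_s) for t in self.onsets]

    def restrict(self, intervals: Sequence[tuple[float, float]]) -> "StimulusEvents":
        keep = np.zeros(self.onsets.shape, dtype=bool)
        for a, b in intervals:
            keep |= (self.onsets >= a) & (self.onsets < b)
        tu = None
        if self.trigger_unit is not None:
            tu = tuple(t for t, k in zip(self.trigger_unit, keep) if k)
        return StimulusEvents(
            self.onsets[keep], self.duration_s, self.dead_time_s, tu
        )


def empty_events(duration_s: float = 0.030, dead_time_s: float = 0.020) -> StimulusEvents:
    return StimulusEvents(np.array([]), duration_s, dead_time_s)


@dataclass
class Session:
    """A recording session: spike trains, epochs and (possibly no) stimuli."""

    trains: dict[str, SpikeTrain]
    epochs: EpochSet
    events: StimulusEvents = field(default_factory=empty_events)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s is None:
            last_spike = max(
                (t.times[-1] for t in self.trains.values() if t.n_spikes), default=0.0
            )
            self.duration_s = max(self.epochs.end, float(last_spike))
        for uid, train in self.trains.items():
            if uid != train.unit_id:
                raise ValueError(f"train keyed {uid!r} has unit_id {train.unit_id!r}")
            if train.n_spikes and train.times[-1] > self.duration_s:
                raise ValueError(f"unit {uid}: spikes beyond session duration")
        if self.events.n_events and "Experience" in self.epochs:
            a, b = self.epochs["Experience"]
            on = self.events.onsets
            if on[0] < a or on[-1] >= b:
                raise ValueError("stimulus events must fall inside the Experience epoch")

    def units(self, cell_class: CellClass | str | None = None) -> list[str]:
        """Unit ids, optionally filtered by cell class."""
        if cell_class is None:
            return list(self.trains)
        cc = CellClass(cell_class)
        return [u for u, t in self.trains.items() if t.cell_class == cc]

    def epoch_train(self, unit_id: str, label: str) -> SpikeTrain:
        """A unit's train restricted to one epoch."""
        return self.trains[unit_id].restrict([self.epochs[label]])

    def epoch_trains(self, unit_id: str, labels: Iterable[str]) -> SpikeTrain:
        """A unit's train restricted to the union of several epochs."""
        return self.trains[unit_id].restrict([self.epochs[l] for l in labels])
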