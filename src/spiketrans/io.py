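"""Readers and writers for the delimited-text session formats.

Formats (all tab-separated, one header row, times in seconds written with six
decimal places):

* ``spikes.tsv`` — ``unit_id  time_s  cell_class  shank``, one spike per row.
* ``events.tsv`` — ``onset_s  duration_s  trigger_unit`` (trigger may be empty).
* ``epochs.tsv`` — ``label  start_s  end_s``.

``read_session(write_session(s))`` restores the session bit-identically; all
downstream modules consume the in-memory types only and never re-parse files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .core import CellClass, EpochSet, Session, SpikeTrain, StimulusEvents

__all__ = ["read_session", "write_session", "load_config", "save_config"]

_TIME_FMT = "{:.6f}"

SPIKES_HEADER = ["unit_id", "time_s", "cell_class", "shank"]
EVENTS_HEADER = ["onset_s", "duration_s", "trigger_unit"]
EPOCHS_HEADER = ["label", "start_s", "end_s"]


class FormatError(ValueError):
    """A malformed row, reported with file, line and field."""


def _parse_float(value: str, path: Path, lineno: int, fieldname: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: field {fieldname!r}: not a number: {value!r}"
        ) from None


def _read_rows(path: Path, header: list[str]):
    with open(path) as fh:
        first = fh.readline()
        cols = first.rstrip("\n").split("\t")
        if cols != header:
            raise FormatError(
                f"{path}:1: expected header {header}, found {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"found {len(fields)}"
                )
            yield lineno, fields


def read_session(
    spike_table_path: str | Path,
    epoch_table_path: str | Path,
    event_table_path: str | Path | None = None,
    stim_duration_s: float = 0.030,
    dead_time_s: float = 0.020,
) -> Session:
    """Read a session from ``spikes.tsv``, ``epochs.tsv`` and optional ``events.tsv``.

    All invariants of the in-memory types are enforced; malformed rows raise
    :class:`FormatError` naming the file, line and field.
    """
    spike_path = Path(spike_table_path)
    times: dict[str, list[float]] = {}
    meta: dict[str, tuple[str, int]] = {}
    for lineno, (uid, t, cc, shank) in _read_rows(spike_path, SPIKES_HEADER):
        if not uid:
            raise FormatError(f"{spike_path}:{lineno}: field 'unit_id': empty")
        tval = _parse_float(t, spike_path, lineno, "time_s")
        if cc not in CellClass.__members__:
            raise FormatError(
                f"{spike_path}:{lineno}: field 'cell_class': unknown class {cc!r}"
            )
        try:
            shank_i = int(shank)
        except ValueError:
            raise FormatError(
                f"{spike_path}:{lineno}: field 'shank': not an integer: {shank!r}"
            ) from None
        prev = meta.get(uid)
        if prev is not None and prev != (cc, shank_i):
            raise FormatError(
                f"{spike_path}:{lineno}: unit {uid!r}: inconsistent metadata"
            )
        meta[uid] = (cc, shank_i)
        bucket = times.setdefault(uid, [])
        if bucket and tval <= bucket[-1]:
            raise FormatError(
                f"{spike_path}:{lineno}: field 'time_s': unsorted time for "
                f"unit {uid!r}"
            )
        bucket.append(tval)

    epoch_path = Path(epoch_table_path)
    intervals: dict[str, tuple[float, float]] = {}
    for lineno, (label, a, b) in _read_rows(epoch_path, EPOCHS_HEADER):
        if label in intervals:
            raise FormatError(f"{epoch_path}:{lineno}: duplicate epoch {label!r}")
        intervals[label] = (
            _parse_float(a, epoch_path, lineno, "start_s"),
            _parse_float(b, epoch_path, lineno, "end_s"),
        )
    epochs = EpochSet(intervals)

    if event_table_path is not None:
        event_path = Path(event_table_path)
        onsets: list[float] = []
        durations: list[float] = []
        triggers: list[str | None] = []
        for lineno, (onset, dur, trig) in _read_rows(event_path, EVENTS_HEADER):
            onsets.append(_parse_float(onset, event_path, lineno, "onset_s"))
            durations.append(_parse_float(dur, event_path, lineno, "duration_s"))
            triggers.append(trig or None)
        duration = durations[0] if durations else stim_duration_s
        if durations and any(d != duration for d in durations):
            raise FormatError(f"{event_path}: mixed stimulus durations")
        events = StimulusEvents(
            np.array(onsets),
            duration,
            dead_time_s,
            tuple(triggers) if onsets else None,
        )
    else:
        events = StimulusEvents(np.array([]), stim_duration_s, dead_time_s)

    trains = {
        uid: SpikeTrain(uid, np.array(ts), CellClass(meta[uid][0]), meta[uid][1])
        for uid, ts in times.items()
    }
    return Session(trains=trains, epochs=epochs, events=events)


def write_session(session: Session, out_dir: str | Path) -> dict[str, Path]:
    """Write a session to ``out_dir``; returns the paths written.

    Spike rows are emitted in time order across units so that re-reading and
    re-writing is byte-stable. Times use fixed six-decimal precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": out / "spikes.tsv",
        "events": out / "events.tsv",
        "epochs": out / "epochs.tsv",
    }

    rows = []
    for uid, train in session.trains.items():
        cc, shank = train.cell_class.value, train.shank
        for t in train.times:
            rows.append((t, uid, cc, shank))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(paths["spikes"], "w") as fh:
        fh.write("\t".join(SPIKES_HEADER) + "\n")
        for t, uid, cc, shank in rows:
            fh.write(f"{uid}\t{_TIME_FMT.format(t)}\t{cc}\t{shank}\n")

    with open(paths["events"], "w") as fh:
        fh.write("\t".join(EVENTS_HEADER) + "\n")
        ev = session.events
        triggers = ev.trigger_unit or (None,) * ev.n_events
        for onset, trig in zip(ev.onsets, triggers):
            fh.write(
                f"{_TIME_FMT.format(onset)}\t{_TIME_FMT.format(ev.duration_s)}"
                f"\t{trig or ''}\n"
            )

    with open(paths["epochs"], "w") as fh:
        fh.write("\t".join(EPOCHS_HEADER) + "\n")
        for label, (a, b) in session.epochs.intervals.items():
            fh.write(
                f"{label}\t{_TIME_FMT.format(a)}\t{_TIME_FMT.format(b)}\n"
            )
    return paths


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON pipeline-configuration mapping."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            cfg = json.load(fh)
        else:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(cfg, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            yaml.safe_dump(cfg, fh, sort_keys=True)
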