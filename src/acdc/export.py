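"""Tabular text writers, note-event export, a minimal MIDI writer, manifests.

All tabular formats are tab-separated text with a header row and round-trip
losslessly through pandas. MIDI export writes a type-0 Standard MIDI File
with one note-on/note-off pair per executed action (duration = the Action
trace's supra-threshold span); the writer is deliberately minimal -- a
single tempo event and fixed-velocity notes.
"""

from __future__ import annotations

import dataclasses
import json
import struct
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dynamics import TrialRecord
from .fixtures import MIDI_PITCHES
from .params import ModelParams
from .plasticity import SequenceSpec

__all__ = [
    "write_traces",
    "write_events",
    "note_events",
    "export_note_events",
    "write_midi",
    "RunManifest",
]


def write_traces(record: TrialRecord, path: Union[str, Path]) -> None:
    """One row per timestep: time_ms, x_000..., inh, g_0..., n_0..., a_0...."""
    if record.x is None:
        raise ValueError("record has no full traces (record_full=False)")
    n = record.x.shape[1]
    k = record.n_actions
    data = {"time_ms": record.time_ms}
    for i in range(n):
        data[f"x_{i:03d}"] = record.x[:, i]
    data["inh"] = record.inh
    for j in range(k):
        data[f"g_{j}"] = record.g[:, j]
    for j in range(k):
        data[f"n_{j}"] = record.n[:, j]
    for j in range(k):
        data[f"a_{j}"] = record.a[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_events(record: TrialRecord, path: Union[str, Path],
                 labels: Optional[Sequence[str]] = None) -> None:
    """Detected events: action_index, order_index, event_time_ms, crossings."""
    order_of = {int(a): i for i, a in enumerate(record.event_order)}
    rows = []
    for j in range(record.n_actions):
        rows.append({
            "action_index": j,
            "order_index": order_of.get(j, -1),
            "event_time_ms": record.event_times[j],
            "crossing_count": int(record.crossing_counts[j]),
            "note_label": labels[j] if labels is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def note_events(record: TrialRecord, spec: SequenceSpec,
                threshold: float = 0.5) -> pd.DataFrame:
    """Executed actions as note events (onset_ms, duration_ms, note_label).

    The duration is the supra-threshold span of the Action trace starting at
    the first crossing.
    """
    rows = []
    for j in range(record.n_actions):
        t = record.event_times[j]
        if np.isnan(t):
            continue
        onset_idx = int(round(t / record.dt))
        above = record.a[onset_idx:, j] >= threshold
        off = np.argmin(above) if not above.all() else len(above)
        label = spec.note_labels[j] if spec.note_labels is not None else f"action_{j}"
        rows.append({"onset_ms": t, "duration_ms": float(off * record.dt),
                     "note_label": label})
    df = pd.DataFrame(rows, columns=["onset_ms", "duration_ms", "note_label"])
    return df.sort_values("onset_ms").reset_index(drop=True)


def export_note_events(record: TrialRecord, spec: SequenceSpec,
                       path: Union[str, Path], fmt: str = "tsv") -> None:
    """Write note events as tab-separated text or a Standard MIDI File."""
    events = note_events(record, spec)
    if fmt == "tsv":
        events.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "midi":
        if spec.note_labels is None:
            raise ValueError("MIDI export requires a sequence with note labels")
        write_midi(events, path)
    else:
        raise ValueError(f"format must be 'tsv' or 'midi', got {fmt!r}")


# -- minimal type-0 Standard MIDI File writer --------------------------------

def _varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def write_midi(events: pd.DataFrame, path: Union[str, Path],
               pitch_map: Optional[Dict[str, int]] = None,
               ticks_per_beat: int = 480, us_per_beat: int = 500000,
               velocity: int = 96) -> None:
    """Write (onset_ms, duration_ms, note_label) rows as a type-0 SMF.

    Default tempo is 120 bpm (500000 us per quarter note); note labels are
    mapped to MIDI pitches via ``pitch_map`` (default: the riff's pitch set,
    scientific notation with C4 = 60).
    """
    pitch_map = pitch_map or MIDI_PITCHES
    ticks_per_ms = ticks_per_beat / (us_per_beat / 1000.0)

    messages: List[tuple] = []  # (tick, order, bytes)
    for _, row in events.iterrows():
        label = row["note_label"]
        if label not in pitch_map:
            raise ValueError(f"no MIDI pitch for note label {label!r}")
        pitch = pitch_map[label]
        on = int(round(row["onset_ms"] * ticks_per_ms))
        off = int(round((row["onset_ms"] + max(row["duration_ms"], 1.0)) * ticks_per_ms))
        messages.append((on, 1, bytes((0x90, pitch, velocity))))
        messages.append((off, 0, bytes((0x80, pitch, 0))))
    messages.sort()

    track = bytearray()
    track += _varlen(0) + bytes((0xFF, 0x51, 0x03)) + struct.pack(">I", us_per_beat)[1:]
    prev = 0
    for tick, _, msg in messages:
        track += _varlen(tick - prev) + msg
        prev = tick
    track += _varlen(0) + bytes((0xFF, 0x2F, 0x00))

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_beat))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


@dataclass
class RunManifest:
    """Provenance of one command-line run: enough to reproduce it bitwise."""

    command: str
    seed: int
    params: dict
    outputs: List[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)
    package_version: str = ""
    created_utc: str = ""

    @classmethod
    def create(cls, command: str, seed: int, params: ModelParams,
               **extra) -> "RunManifest":
        from . import __version__

        return cls(command=command, seed=seed, params=params.to_dict(),
                   extra=extra, package_version=__version__,
                   created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()))

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")
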