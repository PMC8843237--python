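"""Built-in sequence specifications and tempo grids.

``"sim1"`` is the canonical six-action asynchronous sequence (targets at
200, 250, 400, 700, 750 and 900 ms in a 1 s window). ``"thunderstruck"`` is
the sixteen-note guitar-riff fixture: isosynchronous eighth notes at
140 bpm (214.29 ms apart) spanning a 3500 ms window, using six distinct
pitches. The note *order* is a stylised reconstruction over the six printed
pitches (alternating the pedal note with a descending line); event count,
grid and pitch set are the load-bearing features. The ``"bossa"`` tempo grid
is likewise a stylised syncopated re-timing of the sixteen events (interval
cycle 300/200/150/250 ms), used by the compositionality demo.
"""

from __future__ import annotations

import numpy as np

from .plasticity import SequenceSpec

__all__ = ["fixture_sequence", "fixture_tempo_grid", "RIFF_NOTE_ORDER",
           "MIDI_PITCHES"]

#: Stylised sixteen-event note order over the riff's six pitches.
RIFF_NOTE_ORDER = ("B5", "A5", "B5", "G#5", "B5", "A5", "B5", "G#5",
                   "B5", "F#5", "B5", "E5", "B5", "F#5", "B5", "D#5")

#: Scientific pitch notation with middle C = C4 = MIDI 60.
MIDI_PITCHES = {"B5": 83, "A5": 81, "G#5": 80, "F#5": 78, "E5": 76, "D#5": 75}

_EIGHTH_MS = 60000.0 / 140.0 / 2.0   # eighth note at 140 bpm = 214.2857 ms

_BOSSA_INTERVAL_CYCLE = (300.0, 200.0, 150.0, 250.0)


def fixture_sequence(name: str) -> SequenceSpec:
    """A packaged sequence specification by name ("sim1" or "thunderstruck")."""
    if name == "sim1":
        return SequenceSpec((200., 250., 400., 700., 750., 900.),
                            window_ms=1000.0)
    if name == "thunderstruck":
        times = tuple(_EIGHTH_MS * k for k in range(1, 17))
        return SequenceSpec(times, window_ms=3500.0,
                            note_labels=RIFF_NOTE_ORDER)
    raise ValueError(f"unknown fixture {name!r}; available: "
                     "'sim1', 'thunderstruck'")


def fixture_tempo_grid(name: str) -> np.ndarray:
    """A packaged desired-time grid by name (currently only "bossa")."""
    if name == "bossa":
        intervals = [_BOSSA_INTERVAL_CYCLE[k % 4] for k in range(16)]
        return np.cumsum(intervals)
    raise ValueError(f"unknown tempo grid {name!r}; available: 'bossa'")
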