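import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p300composer import composer_core as cc
from p300composer.composer_core import ComposerState, Note, apply_command


def run(tokens, state=None):
    state = state or ComposerState()
    events = []
    for t in tokens:
        events += apply_command(state, t)
    return state, events


class TestGrammar:
    def test_length_latches_across_insertions(self):
        state, _ = run(["len:quarter", "pitch:C", "pitch:E", "pitch:G"])
        assert [n.pitch for n in state.score] == ["C", "E", "G"]
        assert all(n.length == "quarter" for n in state.score)

    def test_accidental_and_dot_are_one_shot(self):
        state, _ = run(["acc:sharp", "dot", "len:quarter", "pitch:F", "pitch:G"])
        f, g = state.score
        assert (f.accidental, f.dotted) == ("sharp", True)
        assert (g.accidental, g.dotted) == ("none", False)

    def test_chord_latches_until_toggled(self):
        state, _ = run(["chord", "pitch:C", "pitch:E", "pitch:G", "chord", "pitch:D"])
        c, e, g, d = state.score
        assert c.chord_group is not None
        assert c.chord_group == e.chord_group == g.chord_group
        assert d.chord_group is None
        # chord members share one onset
        onsets = [ev.onset for ev in cc.play(state, "all")]
        assert onsets[0] == onsets[1] == onsets[2] < onsets[3]

    def test_slurred_notes_share_a_group(self):
        state, _ = run(["slur", "pitch:C", "pitch:D", "slur", "pitch:E"])
        c, d, e = state.score
        assert c.slur_group is not None and c.slur_group == d.slur_group
        assert e.slur_group is None

    def test_octave_steps_and_navigation_clamped(self):
        state, _ = run(["oct:up", "pitch:C"])
        assert state.score[0].octave == 5
        with pytest.warns(UserWarning):
            apply_command(state, "nav:note:next")  # already on the last note
        state2, _ = run(["pitch:C", "pitch:D", "nav:note:prev"])
        assert state2.cursor == 0

    def test_rest_insertion_carries_no_pitch(self):
        state, _ = run(["len:half", "rest"])
        r = state.score[0]
        assert r.is_rest and r.pitch is None and r.beats == 2.0

    def test_delete_undoes_insert(self):
        state, _ = run(["len:eighth", "pitch:A", "acc:flat", "pitch:B"])
        before = state.snapshot()
        apply_command(state, "pitch:D")
        apply_command(state, "delete")
        assert state.snapshot() == before

    def test_delete_on_empty_score_warns(self):
        state = ComposerState()
        with pytest.warns(UserWarning):
            apply_command(state, "delete")
        assert state.score == []

    def test_unknown_token_rejected(self):
        with pytest.raises(cc.GrammarError):
            apply_command(ComposerState(), "pitch:H")
        with pytest.raises(cc.GrammarError):
            apply_command(ComposerState(), "frobnicate")

    def test_bar_navigation_jumps_a_full_measure(self):
        tokens = ["pitch:C"] * 8  # two 4/4 bars of quarters
        state, _ = run(tokens)
        apply_command(state, "nav:bar:prev")
        assert state.cursor == 3  # last note of bar 1
        apply_command(state, "nav:bar:next")
        assert state.cursor == 7


TOKENS = (
    [f"len:{l}" for l in cc.LENGTH_BEATS]
    + [f"acc:{a}" for a in cc.ACCIDENTALS]
    + [f"pitch:{p}" for p in cc.PITCH_LETTERS]
    + ["dot", "slur", "chord", "rest", "oct:up", "oct:down",
       "nav:note:prev", "nav:note:next", "delete", "play:all", "play:rest"]
)


class TestGrammarProperties:
    @given(st.lists(st.sampled_from(TOKENS), min_size=1, max_size=40))
    @settings(max_examples=300, deadline=None)
    def test_one_shot_flags_cleared_after_every_insertion(self, tokens):
        state = ComposerState()
        for t in tokens:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                apply_command(state, t)
            if t.startswith("pitch:") or t == "rest":
                assert state.pending_accidental is None
                assert state.pending_dot is False

    @given(st.lists(st.sampled_from(TOKENS), min_size=1, max_size=40))
    @settings(max_examples=300, deadline=None)
    def test_latch_state_flips_once_per_toggle_token(self, tokens):
        import warnings

        state = ComposerState()
        slur_changes = chord_changes = 0
        prev = (state.slur_active, state.chord_active)
        for t in tokens:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                apply_command(state, t)
            cur = (state.slur_active, state.chord_active)
            slur_changes += prev[0] != cur[0]
            chord_changes += prev[1] != cur[1]
            prev = cur
        assert slur_changes == tokens.count("slur")
        assert chord_changes == tokens.count("chord")

    @given(st.lists(st.sampled_from(TOKENS), min_size=0, max_size=30),
           st.sampled_from(cc.PITCH_LETTERS))
    @settings(max_examples=200, deadline=None)
    def test_insert_then_delete_restores_document(self, tokens, pitch):
        """Deleting a just-inserted note restores the score, cursor and modes.

        Pending one-shot modifiers are excluded: they are consumed by the
        insertion (that is the one-shot property) and are not re-armed.
        """
        import warnings

        def doc_view(snap):
            score, cursor, length, _acc, _dot, slur, chord, octave = snap
            return (score, cursor, length, slur, chord, octave)

        state = ComposerState()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in tokens:
                apply_command(state, t)
            before = doc_view(state.snapshot())
            apply_command(state, f"pitch:{pitch}")
            apply_command(state, "delete")
        assert doc_view(state.snapshot()) == before


class TestPlayback:
    def test_empty_score_plays_nothing(self):
        assert cc.play(ComposerState(), "all") == []

    def test_quarter_notes_land_on_successive_beats(self):
        state, _ = run(["pitch:C", "pitch:D", "pitch:E"])
        events = cc.play(state, "all")
        assert [ev.onset for ev in events] == [0.0, 1.0, 2.0]
        assert [ev.duration for ev in events] == [1.0, 1.0, 1.0]

    def test_play_rest_starts_after_the_cursor(self):
        state, _ = run(["pitch:C", "pitch:D", "pitch:E", "pitch:F", "pitch:G"])
        state.cursor = 1  # sitting on the second note
        events = cc.play(state, "rest")
        assert len(events) == 3
        assert [ev.midi for ev in events] == [Note("E", 4).midi, Note("F", 4).midi,
                                              Note("G", 4).midi]

    def test_midi_numbers(self):
        assert Note("C", 4).midi == 60
        assert Note("A", 4).midi == 69
        assert Note("B", 3, accidental="flat").midi == 58


class TestExport:
    def test_single_quarter_note_document(self):
        state, _ = run(["pitch:C"])
        xml = cc.export_musicxml(state)
        assert xml.count("<note>") == 1
        assert "<step>C</step>" in xml and "<type>quarter</type>" in xml
        assert "<duration>8</duration>" in xml  # 8 divisions per quarter

    def test_dotted_half_spans_three_beats(self):
        state, _ = run(["len:half", "dot", "pitch:G"])
        assert state.score[0].beats == 3.0
        xml = cc.export_musicxml(state)
        assert "<duration>24</duration>" in xml and "<dot />" in xml

    def test_round_trip_preserves_note_list(self):
        tokens = ["len:eighth", "pitch:C", "acc:sharp", "pitch:D", "len:quarter",
                  "dot", "pitch:E", "slur", "pitch:F", "pitch:G", "slur",
                  "len:half", "rest", "chord", "pitch:A", "pitch:C", "chord"]
        state, _ = run(tokens)
        notes = cc.import_musicxml(cc.export_musicxml(state))
        assert notes == cc.canonical_notes(state.score)

    def test_export_import_export_is_byte_stable(self):
        state, _ = run(["pitch:C", "slur", "pitch:D", "pitch:E", "slur",
                        "acc:flat", "pitch:B"])
        x1 = cc.export_musicxml(state)
        x2 = cc.export_musicxml(cc.state_from_notes(cc.import_musicxml(x1)))
        assert x1 == x2

    def test_midi_file_structure(self):
        state, _ = run(["pitch:C", "pitch:E", "chord", "pitch:G", "pitch:B", "chord"])
        blob = cc.export_midi(state)
        assert blob[:4] == b"MThd" and blob[14:18] == b"MTrk"
        n_on = blob.count(bytes([0x90]))
        assert n_on >= 4  # one note-on per pitch
        assert blob.endswith(bytes([0xFF, 0x2F, 0x00]))


class TestSelectionCounting:
    def test_single_default_length_note_costs_three(self):
        assert cc.min_selection_count([Note("C", 4, "quarter")]) == 3

    def test_shared_nondefault_length_costs_once(self):
        melody = [Note("C", 4, "half"), Note("D", 4, "half")]
        assert cc.min_selection_count(melody) == 5

    def test_modifiers_count_per_use(self):
        melody = [Note("F", 4, "quarter", dotted=True, accidental="sharp"),
                  Note("G", 4, "quarter")]
        # Compose + sharp + dot + F + G + play all
        assert cc.min_selection_count(melody) == 6

    def test_octave_steps_counted(self):
        melody = [Note("C", 5, "quarter")]
        assert cc.min_selection_count(melody) == 4

    def test_alouette_fixture_requires_41_selections(self):
        assert cc.min_selection_count(cc.load_alouette()) == 41
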