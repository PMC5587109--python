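"""Closed-loop simulation of the study tasks and their performance metrics.

A simulated user replaces the participant: for every selection the system
generates a randomized flash schedule, the user "attends" the intended matrix
element (or, with some lapse probability, a wrong one), synthetic EEG is
produced, band-pass filtered, epoched and decoded sequence by sequence under
the dynamic stopping rule.  Three tasks mirror the study protocol:

* copy-spelling of given words — errors are not corrected;
* copy-composing of a given melody — after each error the user performs
  corrective selections (navigate, delete, re-enter), and the run is aborted
  once the selection count reaches the 62-70 window with completion no longer
  possible within 70 selections;
* free composing from a scripted command policy with a 30-minute cap.

Every selection is logged with the intended and the actual element, sequences
used, resets and simulated timestamps; accuracy is the ratio of correct to
made selections and timing follows the stimulation parameters (50 ms flash,
125 ms ISI) plus the configured inter-selection pause.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import composer_core as cc
from .composer_core import (ComposerState, CompositionPlanner, GrammarConfig,
                            Note, apply_command)
from .decoder import ErpClassifier, SelectionController, build_features, train
from .matrix_engine import MatrixSet, load_bundled_matrices, make_schedule
from .signal_sim import RecordingParams, bandpass, extract_epochs, synthesize_recording


@dataclass(frozen=True)
class TimingModel:
    """Stimulation and pause timing in seconds (study defaults)."""

    flash: float = 0.050
    isi: float = 0.125
    pause_calibration: float = 4.0
    pause_spelling: float = 6.0
    pause_composing: float = 10.0
    overhead: float = 0.0  # unmodeled per-selection overhead (marking, resets)

    def __post_init__(self):
        for name in ("flash", "isi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def soa(self) -> float:
        return self.flash + self.isi


@dataclass
class SimulatedUser:
    """Stands in for the participant: intention + attention quality."""

    params: RecordingParams = field(default_factory=RecordingParams)
    lapse_probability: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.lapse_probability <= 1.0:
            raise ValueError("lapse probability must be in [0, 1]")


@dataclass
class BciSystem:
    """The decoding pipeline configuration shared by all tasks."""

    matrices: MatrixSet = field(default_factory=load_bundled_matrices)
    classifier: ErpClassifier | None = None
    timing: TimingModel = field(default_factory=TimingModel)
    window: tuple[float, float] = (0.0, 0.8)
    baseline: tuple[float, float] | None = (-0.1, 0.0)
    decimation: int = 12
    max_sequences: int = 15
    max_resets: int = 3
    filter_band: tuple[float, float] = (1.0, 15.0)
    filter_order: int = 4


@dataclass
class SelectionRecord:
    phase: str
    intended_index: int | None
    selected_index: int | None
    intended_symbol: str
    selected_symbol: str
    n_sequences: int
    resets: int
    stopped_by: str
    t_start: float
    t_end: float
    word: str = ""

    @property
    def correct(self) -> bool:
        return self.selected_index is not None and self.selected_index == self.intended_index


@dataclass
class SessionLog:
    """Per-selection protocol of a task run."""

    records: list[SelectionRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    aborted: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": [r.phase for r in self.records],
                "word": [r.word for r in self.records],
                "intended": [r.intended_symbol for r in self.records],
                "selected": [r.selected_symbol for r in self.records],
                "correct": [r.correct for r in self.records],
                "n_sequences": [r.n_sequences for r in self.records],
                "resets": [r.resets for r in self.records],
                "t_start": [r.t_start for r in self.records],
                "t_end": [r.t_end for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def accuracy(log: SessionLog) -> float:
    """Percent of selections whose intended and actual elements coincide.

    Defined as 100 x (correct selections) / (made selections), reported to two
    decimals; undefined for an empty log.
    """
    if not log.records:
        raise ValueError("accuracy is undefined for an empty session log")
    correct = sum(r.correct for r in log.records)
    return round(100.0 * correct / len(log.records), 2)


@dataclass
class TimingSummary:
    total_seconds: float
    selections_per_minute: float
    per_group_seconds: dict[str, float]


def timing_summary(log: SessionLog, timing: TimingModel | None = None) -> TimingSummary:
    """Durations and selection rate from the simulated clock."""
    if not log.records:
        return TimingSummary(0.0, 0.0, {})
    total = log.records[-1].t_end - log.records[0].t_start
    spm = len(log.records) / (total / 60.0) if total > 0 else 0.0
    per_group: dict[str, float] = {}
    for key in dict.fromkeys(r.word or r.phase for r in log.records):
        rs = [r for r in log.records if (r.word or r.phase) == key]
        per_group[key] = rs[-1].t_end - rs[0].t_start
    return TimingSummary(total, spm, per_group)


class _SelectionEngine:
    """Runs single dynamic-stopping selections against the simulator."""

    def __init__(self, system: BciSystem, user: SimulatedUser, rng: np.random.Generator):
        if system.classifier is None:
            raise ValueError("system has no trained classifier; run calibration first")
        self.system = system
        self.user = user
        self.rng = rng

    def _attended(self, intended: tuple[int, int], n_rows: int, n_cols: int) -> tuple[int, int]:
        if self.user.lapse_probability and self.rng.random() < self.user.lapse_probability:
            others = [(r, c) for r in range(n_rows) for c in range(n_cols)
                      if (r, c) != intended]
            return others[self.rng.integers(len(others))]
        return intended

    def select(self, matrix_name: str, intended_index: int):
        """One selection block; returns (selected_index | None, n_seq, resets, stopped_by)."""
        sys_ = self.system
        spec = sys_.matrices.spec(matrix_name)
        intended_rc = divmod(intended_index, spec.cols)
        ctrl = SelectionController(sys_.classifier, spec.rows, spec.cols,
                                   sys_.max_sequences, sys_.max_resets)
        result = None
        while result is None:
            attended = self._attended(intended_rc, spec.rows, spec.cols)
            schedule = make_schedule(
                spec.rows, spec.cols, sys_.max_sequences,
                sys_.timing.flash, sys_.timing.isi,
                seed=int(self.rng.integers(2**31)),
            )
            params = replace(self.user.params, seed=int(self.rng.integers(2**31)))
            rec = bandpass(
                synthesize_recording(schedule, attended, params),
                order=sys_.filter_order, band=sys_.filter_band, mode="causal",
            )
            epochs = extract_epochs(rec, attended, sys_.window, sys_.baseline)
            for s in range(sys_.max_sequences):
                result = ctrl.feed_sequence(epochs.sequence(s))
                if result is not None or ctrl.needs_restart:
                    break
        selected = None
        if result.selected is not None:
            selected = result.selected[0] * spec.cols + result.selected[1]
        return selected, result.n_sequences_used, result.reset_count, result.stopped_by


def simulate_calibration(
    user: SimulatedUser,
    system: BciSystem,
    letters: str = "H3P5FU",
    n_sequences: int = 15,
    matrix_name: str = "letters",
    seed: int | None = None,
):
    """Simulate the calibration run and return (blocks, targets).

    One block of ``n_sequences`` labeled epoch sequences per calibration
    letter, suitable for :func:`p300composer.decoder.calibrate_loo` or for
    training the online classifier.
    """
    rng = np.random.default_rng(seed if seed is not None else user.seed)
    spec = system.matrices.spec(matrix_name)
    blocks, targets = [], []
    for ch in letters:
        idx = spec.index_of_symbol(ch)
        rc = divmod(idx, spec.cols)
        schedule = make_schedule(spec.rows, spec.cols, n_sequences,
                                 system.timing.flash, system.timing.isi,
                                 seed=int(rng.integers(2**31)))
        params = replace(user.params, seed=int(rng.integers(2**31)))
        rec = bandpass(synthesize_recording(schedule, rc, params),
                       order=system.filter_order, band=system.filter_band, mode="causal")
        blocks.append(extract_epochs(rec, rc, system.window, system.baseline))
        targets.append(rc)
    return blocks, targets


def train_from_calibration(system: BciSystem, blocks) -> ErpClassifier:
    """Fit the online classifier on all calibration epochs."""
    full = blocks[0]
    for b in blocks[1:]:
        full = full.concat(b)
    clf = train(build_features(full, system.decimation), full.labels, system.decimation)
    system.classifier = clf
    return clf


def run_copy_spelling(
    words: list[str],
    user: SimulatedUser,
    system: BciSystem,
    seed: int | None = None,
    matrix_name: str = "letters",
) -> SessionLog:
    """Copy-spell the given words; misclassifications are not corrected."""
    rng = np.random.default_rng(seed if seed is not None else user.seed)
    engine = _SelectionEngine(system, user, rng)
    spec = system.matrices.spec(matrix_name)
    log = SessionLog(meta={"task": "copy-spelling", "words": list(words)})
    t = 0.0
    pause = system.timing.pause_spelling
    for word in words:
        for pos, ch in enumerate(word):
            try:
                idx = spec.index_of_symbol(ch)
            except KeyError as exc:
                raise ValueError(f"character {ch!r} not in matrix {matrix_name!r}") from exc
            selected, n_seq, resets, stopped_by = engine.select(matrix_name, idx)
            t_end = t + n_seq * (spec.rows + spec.cols) * system.timing.soa \
                + system.timing.overhead
            log.records.append(SelectionRecord(
                "copy-spelling", idx, selected, ch,
                spec.items[selected].symbol if selected is not None else "",
                n_seq, resets, stopped_by, t, t_end, word=word,
            ))
            t = t_end + (pause if pos < len(word) - 1 else 0.0)
        t += pause  # break before the next word
    return log


def _remaining_min_selections(planner: CompositionPlanner, state: ComposerState,
                              in_composing: bool, played: bool) -> int:
    """Selections still needed to finish the copy-composing task error-free."""
    sim = ComposerState(
        score=[replace(n) for n in state.score],
        cursor=state.cursor, current_length=state.current_length,
        pending_accidental=state.pending_accidental, pending_dot=state.pending_dot,
        slur_active=state.slur_active, chord_active=state.chord_active,
        current_octave=state.current_octave, beats_per_bar=state.beats_per_bar,
        _next_group_id=state._next_group_id,
    )
    count = 0
    ic, pl = in_composing, played
    while True:
        token = planner.next_token(sim, ic, pl)
        if token is None:
            return count
        count += 1
        if count > 1000:
            raise RuntimeError("planner failed to terminate")
        if token == cc.COMPOSE_TOKEN:
            ic = True
        elif token == "play:all":
            apply_command(sim, token)
            pl = True
        else:
            apply_command(sim, token)


def run_copy_composing(
    melody: list[Note],
    user: SimulatedUser,
    system: BciSystem,
    seed: int | None = None,
    abort_window: tuple[int, int] = (62, 70),
) -> SessionLog:
    """Copy-compose a melody with error correction and the abort rule.

    The simulated user follows the planner's minimal command stream; after a
    misclassification the planner's repair (navigate/delete/re-enter) extends
    the intended stream.  The run is aborted at the first selection count
    inside ``abort_window`` at which finishing within its upper bound has
    become impossible.
    """
    rng = np.random.default_rng(seed if seed is not None else user.seed)
    engine = _SelectionEngine(system, user, rng)
    planner = CompositionPlanner(melody)
    mset = system.matrices
    main_spec = mset.spec(mset.entry)
    comp_name = "composing"
    comp_spec = mset.spec(comp_name)

    state = ComposerState()
    in_composing = False
    played = False
    log = SessionLog(meta={"task": "copy-composing", "n_target_notes": len(melody)})
    t = 0.0
    pause = system.timing.pause_composing
    lo, hi = abort_window

    while True:
        token = planner.next_token(state, in_composing, played)
        if token is None:
            break
        n_made = len(log.records)
        if n_made >= lo:
            remaining = _remaining_min_selections(planner, state, in_composing, played)
            if n_made + remaining > hi:
                log.aborted = True
                break
        if token == cc.COMPOSE_TOKEN:
            matrix_name, spec = mset.entry, main_spec
            intended_idx = spec.index_of_symbol("Compose")
        else:
            matrix_name, spec = comp_name, comp_spec
            intended_idx = spec.index_of_value(token)

        selected, n_seq, resets, stopped_by = engine.select(matrix_name, intended_idx)
        t_end = t + n_seq * (spec.rows + spec.cols) * system.timing.soa \
            + system.timing.overhead
        sel_symbol = spec.items[selected].symbol if selected is not None else ""
        log.records.append(SelectionRecord(
            "copy-composing", intended_idx, selected, spec.items[intended_idx].symbol,
            sel_symbol, n_seq, resets, stopped_by, t, t_end,
        ))
        t = t_end + pause

        if selected is None:
            continue  # nothing reached the application
        item = spec.items[selected]
        if matrix_name == mset.entry:
            if item.symbol == "Compose":
                in_composing = True
            # other menu selections open dialogs; they do not change the score
        else:
            if item.link:  # e.g. MENU: leaves the composing matrix
                in_composing = False
            else:
                apply_command(state, item.value)
                if item.value == "play:all" and planner._match_len(state.score) == len(melody) \
                        and len(state.score) == len(melody):
                    played = True
    log.meta["completed"] = not log.aborted
    log.meta["min_selections"] = cc.min_selection_count(melody)
    return log


def run_free_composing(
    policy_tokens: list[str],
    user: SimulatedUser,
    system: BciSystem,
    seed: int | None = None,
    max_minutes: float = 30.0,
) -> SessionLog:
    """Free composing: the user works through a scripted command policy.

    Selections proceed until the policy is exhausted or the simulated clock
    exceeds ``max_minutes``.  Misclassifications are flagged in the log (the
    participant announces them) but not corrected by the system.
    """
    rng = np.random.default_rng(seed if seed is not None else user.seed)
    engine = _SelectionEngine(system, user, rng)
    comp_spec = system.matrices.spec("composing")
    state = ComposerState()
    log = SessionLog(meta={"task": "free-composing", "max_minutes": max_minutes})
    t = 0.0
    pause = system.timing.pause_composing
    for token in policy_tokens:
        if t > max_minutes * 60.0:
            log.meta["stopped_by_clock"] = True
            break
        intended_idx = comp_spec.index_of_value(token)
        selected, n_seq, resets, stopped_by = engine.select("composing", intended_idx)
        t_end = t + n_seq * (comp_spec.rows + comp_spec.cols) * system.timing.soa \
            + system.timing.overhead
        log.records.append(SelectionRecord(
            "free-composing", intended_idx, selected,
            comp_spec.items[intended_idx].symbol,
            comp_spec.items[selected].symbol if selected is not None else "",
            n_seq, resets, stopped_by, t, t_end,
        ))
        t = t_end + pause
        if selected is not None:
            item = comp_spec.items[selected]
            if not item.link:
                apply_command(state, item.value)
    log.meta["score_notes"] = len(state.score)
    return log


def random_melody_policy(n_notes: int = 10, seed: int | None = None) -> list[str]:
    """A simple generative policy: random diatonic quarter/eighth-note melody."""
    rng = np.random.default_rng(seed)
    tokens: list[str] = []
    length = "quarter"
    for _ in range(n_notes):
        if rng.random() < 0.25:
            new = "eighth" if length == "quarter" else "quarter"
            tokens.append(f"len:{new}")
            length = new
        tokens.append(f"pitch:{cc.PITCH_LETTERS[rng.integers(7)]}")
    tokens.append("play:all")
    return tokens
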