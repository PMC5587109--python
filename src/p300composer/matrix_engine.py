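"""Speller matrices, the selection state machine, and oddball flash scheduling.

A P300 speller presents a grid of symbols and flashes its rows and columns in
random order; the user attends one element, and the rare (attended) flashes
elicit the P300 response.  Matrix contents live in JSON documents: each item
carries a display ``symbol``, an output ``value`` (the key sequence sent to the
controlled application), an optional cross-``link`` naming another matrix to
switch to, and a ``selectable`` flag marking elements that stay highlighted
(latched) after selection.  A single document may define several matrices
connected by cross-links, e.g. a small menu matrix linking to a letter matrix
and a composing matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from pydantic import BaseModel, Field, ValidationError, field_validator


class MatrixError(ValueError):
    """Base class for matrix-document problems."""


class MatrixParseError(MatrixError):
    """The document is not syntactically valid JSON."""


class MatrixSchemaError(MatrixError):
    """An item or matrix is missing required fields or violates an invariant."""


class DanglingLinkError(MatrixError):
    """A cross-link or the entry point names a matrix that does not exist."""


class DuplicateNameError(MatrixError):
    """Two matrices in the same document share a name."""


FILLER_SYMBOL = "–,,–"  # the meaningless placeholder shown on unused cells


class MatrixItem(BaseModel):
    """One cell of a speller matrix."""

    symbol: str = Field(min_length=1)
    value: str = ""
    link: str = ""
    selectable: bool = True


class MatrixSpec(BaseModel):
    """A named rows x cols grid of items, stored row-major."""

    name: str = Field(min_length=1)
    rows: int = Field(gt=0)
    cols: int = Field(gt=0)
    items: list[MatrixItem]

    @field_validator("items")
    @classmethod
    def _sized(cls, v, info):
        rows = info.data.get("rows")
        cols = info.data.get("cols")
        if rows is not None and cols is not None and len(v) != rows * cols:
            raise ValueError(f"expected {rows * cols} items, got {len(v)}")
        return v

    def item_at(self, row: int, col: int) -> MatrixItem:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"({row}, {col}) outside {self.rows}x{self.cols} matrix")
        return self.items[row * self.cols + col]

    def index_of_value(self, value: str) -> int:
        """Row-major index of the first item whose output value matches."""
        for i, it in enumerate(self.items):
            if it.value == value:
                return i
        raise KeyError(f"no item with value {value!r} in matrix {self.name!r}")

    def index_of_symbol(self, symbol: str) -> int:
        for i, it in enumerate(self.items):
            if it.symbol == symbol:
                return i
        raise KeyError(f"no item with symbol {symbol!r} in matrix {self.name!r}")


class MatrixSet(BaseModel):
    """All matrices of a document plus the entry matrix name."""

    entry: str
    matrices: dict[str, MatrixSpec]

    def spec(self, name: str) -> MatrixSpec:
        try:
            return self.matrices[name]
        except KeyError:
            raise DanglingLinkError(f"unknown matrix {name!r}") from None

    def to_json(self) -> str:
        doc = {
            "entry": self.entry,
            "matrices": [
                {
                    "name": m.name,
                    "rows": m.rows,
                    "cols": m.cols,
                    "items": [
                        {
                            "symbol": it.symbol,
                            "value": it.value,
                            "link": it.link,
                            "selectable": it.selectable,
                        }
                        for it in m.items
                    ],
                }
                for m in self.matrices.values()
            ],
        }
        return json.dumps(doc, ensure_ascii=False, indent=1)


def parse_matrix_document(text: str) -> MatrixSet:
    """Parse and validate a JSON matrix document.

    Raises :class:`MatrixParseError` on malformed JSON,
    :class:`MatrixSchemaError` on missing/invalid fields,
    :class:`DuplicateNameError` on repeated matrix names and
    :class:`DanglingLinkError` when a cross-link or the entry point does not
    resolve within the document.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MatrixParseError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "matrices" not in doc:
        raise MatrixSchemaError("document must be an object with a 'matrices' list")

    specs: dict[str, MatrixSpec] = {}
    for raw in doc["matrices"]:
        try:
            spec = MatrixSpec.model_validate(raw)
        except ValidationError as exc:
            raise MatrixSchemaError(str(exc)) from exc
        if spec.name in specs:
            raise DuplicateNameError(f"duplicate matrix name {spec.name!r}")
        specs[spec.name] = spec

    if not specs:
        raise MatrixSchemaError("document defines no matrices")
    entry = doc.get("entry", next(iter(specs)))
    if entry not in specs:
        raise DanglingLinkError(f"entry matrix {entry!r} not defined")
    for spec in specs.values():
        for it in spec.items:
            if it.link and it.link not in specs:
                raise DanglingLinkError(
                    f"item {it.symbol!r} in matrix {spec.name!r} links to "
                    f"unknown matrix {it.link!r}"
                )
    return MatrixSet(entry=entry, matrices=specs)


def load_bundled_matrices() -> MatrixSet:
    """The packaged menu / letter / composing matrices."""
    text = resources.files("p300composer.data").joinpath("matrices.json").read_text("utf-8")
    return parse_matrix_document(text)


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of selecting one matrix element."""

    output_value: str
    next_matrix: str
    latches: frozenset[tuple[str, int]]  # (matrix name, row-major index) pairs now latched


def apply_selection(
    mset: MatrixSet,
    current: str,
    element: int,
    latches: frozenset[tuple[str, int]] = frozenset(),
) -> SelectionOutcome:
    """Apply one selection to the matrix state machine.

    Emits the item's output value, follows its cross-link (if any) and toggles
    the latch state of selectable items (latched elements stay highlighted
    until selected again).
    """
    spec = mset.spec(current)
    if not 0 <= element < spec.rows * spec.cols:
        raise IndexError(f"element {element} outside matrix {current!r}")
    item = spec.items[element]
    next_matrix = item.link if item.link else current
    if item.link:
        mset.spec(item.link)  # re-validate; parse already guarantees this
    new_latches = set(latches)
    if item.selectable:
        key = (current, element)
        if key in new_latches:
            new_latches.discard(key)
        else:
            new_latches.add(key)
    return SelectionOutcome(item.value, next_matrix, frozenset(new_latches))


@dataclass(frozen=True)
class StimulusEvent:
    """One row or column flash."""

    onset: float  # seconds from run start
    group_kind: str  # 'row' | 'column'
    group_index: int  # 0-based
    sequence_index: int
    flash_duration: float

    def contains(self, row: int, col: int) -> bool:
        if self.group_kind == "row":
            return self.group_index == row
        return self.group_index == col


@dataclass(frozen=True)
class FlashSchedule:
    """A full stimulation run: ``n_sequences`` random passes over all groups."""

    events: tuple[StimulusEvent, ...]
    n_sequences: int
    soa: float  # stimulus-onset asynchrony = flash + ISI
    n_rows: int
    n_cols: int

    @property
    def duration(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1].onset + self.soa


def make_schedule(
    n_rows: int,
    n_cols: int,
    n_sequences: int,
    flash: float = 0.050,
    isi: float = 0.125,
    seed: int | None = None,
    inter_sequence_gap: float = 0.0,
) -> FlashSchedule:
    """Randomized row/column flash schedule.

    Each sequence is an independent uniform permutation of the
    ``n_rows + n_cols`` groups; successive onsets are spaced by the SOA
    (flash + ISI).  Across a sequence boundary the permutation is redrawn if
    the same group would flash twice in immediate succession, as is standard
    oddball practice.  Deterministic for a given seed.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("matrix dimensions must be positive")
    if n_sequences < 0:
        raise ValueError("n_sequences must be non-negative")
    if flash <= 0 or isi <= 0:
        raise ValueError("flash and ISI must be positive")

    rng = np.random.default_rng(seed)
    groups = [("row", i) for i in range(n_rows)] + [("column", j) for j in range(n_cols)]
    soa = flash + isi

    events: list[StimulusEvent] = []
    t = 0.0
    prev_last: tuple[str, int] | None = None
    for s in range(n_sequences):
        while True:
            order = [groups[k] for k in rng.permutation(len(groups))]
            if prev_last is None or order[0] != prev_last:
                break
        for kind, idx in order:
            events.append(StimulusEvent(t, kind, idx, s, flash))
            t += soa
        prev_last = order[-1]
        t += inter_sequence_gap
    return FlashSchedule(tuple(events), n_sequences, soa, n_rows, n_cols)


def count_target_flashes(schedule: FlashSchedule, element: tuple[int, int]) -> int:
    """Number of flashes whose group contains the given (row, col) element."""
    row, col = element
    if not (0 <= row < schedule.n_rows and 0 <= col < schedule.n_cols):
        raise IndexError(f"element {element} outside {schedule.n_rows}x{schedule.n_cols}")
    return sum(1 for ev in schedule.events if ev.contains(row, col))
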