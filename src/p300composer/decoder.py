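"""Single-trial ERP decoding with dynamic stopping.

Epochs are reduced to feature vectors by per-channel block averaging and
classified target vs non-target with a shrinkage-regularized linear
discriminant (class-mean difference whitened by a Ledoit-Wolf-shrunk pooled
covariance).  Within a selection block the per-group discriminant scores are
accumulated over flashing sequences; the score of matrix element (r, c) is
row_score(r) + column_score(c), and the running argmax after each sequence is
that sequence's decision.  The dynamic stopping rule selects an element as
soon as three consecutive sequence decisions agree (so the minimum is three
sequences); if the maximum number of sequences is reached without agreement
the block is reset — accumulators cleared — and stimulation starts over.

Calibration mimics the copy-spelling calibration run: six attended letters,
fifteen sequences each, evaluated with leave-one-letter-out cross-validation
at every sequence count; the session passes when accuracy exceeds 70% at any
number of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf

from .signal_sim import EpochSet


def build_features(epochs: EpochSet | np.ndarray, decimation: int = 12) -> np.ndarray:
    """Block-average every ``decimation`` samples per channel and concatenate.

    Returns an (n_epochs, n_channels * ceil(n_samples / decimation)) array.
    A trailing partial block is averaged over the samples it has.
    """
    data = epochs.epochs if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if data.ndim != 3:
        raise ValueError("expected (n_epochs, n_channels, n_samples)")
    n_ep, n_ch, n_samp = data.shape
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    if decimation > n_samp:
        raise ValueError(f"decimation {decimation} exceeds epoch length {n_samp}")
    n_blocks = int(np.ceil(n_samp / decimation))
    pad = n_blocks * decimation - n_samp
    if pad:
        # average the final partial block over its actual samples
        blocks = []
        for b in range(n_blocks):
            seg = data[:, :, b * decimation : min((b + 1) * decimation, n_samp)]
            blocks.append(seg.mean(axis=2))
        feat = np.stack(blocks, axis=2)
    else:
        feat = data.reshape(n_ep, n_ch, n_blocks, decimation).mean(axis=3)
    return feat.reshape(n_ep, n_ch * n_blocks)


@dataclass
class ErpClassifier:
    """Binary linear discriminant: score(x) = w . x + b (positive = target)."""

    weights: np.ndarray
    bias: float
    n_train: int = 0
    decimation: int = 12
    shrinkage: float = 0.0

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != self.weights.size:
            raise ValueError("feature length does not match classifier weights")
        return features @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.decision_scores(features) > 0


def train(features: np.ndarray, labels: np.ndarray, decimation: int = 12) -> ErpClassifier:
    """Fit a shrinkage-LDA discriminant for target vs non-target epochs.

    The pooled within-class covariance is shrunk toward a scaled identity with
    the Ledoit-Wolf intensity; a tiny ridge floor keeps the solve well-posed
    even for noiseless (zero-variance) training data.  Deterministic.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")

    mu_t = X[y].mean(axis=0)
    mu_n = X[~y].mean(axis=0)
    centered = np.concatenate([X[y] - mu_t, X[~y] - mu_n])
    d = X.shape[1]

    total_var = float((centered**2).sum()) / max(centered.shape[0], 1)
    if total_var < 1e-24:
        cov = np.eye(d)  # noiseless limit: whitening is a no-op
        lam = 1.0
    else:
        cov, lam = ledoit_wolf(centered, assume_centered=True)
        cov = cov + 1e-10 * (np.trace(cov) / d + 1.0) * np.eye(d)

    w = np.linalg.solve(cov, mu_t - mu_n)
    b = -float(w @ (mu_t + mu_n) / 2.0)
    return ErpClassifier(w, b, n_train=X.shape[0], decimation=decimation, shrinkage=float(lam))


@dataclass
class SequenceDecision:
    """Accumulated element scores after one flashing sequence of a block."""

    scores: np.ndarray  # (n_rows, n_cols), accumulated over the block so far
    argmax: tuple[int, int]
    sequence_index: int


def _argmax_row_major(scores: np.ndarray) -> tuple[int, int]:
    flat = int(np.argmax(scores))  # np.argmax returns the first (lowest) index on ties
    return flat // scores.shape[1], flat % scores.shape[1]


def score_elements(
    classifier: ErpClassifier,
    sequence_epochs: EpochSet,
    n_rows: int,
    n_cols: int,
    accumulated: SequenceDecision | None = None,
) -> SequenceDecision:
    """Score all matrix elements from one flashing sequence.

    The sequence must contain every row and column group exactly once.  The
    element score is row_score + column_score, added onto the accumulated
    scores of previous sequences in the same block; ties at the argmax break
    toward the lowest row-major index.
    """
    feats = build_features(sequence_epochs, classifier.decimation)
    scores = classifier.decision_scores(feats)
    row_scores = np.full(n_rows, np.nan)
    col_scores = np.full(n_cols, np.nan)
    for kind, gi, sc in zip(
        sequence_epochs.group_kinds, sequence_epochs.group_indices, scores
    ):
        vec = row_scores if kind == "row" else col_scores
        if not np.isnan(vec[gi]):
            raise ValueError(f"group {kind} {gi} flashed more than once in the sequence")
        vec[gi] = sc
    if np.isnan(row_scores).any() or np.isnan(col_scores).any():
        raise ValueError("sequence is missing at least one row/column group")

    element = row_scores[:, None] + col_scores[None, :]
    if accumulated is not None:
        element = element + accumulated.scores
    seq_idx = int(sequence_epochs.sequence_indices[0]) if len(sequence_epochs) else 0
    return SequenceDecision(element, _argmax_row_major(element), seq_idx)


#: dynamic_stop status values
PENDING, SELECT, RESET = "pending", "select", "reset"

AGREEMENT_RUN = 3  # consecutive identical sequence decisions required


def dynamic_stop(history: list[tuple[int, int]], max_sequences: int) -> str:
    """Dynamic stopping rule on a block's decision history.

    Returns ``'select'`` when the last three decisions agree, ``'reset'`` when
    ``max_sequences`` sequences elapsed without agreement, else ``'pending'``.
    """
    if max_sequences < AGREEMENT_RUN:
        raise ValueError(f"max_sequences must be >= {AGREEMENT_RUN}")
    if len(history) >= AGREEMENT_RUN and len(set(history[-AGREEMENT_RUN:])) == 1:
        return SELECT
    if len(history) >= max_sequences:
        return RESET
    return PENDING


@dataclass
class SelectionResult:
    """Outcome of one selection block (possibly spanning resets)."""

    selected: tuple[int, int] | None
    n_sequences_used: int  # total sequences across all attempts
    history: list[tuple[int, int]] = field(default_factory=list)
    reset_count: int = 0
    stopped_by: str = "agreement"  # 'agreement' | 'max-reset'


class SelectionController:
    """Feeds per-sequence epochs through scoring and the stopping rule.

    One controller instance handles one selection.  After a reset the score
    accumulator and decision history restart from scratch (no carry-over); at
    most ``max_resets`` resets are tolerated before the controller gives up
    with ``stopped_by='max-reset'`` and no selection.
    """

    def __init__(
        self,
        classifier: ErpClassifier,
        n_rows: int,
        n_cols: int,
        max_sequences: int = 15,
        max_resets: int = 3,
    ):
        if max_sequences < AGREEMENT_RUN:
            raise ValueError(f"max_sequences must be >= {AGREEMENT_RUN}")
        self.classifier = classifier
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.max_sequences = max_sequences
        self.max_resets = max_resets
        self.total_sequences = 0
        self.reset_count = 0
        self.history: list[tuple[int, int]] = []
        self.full_history: list[tuple[int, int]] = []
        self._accumulated: SequenceDecision | None = None
        self.result: SelectionResult | None = None

    def feed_sequence(self, sequence_epochs: EpochSet) -> SelectionResult | None:
        """Process one flashing sequence; returns the result once finished."""
        if self.result is not None:
            return self.result
        dec = score_elements(
            self.classifier, sequence_epochs, self.n_rows, self.n_cols, self._accumulated
        )
        self._accumulated = dec
        self.history.append(dec.argmax)
        self.full_history.append(dec.argmax)
        self.total_sequences += 1
        status = dynamic_stop(self.history, self.max_sequences)
        if status == SELECT:
            self.result = SelectionResult(
                dec.argmax, self.total_sequences, list(self.full_history),
                self.reset_count, "agreement",
            )
        elif status == RESET:
            self.reset_count += 1
            self.history = []
            self._accumulated = None
            if self.reset_count > self.max_resets:
                self.result = SelectionResult(
                    None, self.total_sequences, list(self.full_history),
                    self.reset_count, "max-reset",
                )
        return self.result

    @property
    def needs_restart(self) -> bool:
        """True right after a reset: a fresh stimulation block is required."""
        return self.result is None and not self.history and self.total_sequences > 0


@dataclass
class CalibrationReport:
    """Leave-one-letter-out accuracy as a function of sequence count."""

    accuracy: np.ndarray  # percent, index n-1 -> accuracy using first n sequences
    best_accuracy: float
    passed: bool  # True iff accuracy exceeds 70% at any sequence count
    criterion: float = 70.0

    def as_dict(self) -> dict:
        return {
            "accuracy_per_n_sequences": [round(float(a), 2) for a in self.accuracy],
            "best_accuracy": round(float(self.best_accuracy), 2),
            "passed": bool(self.passed),
            "criterion_percent": self.criterion,
        }


def _decode_block(
    clf: ErpClassifier, block: EpochSet, n_rows: int, n_cols: int, n_sequences: int
) -> tuple[int, int]:
    """Accumulated-score argmax using the first n sequences of a block."""
    acc: SequenceDecision | None = None
    seqs = sorted(set(block.sequence_indices.tolist()))[:n_sequences]
    for s in seqs:
        acc = score_elements(clf, block.sequence(s), n_rows, n_cols, acc)
    assert acc is not None
    return acc.argmax


def calibrate_loo(
    blocks: list[EpochSet],
    targets: list[tuple[int, int]],
    n_rows: int,
    n_cols: int,
    decimation: int = 12,
    max_sequences: int = 15,
    criterion: float = 70.0,
) -> CalibrationReport:
    """Leave-one-letter-out cross-validated calibration accuracy.

    For each held-out letter block, a classifier is trained on the remaining
    blocks' epochs and the held-out letter is decoded from its first n
    sequences, for n = 1..max_sequences.  Accuracy(n) is the percentage of
    letters decoded correctly; calibration passes when any accuracy exceeds
    the criterion (70%).
    """
    if len(blocks) < 2:
        raise ValueError("leave-one-out calibration needs at least two letter blocks")
    if len(blocks) != len(targets):
        raise ValueError("one attended target per block required")

    correct = np.zeros(max_sequences)
    for held in range(len(blocks)):
        rest = [b for i, b in enumerate(blocks) if i != held]
        train_set = rest[0]
        for b in rest[1:]:
            train_set = train_set.concat(b)
        clf = train(build_features(train_set, decimation), train_set.labels, decimation)
        for n in range(1, max_sequences + 1):
            if _decode_block(clf, blocks[held], n_rows, n_cols, n) == targets[held]:
                correct[n - 1] += 1

    acc = 100.0 * correct / len(blocks)
    best = float(acc.max())
    return CalibrationReport(acc, best, bool(best > criterion), criterion)
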