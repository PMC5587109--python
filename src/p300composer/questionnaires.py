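"""Scoring of the study's behavioral instruments.

* VAS — visual analogue scales: a mark on a 10 cm line maps linearly to 0-10.
* NASA-TLX — six workload factors (mental, physical, temporal demand,
  performance, effort, frustration) rated 0-100 on a 20-step scale; 15
  pairwise comparisons determine per-factor weights (win counts, summing to
  15); the weighted global score is sum(weight x rating) / 15 in 0-100, so a
  single factor can contribute at most 100 x 5/15 = 33.33.
* UEQ — 26 bipolar 7-point items mapped to six subscales (attractiveness,
  perspicuity, efficiency, dependability, stimulation, novelty) on -3..+3;
  use quality = mean(efficiency, perspicuity, dependability), design quality =
  mean(novelty, stimulation); values above +0.8 read as a positive impression,
  below -0.8 negative, otherwise neutral.
* paired pre/post comparison — paired-sample t-test with Cohen's d.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
from scipy import stats

TLX_FACTORS = ("mental", "physical", "temporal", "performance", "effort", "frustration")
TLX_N_PAIRS = 15  # C(6, 2)

UEQ_SUBSCALES = ("attractiveness", "perspicuity", "efficiency",
                 "dependability", "stimulation", "novelty")


class ResponseError(ValueError):
    """A questionnaire response violates the instrument's constraints."""


def score_vas(mark_cm: float) -> float:
    """Score of a mark on the 10 cm visual analogue line (linear, 0-10)."""
    if not 0.0 <= mark_cm <= 10.0:
        raise ResponseError(f"VAS mark {mark_cm} outside the 0-10 cm line")
    return float(mark_cm)


@dataclass(frozen=True)
class TlxResult:
    weights: dict[str, int]
    contributions: dict[str, float]  # weight x rating / 15 per factor
    global_score: float


def weights_from_pairs(winners: dict[tuple[str, str], str]) -> dict[str, int]:
    """Win counts from the 15 pairwise more-relevant choices."""
    expected = {tuple(sorted(p)) for p in combinations(TLX_FACTORS, 2)}
    got = {tuple(sorted(p)) for p in winners}
    if got != expected:
        raise ResponseError("pairwise choices must cover all 15 factor pairs exactly once")
    weights = {f: 0 for f in TLX_FACTORS}
    for pair, winner in winners.items():
        if winner not in pair:
            raise ResponseError(f"winner {winner!r} is not a member of pair {pair}")
        weights[winner] += 1
    return weights


def score_tlx(
    ratings: dict[str, float],
    winners: dict[tuple[str, str], str] | None = None,
    weights: dict[str, int] | None = None,
    lenient: bool = False,
) -> TlxResult:
    """Weighted NASA-TLX global workload score.

    Provide either the 15 pairwise ``winners`` or the ``weights`` directly.
    Ratings must lie on the 20-step grid (multiples of 5 in 0-100) unless
    ``lenient``.
    """
    if set(ratings) != set(TLX_FACTORS):
        raise ResponseError(f"ratings must cover exactly the factors {TLX_FACTORS}")
    for f, r in ratings.items():
        if not 0 <= r <= 100:
            raise ResponseError(f"rating for {f} outside 0-100")
        if not lenient and (r % 5 != 0):
            raise ResponseError(f"rating for {f} is off the 20-step (multiple-of-5) grid")

    if weights is None:
        if winners is None:
            raise ResponseError("either pairwise winners or weights are required")
        weights = weights_from_pairs(winners)
    else:
        weights = {f: int(weights.get(f, 0)) for f in TLX_FACTORS}
    if sum(weights.values()) != TLX_N_PAIRS:
        raise ResponseError("factor weights must sum to 15")
    if any(not 0 <= w <= 5 for w in weights.values()):
        raise ResponseError("each factor weight must lie in 0-5")

    contributions = {f: weights[f] * ratings[f] / TLX_N_PAIRS for f in TLX_FACTORS}
    return TlxResult(weights, contributions, sum(contributions.values()))


def _load_ueq_items() -> list[dict]:
    text = resources.files("p300composer.data").joinpath("ueq_items.json").read_text("utf-8")
    return json.loads(text)["items"]


@dataclass(frozen=True)
class UeqResult:
    subscales: dict[str, float]  # each in [-3, 3]
    attractiveness: float
    use_quality: float  # mean of efficiency, perspicuity, dependability
    design_quality: float  # mean of novelty, stimulation
    impressions: dict[str, str]  # value label: positive | neutral | negative


def impression_label(value: float, threshold: float = 0.8) -> str:
    """Positive above +0.8, negative below -0.8, neutral in between
    (boundary values inclusive of neutral)."""
    if value > threshold:
        return "positive"
    if value < -threshold:
        return "negative"
    return "neutral"


def score_ueq(responses: list[int] | np.ndarray) -> UeqResult:
    """Score a complete 26-item UEQ response (values 1..7, item order as in
    the published instrument). No imputation: missing items are an error."""
    items = _load_ueq_items()
    resp = np.asarray(responses, dtype=float)
    if resp.shape != (len(items),):
        raise ResponseError(f"expected {len(items)} item responses, got {resp.shape}")
    if np.any((resp < 1) | (resp > 7)) or np.any(resp != np.round(resp)):
        raise ResponseError("item responses must be integers in 1..7")

    values: dict[str, list[float]] = {s: [] for s in UEQ_SUBSCALES}
    for item, raw in zip(items, resp):
        v = raw - 4.0 if item["positive_pole"] == "right" else 4.0 - raw
        values[item["subscale"]].append(v)
    subscales = {s: float(np.mean(v)) for s, v in values.items()}

    use_q = float(np.mean([subscales["efficiency"], subscales["perspicuity"],
                           subscales["dependability"]]))
    design_q = float(np.mean([subscales["novelty"], subscales["stimulation"]]))
    scored = dict(subscales)
    scored["use_quality"] = use_q
    scored["design_quality"] = design_q
    return UeqResult(
        subscales,
        subscales["attractiveness"],
        use_q,
        design_q,
        {name: impression_label(val) for name, val in scored.items()},
    )


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    degenerate: bool = False  # zero variance of the paired differences


def compare_pre_post(pre, post) -> PairedTestResult:
    """Paired-sample t-test with Cohen's d = mean(diff) / sd(diff)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d samples")
    n = pre.size
    if n < 2:
        raise ValueError("paired comparison needs n >= 2")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return PairedTestResult(0.0, n - 1, 1.0, 0.0)
        t = np.inf if diff.mean() > 0 else -np.inf
        return PairedTestResult(float(t), n - 1, 0.0, float(np.sign(diff.mean()) * np.inf),
                                degenerate=True)
    res = stats.ttest_rel(post, pre)
    d = float(diff.mean() / sd)
    return PairedTestResult(float(res.statistic), n - 1, float(res.pvalue), d)
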