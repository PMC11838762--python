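"""CASP16-style evaluation of stoichiometry predictions.

A prediction is correct only on exact match with the true stoichiometry
— subsets, supersets and scalar multiples (A1B1 for A2B2) all count as
wrong, however structurally similar the corresponding models may be.
The report therefore carries, alongside the exact-match accuracies, a
compatibility annotation for every miss, so near-misses remain visible
without inflating the headline numbers.

Accuracies are stratified the way assembly benchmarks report them:
per-method on all targets and on only the targets the method was
applied to (a method unavailable for a target counts as incorrect in
the all-targets denominator); by difficulty (easy < 60% of community
predictors failing, hard >= 60%); and by homo- vs hetero-multimer.
Every aggregate is reported as numerator/denominator with full internal
precision; percent display rounds half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .stoichiometry import CompatibilityRelation, Stoichiometry, compare

__all__ = [
    "TargetRecord",
    "Aggregate",
    "EvaluationReport",
    "DIFFICULTY_SPLIT",
    "is_correct",
    "classify_difficulty",
    "evaluate",
    "annotate_compatibility",
]

#: Difficulty split: below this percentage of failing community
#: predictors a target is "easy".
DIFFICULTY_SPLIT = 60.0


@dataclass
class TargetRecord:
    """One evaluation target: truth, per-method top-1 calls, outcome flags.

    ``None`` in a per-method slot means the method was not applied
    (N/A).  ``top3_correct`` may be given directly (benchmark tables
    publish only the flag) or derived from ``final_top3`` when the full
    list is available.  ``truth_in_candidates`` feeds the candidate-list
    sensitivity aggregate.
    """

    target_id: str
    true_stoichiometry: Stoichiometry
    difficulty: float
    af_max: Stoichiometry | None = None
    af_avg: Stoichiometry | None = None
    tb: Stoichiometry | None = None
    final_top1: Stoichiometry | None = None
    final_top3: list[Stoichiometry] | None = None
    top3_correct: bool | None = None
    truth_in_candidates: bool | None = None
    decision_choice: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.difficulty <= 100.0):
            raise ValueError(
                f"{self.target_id}: difficulty must be in [0, 100], got {self.difficulty}"
            )

    @property
    def is_homomer(self) -> bool:
        return self.true_stoichiometry.is_homomer

    def top1_correct(self) -> bool:
        return self.final_top1 is not None and is_correct(self.final_top1, self.true_stoichiometry)

    def top3_hit(self) -> bool:
        if self.top3_correct is not None:
            return self.top3_correct
        if self.final_top3 is not None:
            return any(is_correct(p, self.true_stoichiometry) for p in self.final_top3)
        return self.top1_correct()


@dataclass
class Aggregate:
    """One accuracy line: numerator, denominator, derived percent."""

    metric: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError(f"{self.metric}: numerator exceeds denominator")

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator if self.denominator else float("nan")

    def display(self, decimals: int = 1) -> str:
        q = Decimal(1).scaleb(-decimals)
        pct = Decimal(self.percent).quantize(q, rounding=ROUND_HALF_UP)
        return f"{pct}% ({self.numerator}/{self.denominator})"


@dataclass
class EvaluationReport:
    """Per-target outcomes plus stratified accuracy aggregates."""

    records: list[TargetRecord]
    aggregates: dict[str, Aggregate]
    compatibility: dict[str, CompatibilityRelation] = field(default_factory=dict)

    def __getitem__(self, metric: str) -> Aggregate:
        return self.aggregates[metric]

    def to_rows(self) -> list[dict]:
        return [
            {"metric": name, "numerator": agg.numerator,
             "denominator": agg.denominator, "percent": agg.percent}
            for name, agg in self.aggregates.items()
        ]


def is_correct(predicted: Stoichiometry, truth: Stoichiometry) -> bool:
    """Exact-match correctness: identical label multiset, nothing less."""
    return compare(predicted, truth).kind == "identical"


def classify_difficulty(d: float) -> str:
    """"easy" below the 60% community-failure split, "hard" at or above."""
    if not (0.0 <= d <= 100.0):
        raise ValueError(f"difficulty must be in [0, 100], got {d}")
    return "easy" if d < DIFFICULTY_SPLIT else "hard"


def _acc(metric: str, records: Sequence[TargetRecord], hit) -> Aggregate:
    return Aggregate(metric, sum(1 for r in records if hit(r)), len(records))


def evaluate(records: Iterable[TargetRecord]) -> EvaluationReport:
    """Compute the full stratified accuracy report.

    Per-method "all targets" accuracies count N/A targets as incorrect;
    "applied" accuracies restrict the denominator to targets where the
    method produced a prediction.  Sensitivity is the fraction of
    targets whose candidate list contained the truth (falling back to
    the top-3 outcome where the explicit flag is absent).
    """
    records = list(records)
    if not records:
        raise ValueError("no target records to evaluate")

    easy = [r for r in records if classify_difficulty(r.difficulty) == "easy"]
    hard = [r for r in records if classify_difficulty(r.difficulty) == "hard"]
    homo = [r for r in records if r.is_homomer]
    hetero = [r for r in records if not r.is_homomer]

    aggs: dict[str, Aggregate] = {}
    aggs["overall_top1"] = _acc("overall_top1", records, TargetRecord.top1_correct)
    aggs["overall_top3"] = _acc("overall_top3", records, TargetRecord.top3_hit)

    for name, getter in (("af_max", lambda r: r.af_max),
                         ("af_avg", lambda r: r.af_avg),
                         ("tb", lambda r: r.tb)):
        applied = [r for r in records if getter(r) is not None]
        correct = sum(1 for r in applied if is_correct(getter(r), r.true_stoichiometry))
        aggs[f"{name}_top1_all"] = Aggregate(f"{name}_top1_all", correct, len(records))
        aggs[f"{name}_top1_applied"] = Aggregate(f"{name}_top1_applied", correct, len(applied)) \
            if applied else Aggregate(f"{name}_top1_applied", 0, 0)

    for name, subset in (("easy", easy), ("hard", hard), ("homo", homo), ("hetero", hetero)):
        if subset:
            aggs[f"{name}_top1"] = _acc(f"{name}_top1", subset, TargetRecord.top1_correct)
            aggs[f"{name}_top3"] = _acc(f"{name}_top3", subset, TargetRecord.top3_hit)

    aggs["sensitivity"] = _acc(
        "sensitivity", records,
        lambda r: r.truth_in_candidates if r.truth_in_candidates is not None else r.top3_hit(),
    )

    return EvaluationReport(records, aggs, annotate_compatibility(records))


def annotate_compatibility(records: Iterable[TargetRecord]) -> dict[str, CompatibilityRelation]:
    """Relation of each final top-1 to the truth (identical when correct).

    Purely descriptive: a scalar-multiple or subset miss stays a miss in
    every accuracy aggregate.
    """
    out: dict[str, CompatibilityRelation] = {}
    for rec in records:
        if rec.final_top1 is not None:
            out[rec.target_id] = compare(rec.final_top1, rec.true_stoichiometry)
    return out
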