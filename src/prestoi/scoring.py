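"""AlphaFold3 ranking-score ingestion, aggregation and candidate ranking.

AlphaFold3 emits a ranking score for every structural model it builds —
a weighted sum of predicted global quality (pTM), interface quality
(ipTM), a disorder reward and a clash penalty.  With 25–50 models per
stoichiometry candidate, each candidate is summarised by either the
maximum (AF-max) or the arithmetic mean (AF-avg) of its models' ranking
scores, and candidates are ranked by the summary.

Two input dialects are read: a flat TSV
(``target_id  candidate  model_id  ranking_score [ptm iptm disorder has_clash]``)
and AlphaFold3 ``summary_confidences`` JSON files laid out as
``<root>/<target_id>/<candidate>/*.json`` — the candidate string is taken
from the model file's parent directory and the target from the directory
above it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .stoichiometry import Stoichiometry, format_stoichiometry, parse_stoichiometry

__all__ = [
    "ModelScoreRecord",
    "CandidateRanking",
    "DEFAULT_SCORE_WEIGHTS",
    "MIN_MODELS_FOR_AVG",
    "read_model_scores",
    "compose_ranking_score",
    "aggregate",
    "rank_candidates",
    "top_k",
]

#: (w_iptm, w_ptm, w_disorder, w_clash) — AlphaFold3's published
#: recomposition: 0.8*ipTM + 0.2*pTM + 0.5*disorder - 100*clash.
DEFAULT_SCORE_WEIGHTS = (0.8, 0.2, 0.5, 100.0)

#: Below this many models per candidate, AF-avg is flagged unreliable.
MIN_MODELS_FOR_AVG = 5


@dataclass(frozen=True)
class ModelScoreRecord:
    """One AlphaFold3 model's confidence for one stoichiometry candidate."""

    target_id: str
    candidate: Stoichiometry
    model_id: str
    ranking_score: float | None = None
    ptm: float | None = None
    iptm: float | None = None
    disorder: float | None = None
    has_clash: int | None = None

    def __post_init__(self) -> None:
        if self.ranking_score is None and not self.has_components:
            raise ValueError(
                f"model {self.model_id} of {self.target_id}/{self.candidate}: "
                "needs a ranking score or all four components"
            )
        for name in ("ptm", "iptm"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")

    @property
    def has_components(self) -> bool:
        return None not in (self.ptm, self.iptm, self.disorder, self.has_clash)

    def score(self, weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS) -> float:
        """Supplied ranking score, else recomposed from components."""
        if self.ranking_score is not None:
            return self.ranking_score
        return compose_ranking_score(
            {"iptm": self.iptm, "ptm": self.ptm,
             "disorder": self.disorder, "has_clash": self.has_clash},
            weights,
        )


@dataclass
class CandidateRanking:
    """Ranked candidates for one target under one aggregation mode."""

    target_id: str
    mode: str  # "max" | "avg"
    entries: list[tuple[Stoichiometry, float, int]]  # (candidate, score, n_models)
    tie_break_trace: list[str] = field(default_factory=list)
    #: candidates excluded upstream (e.g. size cap) — never scored, never 0
    untested: list[Stoichiometry] = field(default_factory=list)
    #: candidates whose AF-avg rests on fewer models than the
    #: reliability floor (the aggregate is still computed)
    low_model_count: list[Stoichiometry] = field(default_factory=list)

    @property
    def candidates(self) -> list[Stoichiometry]:
        return [cand for cand, _, _ in self.entries]

    def top1(self) -> Stoichiometry:
        return self.entries[0][0]


def compose_ranking_score(components: Mapping[str, float],
                          weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS) -> float:
    """Weighted recomposition of the AlphaFold3 ranking score.

    ``w_iptm*ipTM + w_ptm*pTM + w_dis*disorder - w_clash*clash``; the
    clash penalty dominates by construction.
    """
    required = ("iptm", "ptm", "disorder", "has_clash")
    missing = [k for k in required if components.get(k) is None]
    if missing:
        raise ValueError(f"cannot compose ranking score, missing components: {missing}")
    w_iptm, w_ptm, w_dis, w_clash = weights
    return (w_iptm * components["iptm"] + w_ptm * components["ptm"]
            + w_dis * components["disorder"] - w_clash * components["has_clash"])


def _record_from_json(path: Path) -> ModelScoreRecord:
    with open(path) as fh:
        payload = json.load(fh)
    candidate = parse_stoichiometry(path.parent.name.upper())
    target_id = path.parent.parent.name
    return ModelScoreRecord(
        target_id=target_id,
        candidate=candidate,
        model_id=path.stem,
        ranking_score=payload.get("ranking_score"),
        ptm=payload.get("ptm"),
        iptm=payload.get("iptm"),
        disorder=payload.get("fraction_disordered", payload.get("disorder")),
        has_clash=int(payload["has_clash"]) if "has_clash" in payload else None,
    )


def read_model_scores(path: str | Path, dialect: str = "tsv") -> list[ModelScoreRecord]:
    """Read per-model score records.

    ``tsv``: one file, columns ``target_id candidate model_id
    ranking_score`` plus optional component columns.  ``af3_summary_json``:
    ``path`` is a root directory scanned for
    ``<target>/<candidate>/*.json`` summary-confidence files.
    """
    path = Path(path)
    if dialect == "af3_summary_json":
        records = [
            _record_from_json(p)
            for p in sorted(path.glob("*/*/*.json"))
        ]
        if not records:
            raise FileNotFoundError(f"no summary-confidence JSON under {path}")
        return records
    if dialect != "tsv":
        raise ValueError(f"unknown score dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "model_id": str})
    required = {"target_id", "candidate", "model_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: score TSV needs columns {sorted(required)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(ModelScoreRecord(
                target_id=row.target_id,
                candidate=parse_stoichiometry(row.candidate),
                model_id=row.model_id,
                ranking_score=_opt(row, "ranking_score"),
                ptm=_opt(row, "ptm"),
                iptm=_opt(row, "iptm"),
                disorder=_opt(row, "disorder"),
                has_clash=(int(v) if (v := _opt(row, "has_clash")) is not None else None),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def _opt(row, name: str):
    val = getattr(row, name, None)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return None
    return val


def aggregate(records: Iterable[ModelScoreRecord], mode: str,
              weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS,
              ) -> dict[Stoichiometry, tuple[float, int]]:
    """Per-candidate AF-max or AF-avg: ``{candidate: (score, n_models)}``.

    Candidates simply absent from ``records`` are absent from the result
    (not-scored), never given a zero.
    """
    if mode not in ("max", "avg"):
        raise ValueError(f"aggregation mode must be 'max' or 'avg', got {mode!r}")
    scores: dict[Stoichiometry, list[float]] = {}
    for rec in records:
        scores.setdefault(rec.candidate, []).append(rec.score(weights))
    # fsum keeps the mean invariant under record permutation
    return {
        cand: ((max(vals) if mode == "max" else math.fsum(sorted(vals)) / len(vals)),
               len(vals))
        for cand, vals in scores.items()
    }


def rank_candidates(aggregates: Mapping[Stoichiometry, tuple[float, int]],
                    target_id: str = "", mode: str = "max",
                    untested: Sequence[Stoichiometry] = (),
                    min_models: int = MIN_MODELS_FOR_AVG) -> CandidateRanking:
    """Rank by descending aggregate score.

    Exact score ties go to the candidate with fewer total subunit copies
    (parsimony), then canonical string order; every tie-break is traced.
    In ``avg`` mode, candidates resting on fewer than ``min_models``
    models are flagged as low-sample (but still ranked).
    """
    if not aggregates:
        raise ValueError(f"no scored candidates for target {target_id!r}")
    ordered = sorted(
        aggregates.items(),
        key=lambda kv: (-kv[1][0], kv[0].total_copies, format_stoichiometry(kv[0])),
    )
    trace: list[str] = []
    for (a, (sa, _)), (b, (sb, _)) in zip(ordered, ordered[1:]):
        if sa == sb:
            trace.append(
                f"tie at {sa:.6g}: {format_stoichiometry(a)} before "
                f"{format_stoichiometry(b)} (parsimony/canonical)"
            )
    entries = [(cand, score, n) for cand, (score, n) in ordered]
    low = ([cand for cand, (_, n) in ordered if n < min_models]
           if mode == "avg" else [])
    return CandidateRanking(target_id, mode, entries, trace, list(untested), low)


def top_k(ranking: CandidateRanking, k: int) -> list[Stoichiometry]:
    """First ``min(k, available)`` candidates of the ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ranking.candidates[:k]
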