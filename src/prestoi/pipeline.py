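"""End-to-end prediction for one target and batch evaluation helpers.

Glues the pipeline stages together in the order the method runs:
candidate generation (template-derived ranges or homomer enumeration,
size filter), AlphaFold3 score aggregation and ranking in both modes,
template-based prediction, and integration into the final top-k list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .candidates import (
    CandidateSet,
    enumerate_from_ranges,
    enumerate_homomer,
    filter_by_size,
    order_candidates,
)
from .config import RunConfig
from .evaluation import EvaluationReport, TargetRecord, evaluate
from .integration import FinalPrediction, MethodPrediction, integrate
from .scoring import CandidateRanking, ModelScoreRecord, aggregate, rank_candidates
from .simulate import SyntheticDataset
from .stoichiometry import Stoichiometry
from .templates import (
    TBPrediction,
    TemplateHit,
    derive_copy_ranges,
    partial_template_completion,
    tb_predict,
)

__all__ = ["TargetPrediction", "generate_candidates", "predict_target",
           "evaluate_synthetic", "read_target_lengths"]


def read_target_lengths(path) -> dict[str, dict[str, int]]:
    """Read subunit lengths per target.

    Accepts the targets TSV (``target_id  subunit  length``) or a FASTA
    file with record ids ``<target_id>_<subunit>`` (sequence lengths are
    taken from the sequences).
    """
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".faa"):
        from Bio import SeqIO

        out: dict[str, dict[str, int]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            target_id, _, subunit = rec.id.rpartition("_")
            if not target_id or len(subunit) != 1:
                raise ValueError(f"FASTA id {rec.id!r} is not <target>_<subunit>")
            out.setdefault(target_id, {})[subunit] = len(rec.seq)
        return out
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "subunit": str})
    required = {"target_id", "subunit", "length"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: targets table needs columns {sorted(required)}")
    out = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.target_id, {})[row.subunit] = int(row.length)
    return out


@dataclass
class TargetPrediction:
    """Everything one target's run produced, stage by stage."""

    target_id: str
    candidate_set: CandidateSet
    af_max: MethodPrediction
    af_avg: MethodPrediction
    tb: TBPrediction
    final: FinalPrediction
    rankings: dict[str, CandidateRanking] = field(default_factory=dict)


def _narrow_homomer_range(base: tuple[int, int],
                          derived: tuple[int, int]) -> tuple[int, int]:
    """Template evidence may narrow the homomer span, never widen it."""
    lo = max(base[0], derived[0])
    hi = min(base[1], derived[1])
    return (lo, hi) if lo <= hi else base


def generate_candidates(target_id: str,
                        lengths: Mapping[str, int],
                        hits: Sequence[TemplateHit],
                        config: RunConfig | None = None) -> CandidateSet:
    """Size-filtered candidate shortlist for one target.

    Homo-multimers enumerate copy counts over the homomer span, narrowed
    (never widened) by template evidence; hetero-multimers take the
    Cartesian product of template-derived per-subunit ranges plus any
    completions of a partially-covering complex template.
    """
    config = config or RunConfig()
    subunits = sorted(lengths)
    if len(subunits) == 1:
        base = config.homomer_range
        if hits:
            derived = derive_copy_ranges(hits, subunits, config.e_threshold,
                                         config.relax_schedule, base)[subunits[0]]
            base = _narrow_homomer_range(config.homomer_range, derived)
        pool = enumerate_homomer(*base, label=subunits[0])
    else:
        ranges = derive_copy_ranges(hits, subunits, config.e_threshold,
                                    config.relax_schedule, config.heteromer_range)
        pool = enumerate_from_ranges(ranges)
        # candidates completing a partially-covering complex template
        _, completions = partial_template_completion(hits, subunits, config.e_threshold,
                                                     config.heteromer_range)
        pool.extend(c for c in completions if c not in pool)
    return filter_by_size(order_candidates(pool), lengths,
                          config.residue_cap, target_id)


def predict_target(target_id: str,
                   lengths: Mapping[str, int],
                   hits: Sequence[TemplateHit],
                   score_records: Sequence[ModelScoreRecord],
                   config: RunConfig | None = None,
                   override: str | None = None) -> TargetPrediction:
    """Run the full prediction for one target.

    ``score_records`` are the pre-computed AlphaFold3 model scores for
    whatever candidates were modelled; candidates excluded by the size
    cap are reported as untested rather than scored."""
    config = config or RunConfig()
    subunits = sorted(lengths)
    candidate_set = generate_candidates(target_id, lengths, hits, config)

    kept = set(candidate_set.kept)
    usable = [r for r in score_records if r.candidate in kept]
    untested = [cand for cand, _ in candidate_set.excluded]

    rankings: dict[str, CandidateRanking] = {}
    af_preds: dict[str, MethodPrediction] = {}
    for mode, name in (("max", "AF-max"), ("avg", "AF-avg")):
        if usable:
            agg = aggregate(usable, mode)
            ranking = rank_candidates(agg, target_id, mode, untested)
            rankings[name] = ranking
            af_preds[name] = MethodPrediction(name, True, ranking.candidates)
        else:
            af_preds[name] = MethodPrediction.not_applicable(name)

    tb = tb_predict(hits, subunits, config.e_threshold)
    tb_pred = (MethodPrediction("TB", True, [tb.stoichiometry], grade=tb.grade)
               if tb.applicable else MethodPrediction.not_applicable("TB"))

    final = integrate(af_preds["AF-max"], af_preds["AF-avg"], tb_pred,
                      config.policy, target_id, override)
    return TargetPrediction(target_id, candidate_set, af_preds["AF-max"],
                            af_preds["AF-avg"], tb, final, rankings)


def evaluate_synthetic(dataset: SyntheticDataset,
                       config: RunConfig | None = None) -> tuple[EvaluationReport,
                                                                 list[TargetPrediction]]:
    """Run the pipeline over a synthetic dataset and score it against truth."""
    config = config or RunConfig()
    records: list[TargetRecord] = []
    predictions: list[TargetPrediction] = []
    for t in dataset.targets:
        pred = predict_target(t.target_id, t.lengths, t.hits,
                              dataset.scores_for(t.target_id), config)
        predictions.append(pred)
        records.append(TargetRecord(
            target_id=t.target_id,
            true_stoichiometry=t.truth,
            difficulty=50.0,
            af_max=pred.af_max.top1,
            af_avg=pred.af_avg.top1,
            tb=pred.tb.stoichiometry,
            final_top1=pred.final.top1,
            final_top3=pred.final.stoichiometries,
            truth_in_candidates=t.truth in pred.candidate_set.kept,
        ))
    return evaluate(records), predictions
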