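"""Template-based copy-range derivation and stoichiometry prediction.

Homologous complexes of known structure in the PDB carry stoichiometric
evidence: if a subunit matches a template chain that occurs twice in the
template complex, the subunit plausibly occurs twice in the target.
This module consumes a pre-computed hit table (one row per
subunit-template match, with an E-value and the matched chain's copy
count in the template) — it does not run any search engine.

Two mechanical prediction rules are supported, graded by confidence:

* ``high`` — a single complex template covers every subunit; its
  per-subunit copy counts are used directly.
* ``medium`` — no covering template, but every subunit has a strict
  modal copy count over its own hits (distinct templates); the product
  of the modes is predicted.  This is deliberately weaker: hetero-dimer
  subunits that each match only homodimer templates yield A2B2 at
  medium grade even when the complex is a hetero-dimer.

A third, also ``medium``, rule completes a partial covering template
(one that misses some subunits) with the lower bound of a completion
range — the uncovered subunits' copies are guesses, not evidence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .candidates import CopyRanges, DEFAULT_HETEROMER_RANGE
from .stoichiometry import Stoichiometry

__all__ = [
    "TemplateHit",
    "TBPrediction",
    "DEFAULT_E_THRESHOLD",
    "DEFAULT_RELAX_SCHEDULE",
    "derive_copy_ranges",
    "common_complex_template",
    "per_subunit_consensus",
    "partial_template_completion",
    "tb_predict",
    "read_hit_table",
]

#: E-value below which a template hit counts as significant.
DEFAULT_E_THRESHOLD = 1e-3
#: Progressive relaxation for subunits with no significant hit.
DEFAULT_RELAX_SCHEDULE = (1e-2, 1e-1, 1.0)

GRADE_ORDER = {"none": 0, "medium": 1, "high": 2}


@dataclass(frozen=True)
class TemplateHit:
    """One subunit-to-template match with stoichiometric evidence."""

    subunit: str
    template_pdb: str
    evalue: float
    copies_in_template: int
    template_stoichiometry: Stoichiometry | None = None

    def __post_init__(self) -> None:
        if self.copies_in_template < 1:
            raise ValueError(f"copies_in_template must be >= 1, got {self.copies_in_template}")
        if self.evalue < 0:
            raise ValueError(f"E-value must be non-negative, got {self.evalue}")


@dataclass
class TBPrediction:
    """Template-based stoichiometry prediction with a confidence grade."""

    stoichiometry: Stoichiometry | None
    grade: str  # high | medium | none
    supporting_templates: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.grade not in GRADE_ORDER:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.grade == "none" and self.stoichiometry is not None:
            raise ValueError("grade 'none' carries no stoichiometry")

    @property
    def applicable(self) -> bool:
        return self.grade != "none"


def _check_subunits(hits: Iterable[TemplateHit], subunits: Iterable[str]) -> None:
    known = set(subunits)
    for hit in hits:
        if hit.subunit not in known:
            raise ValueError(f"hit references unknown subunit {hit.subunit!r}")


def derive_copy_ranges(hits: Sequence[TemplateHit],
                       subunits: Iterable[str],
                       e_threshold: float = DEFAULT_E_THRESHOLD,
                       relax_schedule: Sequence[float] = DEFAULT_RELAX_SCHEDULE,
                       default_range: tuple[int, int] = DEFAULT_HETEROMER_RANGE) -> CopyRanges:
    """Per-subunit (min, max) copy ranges from qualifying hits.

    A subunit with no hit at the base threshold walks the relaxation
    schedule; with no hit anywhere it falls back to ``default_range``, so
    a candidate list can always be generated.
    """
    subunits = sorted(set(subunits))
    _check_subunits(hits, subunits)
    by_subunit: dict[str, list[TemplateHit]] = defaultdict(list)
    for hit in hits:
        by_subunit[hit.subunit].append(hit)

    ranges: dict[str, tuple[int, int]] = {}
    for lab in subunits:
        copies: list[int] = []
        for thr in (e_threshold, *relax_schedule):
            copies = [h.copies_in_template for h in by_subunit[lab] if h.evalue <= thr]
            if copies:
                break
        ranges[lab] = (min(copies), max(copies)) if copies else default_range
    return ranges


def _qualifying_by_template(hits: Sequence[TemplateHit],
                            e_threshold: float) -> dict[str, dict[str, TemplateHit]]:
    """pdb -> subunit -> best qualifying hit; errors on conflicting copies."""
    grouped: dict[str, dict[str, TemplateHit]] = defaultdict(dict)
    for hit in hits:
        if hit.evalue > e_threshold:
            continue
        prev = grouped[hit.template_pdb].get(hit.subunit)
        if prev is not None:
            if prev.copies_in_template != hit.copies_in_template:
                raise ValueError(
                    f"inconsistent copy counts for subunit {hit.subunit} in template "
                    f"{hit.template_pdb}: {prev.copies_in_template} vs {hit.copies_in_template}"
                )
            if hit.evalue < prev.evalue:
                grouped[hit.template_pdb][hit.subunit] = hit
        else:
            grouped[hit.template_pdb][hit.subunit] = hit
    return grouped


def common_complex_template(hits: Sequence[TemplateHit],
                            subunits: Iterable[str],
                            e_threshold: float = DEFAULT_E_THRESHOLD) -> TBPrediction:
    """Predict from a single complex template covering every subunit.

    Among multiple covering templates, the one whose worst-covered
    subunit has the lowest E-value wins.  Grade ``high`` on success,
    ``none`` otherwise.
    """
    subunits = sorted(set(subunits))
    _check_subunits(hits, subunits)
    grouped = _qualifying_by_template(hits, e_threshold)
    covering = {
        pdb: per_sub for pdb, per_sub in grouped.items()
        if set(per_sub) >= set(subunits)
    }
    if not covering:
        return TBPrediction(None, "none")
    best_pdb = min(
        covering,
        key=lambda pdb: (max(covering[pdb][lab].evalue for lab in subunits), pdb),
    )
    per_sub = covering[best_pdb]
    stoich = Stoichiometry(tuple((lab, per_sub[lab].copies_in_template) for lab in subunits))
    return TBPrediction(stoich, "high", (best_pdb,))


def per_subunit_consensus(hits: Sequence[TemplateHit],
                          subunits: Iterable[str],
                          e_threshold: float = DEFAULT_E_THRESHOLD) -> TBPrediction:
    """Predict from independent per-subunit copy-count consensus.

    Each subunit needs a strict modal copy count over its qualifying
    hits (ties break the consensus); the prediction is the product of
    the modes at grade ``medium``.
    """
    subunits = sorted(set(subunits))
    _check_subunits(hits, subunits)
    items: list[tuple[str, int]] = []
    support: list[str] = []
    for lab in subunits:
        qualifying = [h for h in hits if h.subunit == lab and h.evalue <= e_threshold]
        if not qualifying:
            return TBPrediction(None, "none")
        tally = Counter(h.copies_in_template for h in qualifying)
        (mode, top), *rest = tally.most_common()
        if rest and rest[0][1] == top:
            return TBPrediction(None, "none")  # tied mode: no consensus
        items.append((lab, mode))
        support.extend(sorted({h.template_pdb for h in qualifying
                               if h.copies_in_template == mode}))
    return TBPrediction(Stoichiometry(tuple(items)), "medium", tuple(dict.fromkeys(support)))


def partial_template_completion(hits: Sequence[TemplateHit],
                                subunits: Iterable[str],
                                e_threshold: float = DEFAULT_E_THRESHOLD,
                                completion_range: tuple[int, int] = DEFAULT_HETEROMER_RANGE,
                                ) -> tuple[TBPrediction, list[Stoichiometry]]:
    """Complete the best partially-covering complex template.

    Picks the qualifying template covering the most subunits (but not
    all), assigns covered subunits its copy counts, and enumerates the
    completion range for uncovered subunits.  The returned prediction
    uses the range's lower bound at grade ``medium``; the full list of
    completions is also returned so candidate generation can test them.
    """
    import itertools

    subunits = sorted(set(subunits))
    _check_subunits(hits, subunits)
    grouped = _qualifying_by_template(hits, e_threshold)
    partial = {
        pdb: per_sub for pdb, per_sub in grouped.items()
        if set(per_sub) < set(subunits)
    }
    if not partial:
        return TBPrediction(None, "none"), []
    best_pdb = max(
        partial,
        key=lambda pdb: (len(partial[pdb]),
                         -max(h.evalue for h in partial[pdb].values()),
                         pdb),
    )
    per_sub = partial[best_pdb]
    uncovered = [lab for lab in subunits if lab not in per_sub]
    lo, hi = completion_range
    completions: list[Stoichiometry] = []
    for combo in itertools.product(range(lo, hi + 1), repeat=len(uncovered)):
        filler = dict(zip(uncovered, combo))
        completions.append(Stoichiometry(tuple(
            (lab, per_sub[lab].copies_in_template if lab in per_sub else filler[lab])
            for lab in subunits
        )))
    prediction = TBPrediction(completions[0], "medium", (best_pdb,))
    return prediction, completions


def read_hit_table(path) -> dict[str, list[TemplateHit]]:
    """Read a hit-table TSV (columns: target_id, subunit, template_pdb,
    evalue, copies_in_template[, template_stoichiometry]) grouped by target."""
    import pandas as pd

    from .stoichiometry import parse_stoichiometry

    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "subunit": str,
                                            "template_pdb": str})
    required = {"target_id", "subunit", "template_pdb", "evalue", "copies_in_template"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: hit table needs columns {sorted(required)}")
    out: dict[str, list[TemplateHit]] = defaultdict(list)
    for row in df.itertuples(index=False):
        stoich = getattr(row, "template_stoichiometry", None)
        stoich = (parse_stoichiometry(stoich)
                  if isinstance(stoich, str) and stoich not in ("", "NA") else None)
        out[row.target_id].append(TemplateHit(
            subunit=row.subunit,
            template_pdb=row.template_pdb,
            evalue=float(row.evalue),
            copies_in_template=int(row.copies_in_template),
            template_stoichiometry=stoich,
        ))
    return dict(out)


def tb_predict(hits: Sequence[TemplateHit],
               subunits: Iterable[str],
               e_threshold: float = DEFAULT_E_THRESHOLD,
               allow_partial: bool = True) -> TBPrediction:
    """Template-based prediction: covering template, else consensus,
    else (optionally) partial-template completion, else not applicable."""
    full = common_complex_template(hits, subunits, e_threshold)
    if full.grade == "high":
        return full
    consensus = per_subunit_consensus(hits, subunits, e_threshold)
    if consensus.applicable:
        return consensus
    if allow_partial:
        partial, _ = partial_template_completion(hits, subunits, e_threshold)
        if partial.applicable:
            return partial
    return TBPrediction(None, "none")
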