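"""Stoichiometry candidate generation.

Building an AlphaFold3 model for a candidate stoichiometry is expensive,
so the shortlist of candidates must stay small.  For hetero-multimers
the list is the Cartesian product of per-subunit copy ranges (derived
from template evidence, or a (1, 2) fallback); for homo-multimers a
plain enumeration of copy counts, by default dimer through 9-mer — the
largest assembly AlphaFold3 typically handles.  Candidates whose total
residue count exceeds the scoring budget (5000 residues on the
AlphaFold3 web server) are excluded but kept visible: an excluded true
stoichiometry is a diagnosable failure, not a silent one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .stoichiometry import Stoichiometry, SubunitLengths, format_stoichiometry, total_residues

__all__ = [
    "CopyRanges",
    "CandidateSet",
    "DEFAULT_RESIDUE_CAP",
    "DEFAULT_HOMOMER_RANGE",
    "DEFAULT_HETEROMER_RANGE",
    "MAX_CANDIDATES",
    "enumerate_from_ranges",
    "enumerate_homomer",
    "filter_by_size",
    "order_candidates",
]

CopyRanges = Mapping[str, tuple[int, int]]

#: AlphaFold3 web-server assembly size limit, in residues.
DEFAULT_RESIDUE_CAP = 5000
#: Homo-multimer enumeration span: dimer up to 9-mer.
DEFAULT_HOMOMER_RANGE = (2, 9)
#: Per-subunit fallback range when no template evidence exists.
DEFAULT_HETEROMER_RANGE = (1, 2)
#: Combinatorial guard — refuse larger enumerations unless forced.
MAX_CANDIDATES = 512


@dataclass
class CandidateSet:
    """Shortlist for one target: kept candidates plus visible exclusions."""

    target_id: str
    kept: list[Stoichiometry] = field(default_factory=list)
    excluded: list[tuple[Stoichiometry, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.kept)

    def contains(self, s: Stoichiometry) -> bool:
        return s in self.kept


def enumerate_from_ranges(ranges: CopyRanges, *, force: bool = False) -> list[Stoichiometry]:
    """Cartesian product of per-subunit copy ranges.

    Three subunits each spanning (1, 2) give the classic eight-candidate
    list A1B1C1 … A2B2C2.  Enumerations larger than ``MAX_CANDIDATES``
    are refused unless ``force`` is set.
    """
    if not ranges:
        raise ValueError("cannot enumerate candidates from empty copy ranges")
    labels = sorted(ranges)
    spans = []
    for lab in labels:
        lo, hi = ranges[lab]
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid copy range for subunit {lab}: ({lo}, {hi})")
        spans.append(range(lo, hi + 1))
    n = math.prod(len(span) for span in spans)
    if n > MAX_CANDIDATES and not force:
        raise ValueError(
            f"{n} candidates exceed the guard of {MAX_CANDIDATES}; "
            "narrow the ranges or pass force=True"
        )
    out = [
        Stoichiometry(tuple(zip(labels, combo)))
        for combo in itertools.product(*spans)
    ]
    # product over distinct labels cannot repeat, but dedup defensively
    seen: set[Stoichiometry] = set()
    unique = []
    for cand in out:
        if cand not in seen:
            seen.add(cand)
            unique.append(cand)
    return unique


def enumerate_homomer(min_copies: int = DEFAULT_HOMOMER_RANGE[0],
                      max_copies: int = DEFAULT_HOMOMER_RANGE[1],
                      label: str = "A") -> list[Stoichiometry]:
    """Homo-multimer candidates ``A{min} … A{max}`` in ascending order."""
    if not (1 <= min_copies <= max_copies):
        raise ValueError(f"invalid homomer range ({min_copies}, {max_copies})")
    return [Stoichiometry(((label, k),)) for k in range(min_copies, max_copies + 1)]


def filter_by_size(candidates: Sequence[Stoichiometry],
                   lengths: SubunitLengths,
                   cap: float = DEFAULT_RESIDUE_CAP,
                   target_id: str = "") -> CandidateSet:
    """Partition candidates at the residue budget; exclusions stay visible.

    ``cap`` may be ``math.inf`` (local AlphaFold3 with ample memory).
    Duplicates are removed before partitioning, so kept + excluded
    conserves the deduplicated input.
    """
    out = CandidateSet(target_id=target_id)
    seen: set[Stoichiometry] = set()
    for cand in candidates:
        if cand in seen:
            continue
        seen.add(cand)
        if total_residues(cand, lengths) <= cap:
            out.kept.append(cand)
        else:
            out.excluded.append((cand, "size_cap"))
    return out


def order_candidates(candidates: Sequence[Stoichiometry]) -> list[Stoichiometry]:
    """Deterministic low-to-high order: total copies, then canonical string."""
    return sorted(candidates, key=lambda s: (s.total_copies, format_stoichiometry(s)))
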