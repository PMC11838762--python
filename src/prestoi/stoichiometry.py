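"""Stoichiometry value type and compatibility relations.

A stoichiometry is the multiset of subunit copy counts of a protein
complex, written in the compact notation used throughout structural
biology: ``A2B2C2`` is a hetero-hexamer of three distinct subunits with
two copies each, ``A6`` a homo-hexamer.  Subunits are labelled with
single capital letters; a count of one is always written explicitly
(``A1``, never a bare ``A``).

Besides parsing and formatting, this module implements the structural
compatibility relations between two stoichiometries that exact-match
scoring ignores: one may be a scalar multiple of the other (``A1B1`` vs
``A2B2`` — the dimer/tetramer ambiguity), a subset or superset
(``A2B2C1`` vs ``A2B2C2``), or simply disagree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

__all__ = [
    "Stoichiometry",
    "SubunitLengths",
    "CompatibilityRelation",
    "StoichiometryParseError",
    "parse_stoichiometry",
    "format_stoichiometry",
    "total_residues",
    "compare",
]

_TOKEN = re.compile(r"([A-Z])(\d+)")

SubunitLengths = Mapping[str, int]


class StoichiometryParseError(ValueError):
    """Raised when a stoichiometry string cannot be parsed."""


@dataclass(frozen=True)
class Stoichiometry:
    """Copy count of each unique subunit of a complex.

    ``items`` keeps first-appearance order; equality and hashing are
    order-insensitive (``A2B1`` built as ``B1A2`` is the same complex)
    but label-sensitive (``A2B1`` differs from ``A1B2``).
    """

    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("a stoichiometry needs at least one subunit")
        labels = [lab for lab, _ in self.items]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate subunit label in {self.items!r}")
        for lab, count in self.items:
            if not (len(lab) == 1 and "A" <= lab <= "Z"):
                raise ValueError(f"subunit label must be A-Z, got {lab!r}")
            if count < 1:
                raise ValueError(f"copy count for {lab} must be >= 1, got {count}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int] | Iterable[tuple[str, int]]) -> "Stoichiometry":
        if isinstance(counts, Mapping):
            return cls(tuple(counts.items()))
        return cls(tuple(counts))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.items)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(lab for lab, _ in self.items)

    @property
    def total_copies(self) -> int:
        return sum(count for _, count in self.items)

    @property
    def n_unique_subunits(self) -> int:
        return len(self.items)

    @property
    def is_homomer(self) -> bool:
        return len(self.items) == 1

    def scaled(self, k: int) -> "Stoichiometry":
        """The complex with every copy count multiplied by ``k``."""
        if k < 1:
            raise ValueError("scale factor must be a positive integer")
        return Stoichiometry(tuple((lab, count * k) for lab, count in self.items))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Stoichiometry):
            return NotImplemented
        return sorted(self.items) == sorted(other.items)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.items)))

    def __str__(self) -> str:
        return format_stoichiometry(self)

    def __repr__(self) -> str:
        return f"Stoichiometry({format_stoichiometry(self)!r})"


@dataclass(frozen=True)
class CompatibilityRelation:
    """Structural relation of one stoichiometry to another.

    ``kind`` is one of ``identical``, ``scalar_multiple``, ``subset``,
    ``superset`` or ``disjoint_counts``, reported from the first
    argument's perspective.  For ``scalar_multiple``, ``factor`` is the
    rational k with ``b == k * a``, so ``compare(A1B1, A2B2)`` carries
    factor 2 and the swapped call factor 1/2.
    """

    kind: str
    factor: Fraction | None = field(default=None)

    def __str__(self) -> str:
        if self.kind == "scalar_multiple" and self.factor is not None:
            return f"scalar_multiple(x{self.factor})"
        return self.kind


def parse_stoichiometry(text: str) -> Stoichiometry:
    """Parse compact notation like ``"A2B2C2"`` or ``"A9B18"``.

    Every subunit must carry an explicit count (``"A"`` alone is
    rejected), counts may be multi-digit, and labels may not repeat.
    """
    if not isinstance(text, str) or not text:
        raise StoichiometryParseError("empty stoichiometry string")
    pos = 0
    items: list[tuple[str, int]] = []
    seen: set[str] = set()
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise StoichiometryParseError(
                f"malformed stoichiometry {text!r}: unexpected token at {text[pos:match.start()]!r}"
            )
        lab, digits = match.group(1), match.group(2)
        count = int(digits)
        if count == 0:
            raise StoichiometryParseError(f"zero copy count for subunit {lab} in {text!r}")
        if lab in seen:
            raise StoichiometryParseError(f"duplicate subunit label {lab} in {text!r}")
        seen.add(lab)
        items.append((lab, count))
        pos = match.end()
    if pos != len(text) or not items:
        raise StoichiometryParseError(
            f"malformed stoichiometry {text!r}: trailing token {text[pos:]!r}"
        )
    return Stoichiometry(tuple(items))


def format_stoichiometry(s: Stoichiometry) -> str:
    """Canonical string: alphabetical labels, explicit counts (``A1B2``)."""
    return "".join(f"{lab}{count}" for lab, count in sorted(s.items))


def total_residues(s: Stoichiometry, lengths: SubunitLengths) -> int:
    """Total residue count of the assembled complex.

    Used against size caps such as the 5000-residue limit of the
    AlphaFold3 web server.
    """
    total = 0
    for lab, count in s.items:
        if lab not in lengths:
            raise KeyError(f"no sequence length for subunit {lab!r}")
        total += count * int(lengths[lab])
    return total


def compare(a: Stoichiometry, b: Stoichiometry) -> CompatibilityRelation:
    """Classify the structural relation of ``a`` to ``b``.

    identical: same labels and counts.  scalar_multiple: same labels and
    ``b == k*a`` (or the inverse) for an integer k > 1 — the relation
    behind the dimer/tetramer ambiguity.  subset / superset: label sets
    nest and counts compare component-wise (and the pair is not
    identical or a scalar multiple).  Anything else: disjoint_counts.
    """
    ca, cb = a.counts, b.counts
    if ca == cb:
        return CompatibilityRelation("identical")
    if a.labels == b.labels:
        ratios = {Fraction(cb[lab], ca[lab]) for lab in ca}
        if len(ratios) == 1:
            k = ratios.pop()
            if k.denominator == 1 and k > 1 or k.numerator == 1 and k < 1:
                return CompatibilityRelation("scalar_multiple", factor=k)
    if a.labels <= b.labels and all(ca[lab] <= cb[lab] for lab in ca):
        return CompatibilityRelation("subset")
    if b.labels <= a.labels and all(cb[lab] <= ca[lab] for lab in cb):
        return CompatibilityRelation("superset")
    return CompatibilityRelation("disjoint_counts")
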