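"""Integration of AlphaFold3-based and template-based predictions.

The final call for a target combines up to three method predictions:
AF-max and AF-avg (AlphaFold3 ranking-score aggregates) and TB (template
based).  Template evidence, when confident, is more precise than
AlphaFold3 ranking at picking the top-1 stoichiometry, so a conflicting
TB prediction at or above the policy's override grade takes precedence;
the displaced AlphaFold3 top-1 stays within the top three.  When the
two AlphaFold3 modes disagree and no template prediction exists, the
choice is genuinely ambiguous — the policy deterministically prefers
one mode (AF-max by default, the more accurate of the two on its own)
and flags the conflict in the decision trace; a per-target override can
force the other mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .stoichiometry import Stoichiometry
from .templates import GRADE_ORDER

__all__ = [
    "MethodPrediction",
    "FinalPrediction",
    "IntegrationPolicy",
    "integrate",
    "decision_trace_label",
]

METHOD_ORDER = ("AF-max", "AF-avg", "TB")


@dataclass
class MethodPrediction:
    """One method's ranked stoichiometries for one target."""

    method: str  # "AF-max" | "AF-avg" | "TB"
    applicable: bool
    ranking: list[Stoichiometry] = field(default_factory=list)
    grade: str | None = None  # TB confidence grade

    def __post_init__(self) -> None:
        if self.method not in METHOD_ORDER:
            raise ValueError(f"unknown method {self.method!r}")
        if self.applicable and not self.ranking:
            raise ValueError(f"{self.method}: applicable but empty ranking")
        if not self.applicable and self.ranking:
            raise ValueError(f"{self.method}: not applicable yet carries a ranking")

    @property
    def top1(self) -> Stoichiometry | None:
        return self.ranking[0] if self.applicable else None

    @classmethod
    def not_applicable(cls, method: str) -> "MethodPrediction":
        return cls(method, False)


@dataclass
class IntegrationPolicy:
    """Tunable precedence rules.

    ``preferred_af``: which AlphaFold3 aggregate wins when the modes
    disagree and no template prediction decides.  ``tb_override_grade``:
    minimum TB confidence that overrides a conflicting AlphaFold3 top-1
    ("medium" reproduces the CASP16 pipeline, including its known
    homodimer-template failure mode; "high" is the conservative
    setting).  ``top_n``: number of final predictions.
    """

    preferred_af: str = "max"
    tb_override_grade: str = "medium"
    top_n: int = 3


@dataclass
class FinalPrediction:
    """1–3 final ranked stoichiometries with a decision trace."""

    target_id: str
    stoichiometries: list[Stoichiometry]
    rule: str
    trace: list[str] = field(default_factory=list)
    af_conflict_no_tb: bool = False
    method_top1s: dict[str, Stoichiometry | None] = field(default_factory=dict)

    @property
    def top1(self) -> Stoichiometry:
        return self.stoichiometries[0]


def _fill(slots: list[Stoichiometry], extras: Sequence[Stoichiometry | None], n: int) -> None:
    for cand in extras:
        if cand is not None and cand not in slots and len(slots) < n:
            slots.append(cand)


def integrate(af_max: MethodPrediction,
              af_avg: MethodPrediction,
              tb: MethodPrediction,
              policy: IntegrationPolicy | None = None,
              target_id: str = "",
              override: str | None = None) -> FinalPrediction:
    """Combine method predictions into the final ranked list.

    Rules, in order: TB-only targets take the TB prediction; a TB
    prediction agreeing with the preferred AlphaFold3 top-1 confirms it;
    a conflicting TB at or above the override grade replaces it (the
    AlphaFold3 top-1 is kept within the top three); otherwise the
    preferred AlphaFold3 mode wins.  ``override`` names a method
    ("AF-max", "AF-avg" or "TB", or a " + "-joined label whose first
    entry is used) whose top-1 is forced as the final top-1.
    """
    policy = policy or IntegrationPolicy()
    preds = {"AF-max": af_max, "AF-avg": af_avg, "TB": tb}
    if not any(p.applicable for p in preds.values()):
        raise ValueError(f"no applicable prediction method for target {target_id!r}")

    preferred_name = "AF-max" if policy.preferred_af == "max" else "AF-avg"
    other_name = "AF-avg" if preferred_name == "AF-max" else "AF-max"
    af_pref = preds[preferred_name] if preds[preferred_name].applicable else preds[other_name]
    af_other = preds[other_name] if af_pref is preds[preferred_name] else preds[preferred_name]

    trace: list[str] = []
    af_conflict = (af_max.applicable and af_avg.applicable
                   and af_max.top1 != af_avg.top1)
    af_conflict_no_tb = af_conflict and not tb.applicable
    if af_conflict:
        trace.append(
            f"AF-max top-1 {af_max.top1} != AF-avg top-1 {af_avg.top1}"
            + ("" if tb.applicable else "; no TB to decide — preferred mode used")
        )

    slots: list[Stoichiometry] = []
    if override:
        forced = override.split(" + ")[0].strip()
        if forced not in preds or not preds[forced].applicable:
            raise ValueError(f"override method {forced!r} not applicable for {target_id!r}")
        rule = f"override:{forced}"
        slots.append(preds[forced].top1)
        trace.append(f"per-target override forces {forced} top-1")
    elif not af_pref.applicable:
        rule = "tb_only"
        slots.append(tb.top1)
        trace.append("AlphaFold3 not applicable; TB prediction used")
    elif not tb.applicable:
        rule = "af_only"
        slots.append(af_pref.top1)
        trace.append(f"no TB prediction; {af_pref.method} top-1 used")
    elif tb.top1 == af_pref.top1:
        rule = "tb_confirms_af"
        slots.append(af_pref.top1)
        trace.append(f"TB agrees with {af_pref.method} top-1; retained")
    elif GRADE_ORDER[tb.grade or "none"] >= GRADE_ORDER[policy.tb_override_grade]:
        rule = "tb_overrides_af"
        slots.append(tb.top1)
        trace.append(
            f"TB ({tb.grade}) conflicts with {af_pref.method} and takes precedence; "
            f"{af_pref.method} top-1 kept in top-{policy.top_n}"
        )
    else:
        rule = "af_over_low_grade_tb"
        slots.append(af_pref.top1)
        trace.append(
            f"TB grade {tb.grade} below override grade {policy.tb_override_grade}; "
            f"{af_pref.method} top-1 retained, TB kept in top-{policy.top_n}"
        )

    _fill(slots, [af_pref.top1, af_other.top1, tb.top1], policy.top_n)
    _fill(slots, af_pref.ranking, policy.top_n)
    if af_other.applicable:
        _fill(slots, af_other.ranking, policy.top_n)

    return FinalPrediction(
        target_id=target_id,
        stoichiometries=slots,
        rule=rule,
        trace=trace,
        af_conflict_no_tb=af_conflict_no_tb,
        method_top1s={name: preds[name].top1 for name in METHOD_ORDER},
    )


def decision_trace_label(final: FinalPrediction) -> str:
    """Canonical label of the methods whose top-1 equals the final top-1,
    joined with " + " in AF-max, AF-avg, TB order (e.g. "AF-max + TB")."""
    contributors = [
        name for name in METHOD_ORDER
        if final.method_top1s.get(name) == final.top1
    ]
    return " + ".join(contributors)
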