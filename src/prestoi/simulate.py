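"""Seeded synthetic benchmark generator.

Emulates the two upstream data sources the predictor consumes — model
ranking-score files and template hit tables — for targets with known
true stoichiometry, so the whole pipeline is testable offline and its
statistical behaviour (signal-to-noise recovery, template rescue, the
dimer/tetramer ambiguity) can be measured.

The score model is deliberately simple: every model of a candidate
draws ``base + bonus*1[candidate == truth] + noise`` (truncated to
[-1, 1]), i.e. the correct stoichiometry carries a constant score bonus
that the per-model noise can mask.  The ambiguity mode additionally
grants a partial bonus to candidates that are scalar multiples of the
truth, reproducing the hetero-dimer/hetero-tetramer confusion that
dominates the real failure modes.  Template tables are planted with
configurable coverage (a full complex template, independent per-subunit
templates, or nothing) and a per-subunit copy-corruption rate.

Defaults mirror the benchmark conditions: 28 targets with roughly a
third homo-multimers, templates available for about 60% of targets,
25 models per candidate, base score 0.6, bonus 0.2, noise s.d. 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .candidates import (
    DEFAULT_HETEROMER_RANGE,
    DEFAULT_HOMOMER_RANGE,
    enumerate_from_ranges,
    enumerate_homomer,
    order_candidates,
)
from .scoring import ModelScoreRecord
from .stoichiometry import Stoichiometry, compare, format_stoichiometry
from .templates import TemplateHit

__all__ = ["SyntheticSpec", "SyntheticTarget", "SyntheticDataset", "generate_dataset"]

_PDB_ALPHABET = list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark."""

    n_targets: int = 28
    homo_fraction: float = 9 / 28
    max_hetero_subunits: int = 3
    length_range: tuple[int, int] = (100, 400)
    homo_truth_range: tuple[int, int] = (2, 6)
    hetero_truth_range: tuple[int, int] = DEFAULT_HETEROMER_RANGE
    # score model
    base_score: float = 0.6
    bonus: float = 0.2
    noise_sd: float = 0.05
    models_per_candidate: int = 25
    #: fraction of ``bonus`` granted to scalar multiples of the truth;
    #: > 0 switches on the dimer/tetramer-ambiguity mode
    ambiguity_bonus_fraction: float = 0.0
    # template model
    p_full_template: float = 0.4
    p_subunit_template: float = 0.2
    hits_per_subunit: int = 3
    copy_corruption_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("homo_fraction", "ambiguity_bonus_fraction",
                     "p_full_template", "p_subunit_template", "copy_corruption_rate"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.p_full_template + self.p_subunit_template > 1.0:
            raise ValueError("template coverage probabilities exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.models_per_candidate < 1:
            raise ValueError("models_per_candidate must be >= 1")


@dataclass
class SyntheticTarget:
    """One generated target with its ground truth and planted evidence."""

    target_id: str
    truth: Stoichiometry
    lengths: dict[str, int]
    candidates: list[Stoichiometry]
    hits: list[TemplateHit]
    template_mode: str  # "full" | "subunit" | "none"

    @property
    def is_homomer(self) -> bool:
        return self.truth.is_homomer


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    targets: list[SyntheticTarget]
    scores: list[ModelScoreRecord] = field(default_factory=list)

    def scores_for(self, target_id: str) -> list[ModelScoreRecord]:
        return [r for r in self.scores if r.target_id == target_id]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the pipeline's exchange TSVs (targets, hits, scores, truth)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {name: out / f"{name}.tsv"
                 for name in ("targets", "hits", "scores", "truth")}
        with open(paths["targets"], "w") as fh:
            fh.write("target_id\tsubunit\tlength\n")
            for t in self.targets:
                for lab in sorted(t.lengths):
                    fh.write(f"{t.target_id}\t{lab}\t{t.lengths[lab]}\n")
        with open(paths["hits"], "w") as fh:
            fh.write("target_id\tsubunit\ttemplate_pdb\tevalue\tcopies_in_template"
                     "\ttemplate_stoichiometry\n")
            for t in self.targets:
                for h in t.hits:
                    stoich = (format_stoichiometry(h.template_stoichiometry)
                              if h.template_stoichiometry else "NA")
                    fh.write(f"{t.target_id}\t{h.subunit}\t{h.template_pdb}"
                             f"\t{h.evalue:.3e}\t{h.copies_in_template}\t{stoich}\n")
        with open(paths["scores"], "w") as fh:
            fh.write("target_id\tcandidate\tmodel_id\tranking_score\n")
            for r in self.scores:
                fh.write(f"{r.target_id}\t{format_stoichiometry(r.candidate)}"
                         f"\t{r.model_id}\t{r.ranking_score:.6f}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("target_id\ttrue_stoichiometry\tdifficulty\n")
            for t in self.targets:
                fh.write(f"{t.target_id}\t{format_stoichiometry(t.truth)}\t50\n")
        return paths


def _random_pdb(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_PDB_ALPHABET) for _ in range(4))


def _corrupt(copies: int, rng: np.random.Generator, rate: float) -> int:
    if rate > 0 and rng.random() < rate:
        return copies + 1 if copies == 1 or rng.random() < 0.5 else copies - 1
    return copies


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate targets, hit tables and score records; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    targets: list[SyntheticTarget] = []
    scores: list[ModelScoreRecord] = []

    for i in range(spec.n_targets):
        homo = rng.random() < spec.homo_fraction
        target_id = f"{'S' if homo else 'X'}{i:04d}{'o' if homo else ''}"

        if homo:
            lo, hi = spec.homo_truth_range
            truth = Stoichiometry((("A", int(rng.integers(lo, hi + 1))),))
            labels = ["A"]
            candidates = enumerate_homomer(*DEFAULT_HOMOMER_RANGE)
        else:
            n_sub = int(rng.integers(2, spec.max_hetero_subunits + 1))
            labels = [chr(ord("A") + j) for j in range(n_sub)]
            lo, hi = spec.hetero_truth_range
            if spec.ambiguity_bonus_fraction > 0:
                # ambiguity mode: hetero truths are all-ones so a scalar
                # double always sits in the candidate list
                truth = Stoichiometry(tuple((lab, 1) for lab in labels))
            else:
                truth = Stoichiometry(tuple(
                    (lab, int(rng.integers(lo, hi + 1))) for lab in labels))
            candidates = enumerate_from_ranges({lab: (lo, hi) for lab in labels})
        if truth not in candidates:
            raise ValueError(f"infeasible spec: truth {truth} not enumerable "
                             f"for target {target_id}")
        candidates = order_candidates(candidates)

        lengths = {lab: int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
                   for lab in labels}

        # template evidence
        u = rng.random()
        hits: list[TemplateHit] = []
        if u < spec.p_full_template:
            mode = "full"
            pdb = _random_pdb(rng)
            for lab in labels:
                hits.append(TemplateHit(
                    subunit=lab, template_pdb=pdb,
                    evalue=float(10 ** rng.uniform(-10, -4)),
                    copies_in_template=_corrupt(truth.counts[lab], rng,
                                                spec.copy_corruption_rate),
                    template_stoichiometry=truth,
                ))
        elif u < spec.p_full_template + spec.p_subunit_template:
            mode = "subunit"
            for lab in labels:
                for _ in range(spec.hits_per_subunit):
                    hits.append(TemplateHit(
                        subunit=lab, template_pdb=_random_pdb(rng),
                        evalue=float(10 ** rng.uniform(-10, -4)),
                        copies_in_template=_corrupt(truth.counts[lab], rng,
                                                    spec.copy_corruption_rate),
                    ))
        else:
            mode = "none"

        # model ranking scores
        for cand in candidates:
            rel = compare(cand, truth).kind
            signal = spec.base_score
            if rel == "identical":
                signal += spec.bonus
            elif rel == "scalar_multiple" and spec.ambiguity_bonus_fraction > 0:
                signal += spec.ambiguity_bonus_fraction * spec.bonus
            noise = rng.normal(0.0, spec.noise_sd, size=spec.models_per_candidate) \
                if spec.noise_sd > 0 else np.zeros(spec.models_per_candidate)
            for m, eps in enumerate(noise):
                scores.append(ModelScoreRecord(
                    target_id=target_id, candidate=cand, model_id=f"m{m}",
                    ranking_score=float(np.clip(signal + eps, -1.0, 1.0)),
                ))

        targets.append(SyntheticTarget(target_id, truth, lengths,
                                       candidates, hits, mode))

    return SyntheticDataset(spec, targets, scores)
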