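# Methods

## The prediction problem

A protein complex's stoichiometry is the multiset of copy counts of
its unique subunits. The package predicts it by scoring a shortlist of
candidate stoichiometries with two independent evidence sources —
aggregated AlphaFold3 model ranking scores and homologous complex
templates from the PDB — and integrating the two with a precedence
policy. Both sources arrive as files (per-model score records, a
subunit-to-template hit table); the package never runs AlphaFold3,
Jackhmmer or HHSearch itself.

## Candidate generation

Homo-multimers enumerate `A2 … A9`: dimer up to the largest assembly
AlphaFold3 routinely handles. Template evidence may *narrow* this span
(intersection of the evidence range with (2, 9)) but never widen it;
widening past 9 requires explicit configuration, so unusual filament
stoichiometries such as A9B18 are out of reach by default — a known,
deliberate limitation, since proposing them without template support
would explode the shortlist.

Hetero-multimers take the Cartesian product of per-subunit copy
ranges. Each subunit's range is the (min, max) of
`copies_in_template` over its hits at E-value ≤ 10⁻³; a subunit with
no qualifying hit walks the relaxation schedule 10⁻², 10⁻¹, 1 and
finally falls back to (1, 2), so a candidate list always exists. The
(1, 2) fallback reflects the empirical prior that unknown hetero
subunits most often occur once or twice. Completions of a partially
covering complex template (pattern `A2B2C2D2E2F?`) are added to the
pool. Enumerations above 512 candidates are refused unless forced.

Candidates whose assembled residue count exceeds the cap (default
5000, the AlphaFold3 web-server limit; `inf` for local installations)
are moved to a visible *excluded* list with reason `size_cap` — an
excluded true stoichiometry must be diagnosable downstream, where the
ranking reports such candidates as *untested* rather than low-scoring.

## Score aggregation and ranking

Each model score record carries a ranking score, or the four
components to recompose one as
`0.8·ipTM + 0.2·pTM + 0.5·disorder − 100·clash` (weights
configurable; a supplied ranking score always wins over
recomposition). AF-max and AF-avg are the per-candidate maximum and
arithmetic mean over models; the mean uses a sorted compensated sum so
the aggregate is exactly invariant under record permutation. A
candidate with fewer than 5 models still gets an AF-avg but is
flagged, since small-sample means are noisy against the typical 25–50
models per candidate. Ranking is by descending aggregate; exact ties
break toward fewer total subunit copies (parsimony), then canonical
string order, and every fired tie-break is recorded.

## Template-based prediction and confidence grades

- **high** — a single complex template covers every subunit; its
  per-subunit copy counts are the prediction. Among several covering
  templates the one with the best worst-subunit E-value wins.
- **medium** — per-subunit consensus: every subunit has a *strict*
  modal copy count over its qualifying hits; ties break the consensus
  rather than being resolved arbitrarily. This grade is deliberately
  weaker: two hetero-dimer subunits that each match only homodimer
  templates produce A2B2 at medium grade, which is exactly the failure
  mode that motivates the grade distinction.
- **medium (partial)** — a template covering a strict subset of
  subunits is completed with the lower bound of the completion range
  for uncovered subunits; the copies of uncovered subunits are guesses,
  not evidence, hence not high grade.
- **none** — no rule fires; TB is not applicable.

The E-value thresholds are configuration, not claims: profile-profile
search significance scales vary by tool, so all of them are exposed in
`RunConfig`.

## Integration policy

If the TB prediction agrees with the preferred AlphaFold3 aggregate's
top-1, it is confirmed. If it conflicts and its grade is at or above
`tb_override_grade`, TB takes the top-1 and the displaced AlphaFold3
call stays within the top three. The default override grade is
`medium`, which reproduces the CASP16 pipeline's behaviour including
its one documented template-interpretation error on a hetero-dimer;
`high` is the conservative recommendation and flips exactly those
medium-grade conflicts back to AlphaFold3.

When no TB prediction exists and AF-max and AF-avg disagree, no
mechanical rule is clearly right — the benchmark record shows human
judgement went both ways. The policy deterministically prefers AF-max
(the stronger standalone aggregate, 56% vs 48% top-1 on applied
targets) and flags the conflict in the decision trace; a per-target
override input reproduces the recorded human choices exactly. Slots 2
and 3 of the final list are filled from the other method's top-1 and
the next-ranked candidates, deduplicated; the ordering within slots
2–3 is a package convention, as benchmark tables record only the top-1
and a top-3 outcome flag.

## Evaluation

Correctness is exact match only. Scalar multiples (A1B1 vs A2B2),
subsets and supersets are annotated per target via the compatibility
relation but never credited — structurally similar wrong answers stay
wrong. Per-method accuracy on *all* targets counts not-applicable
targets as incorrect; accuracy on *applied* targets restricts the
denominator. The easy/hard split is at 60% community-failure
difficulty. Homo/hetero classification derives from the true
stoichiometry's unique-subunit count and is cross-checked against the
`T####o`/`H####` naming convention when loading the packaged table.
Percentages keep full precision internally and round half-up for
display (one decimal by default).

The packaged benchmark table is checksum-verified at load. Two cells
of the published table contain obvious typographical slips (a stray
`G` in one true stoichiometry that the running text spells
`A2B2C2D2E2F2` three times, and `H/A` for `N/A`); the transcription
uses the corrected values.

## Synthetic data generator

The generator emulates the two input files with planted ground truth.
Per target: a truth drawn from the copy distribution (homo-multimers
2–6 copies, hetero subunits 1–2 copies, 2–3 unique subunits), subunit
lengths uniform on 100–400 residues, and for every enumerable
candidate `models_per_candidate` score records drawn as
`base + bonus·1[candidate = truth] + N(0, noise_sd)` clipped to
[−1, 1]. Defaults — 28 targets, ~32% homo-multimers, base 0.6, bonus
0.2, noise s.d. 0.05, 25 models per candidate, template coverage 40%
full / 20% per-subunit — mirror the benchmark's composition and
produce score gaps of the size seen in practice (e.g. 0.96 vs 0.89
between compatible candidates). All draws flow from one seed;
identical seeds produce byte-identical output files.

The *ambiguity mode* (`ambiguity_bonus_fraction` > 0) grants scalar
multiples of the truth a partial bonus (0.9 of the full bonus in the
tests, making the planted gap comparable to the model-level noise) and
pins hetero truths at one copy per subunit so the scalar double is
always enumerable — reproducing the hetero-dimer/hetero-tetramer
confusion that dominates real failures. Template corruption perturbs
planted copy counts at a configurable rate.

What the generator does **not** emulate: real sequences, structures or
pLDDT; correlated errors between AlphaFold3 models; template E-value
distributions of real profile searches; size-capped targets. Passing
recovery tests therefore demonstrates that the pipeline's selection
logic is correct under its own assumptions, not that those accuracy
levels transfer to real complexes.

## Problem sizes and numerical choices

The recovery studies use 200 synthetic targets for score-signal
recovery and 100 for planted-template recovery — large enough that a
95% accuracy bound is meaningful, and each runs in seconds. Exact
score ties are resolved by parsimony before canonical order, chosen
over random tie-breaks for determinism. Degenerate inputs are errors,
never silent defaults: empty ranges, zero copy counts, inconsistent
duplicate template hits, candidates with no scored models.

## Known limitations

- Filament-scale and otherwise unusual stoichiometries outside the
  default enumeration ranges are never proposed without explicit
  configuration.
- Literature-based and manual template reinterpretation (e.g. reading
  a homodimer template of two homologous subunits as hetero-dimer
  evidence) is out of scope; only the mechanical rules above run.
- Symmetry, interface packing and higher-order oligomerisation cues
  are not used; a per-target override hook is the only entry point for
  such judgement.
- Structural similarity scoring of predictions (QS-score/TM-score)
  requires structural models and is replaced by the descriptive
  compatibility annotation.
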