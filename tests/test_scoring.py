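import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prestoi import (
    ModelScoreRecord,
    aggregate,
    compose_ranking_score,
    parse_stoichiometry,
    rank_candidates,
    read_model_scores,
    top_k,
)
from conftest import make_scores


def rec(cand, model, score, target="T"):
    return ModelScoreRecord(target_id=target, candidate=parse_stoichiometry(cand),
                            model_id=model, ranking_score=score)


class TestReadModelScores:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("target_id\tcandidate\tmodel_id\tranking_score\n"
                        "H0245\tA1B1\tm0\t0.91\n")
        (record,) = read_model_scores(path)
        assert record.target_id == "H0245"
        assert record.candidate == parse_stoichiometry("A1B1")
        assert record.ranking_score == 0.91

    def test_af3_summary_json_layout(self, tmp_path):
        mdir = tmp_path / "H0208" / "A1B1"
        mdir.mkdir(parents=True)
        (mdir / "summary_confidences_0.json").write_text(json.dumps({
            "ranking_score": 0.96, "ptm": 0.9, "iptm": 0.95,
            "fraction_disordered": 0.02, "has_clash": 0,
        }))
        (record,) = read_model_scores(tmp_path, dialect="af3_summary_json")
        assert record.target_id == "H0208"
        assert record.candidate == parse_stoichiometry("A1B1")
        assert record.ranking_score == 0.96
        assert record.has_components

    def test_missing_score_and_components_rejected(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("target_id\tcandidate\tmodel_id\tranking_score\n"
                        "H0245\tA1B1\tm0\t\n")
        with pytest.raises(ValueError, match="line 2"):
            read_model_scores(path)

    def test_typical_model_count_per_candidate(self, tmp_path):
        path = tmp_path / "scores.tsv"
        lines = ["target_id\tcandidate\tmodel_id\tranking_score"]
        lines += [f"T\tA2\tm{i}\t0.8" for i in range(25)]
        path.write_text("\n".join(lines) + "\n")
        assert len(read_model_scores(path)) == 25


class TestComposeRankingScore:
    def test_perfect_model_limit(self):
        comps = {"iptm": 1.0, "ptm": 1.0, "disorder": 0.0, "has_clash": 0}
        assert compose_ranking_score(comps) == pytest.approx(1.0)

    def test_clash_penalty_dominates(self):
        comps = {"iptm": 1.0, "ptm": 1.0, "disorder": 1.0, "has_clash": 1}
        assert compose_ranking_score(comps) < 0

    def test_hand_arithmetic(self):
        comps = {"iptm": 0.5, "ptm": 0.5, "disorder": 0.2, "has_clash": 0}
        assert compose_ranking_score(comps) == pytest.approx(0.6)

    def test_missing_component_errors(self):
        with pytest.raises(ValueError, match="missing"):
            compose_ranking_score({"iptm": 1.0, "ptm": 1.0, "disorder": 0.0})

    def test_used_as_fallback_when_no_ranking_score(self):
        record = ModelScoreRecord("T", parse_stoichiometry("A2"), "m0",
                                  ptm=0.5, iptm=0.5, disorder=0.2, has_clash=0)
        assert record.score() == pytest.approx(0.6)


score_sets = st.dictionaries(
    st.sampled_from(["A1B1", "A1B2", "A2B1", "A2B2", "A2", "A3"]),
    st.lists(st.floats(-1, 1, allow_nan=False, width=32), min_size=1, max_size=8),
    min_size=1, max_size=6,
)


class TestAggregate:
    def test_worked_maxima(self, h0208_scores):
        agg = aggregate(h0208_scores, "max")
        assert agg[parse_stoichiometry("A1B1")][0] == pytest.approx(0.96)
        assert agg[parse_stoichiometry("A2B2")][0] == pytest.approx(0.89)

    def test_single_model_max_equals_avg(self):
        records = [rec("A2", "m0", 0.7)]
        assert aggregate(records, "max") == aggregate(records, "avg")

    def test_unscored_candidates_absent_not_zero(self):
        agg = aggregate([rec("A2", "m0", 0.7)], "max")
        assert parse_stoichiometry("A3") not in agg

    @given(score_sets)
    @settings(max_examples=150, deadline=None)
    def test_max_at_least_avg(self, sets):
        records = [rec(c, f"m{i}", v) for c, vals in sets.items()
                   for i, v in enumerate(vals)]
        mx, av = aggregate(records, "max"), aggregate(records, "avg")
        for cand in mx:
            assert mx[cand][0] >= av[cand][0] - 1e-12

    @given(score_sets, st.randoms())
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, sets, rnd):
        records = [rec(c, f"m{i}", v) for c, vals in sets.items()
                   for i, v in enumerate(vals)]
        shuffled = records[:]
        rnd.shuffle(shuffled)
        for mode in ("max", "avg"):
            assert aggregate(records, mode) == aggregate(shuffled, mode)
            assert rank_candidates(aggregate(records, mode)).entries == \
                rank_candidates(aggregate(shuffled, mode)).entries

    def test_low_score_model_never_raises_max(self):
        records = [rec("A2", "m0", 0.8), rec("A2", "m1", 0.7)]
        before = aggregate(records, "max")[parse_stoichiometry("A2")][0]
        extended = records + [rec("A2", "m2", 0.5)]
        after_max = aggregate(extended, "max")[parse_stoichiometry("A2")][0]
        after_avg = aggregate(extended, "avg")[parse_stoichiometry("A2")][0]
        assert after_max == before and after_avg <= before


class TestRanking:
    def test_descending_scores_and_top1(self, t0235o_scores):
        ranking = rank_candidates(aggregate(t0235o_scores, "max"), "T0235o")
        scores = [s for _, s, _ in ranking.entries]
        assert scores == sorted(scores, reverse=True)
        assert str(ranking.top1()) == "A6"
        assert ranking.entries[0][1] == pytest.approx(0.88)

    def test_reproduces_higher_scoring_wrong_candidate(self):
        # an incorrect lower-order stoichiometry outscoring the truth is
        # ranked first: the ranking follows the scores, not the truth
        records = make_scores("H0236", {"A3B3": 0.90, "A3B6": 0.85})
        ranking = rank_candidates(aggregate(records, "max"), "H0236")
        assert str(ranking.top1()) == "A3B3"

    def test_exact_tie_goes_to_fewer_copies_with_trace(self):
        records = [rec("A2B2", "m0", 0.8), rec("A1B1", "m0", 0.8)]
        ranking = rank_candidates(aggregate(records, "max"))
        assert str(ranking.top1()) == "A1B1"
        assert ranking.tie_break_trace

    def test_oracle_equivalence_on_random_sets(self):
        rnd = random.Random(7)
        for _ in range(30):
            cands = rnd.sample(["A1B1", "A1B2", "A2B1", "A2B2", "A3B1"], 3)
            sets = {c: [round(rnd.uniform(0, 1), 3)
                        for _ in range(rnd.randint(1, 6))] for c in cands}
            records = [rec(c, f"m{i}", v) for c, vals in sets.items()
                       for i, v in enumerate(vals)]
            for mode, fn in (("max", max), ("avg", lambda v: sum(v) / len(v))):
                expected = sorted(
                    cands, key=lambda c: (-fn(sets[c]),
                                          parse_stoichiometry(c).total_copies, c))
                got = rank_candidates(aggregate(records, mode)).candidates
                assert [str(s) for s in got] == expected

    def test_avg_mode_flags_small_model_samples(self):
        records = [rec("A2", f"m{i}", 0.8) for i in range(2)] + \
            [rec("A3", f"m{i}", 0.7) for i in range(6)]
        ranking = rank_candidates(aggregate(records, "avg"), mode="avg")
        assert ranking.low_model_count == [parse_stoichiometry("A2")]
        assert not rank_candidates(aggregate(records, "max")).low_model_count

    def test_no_scored_candidates_errors(self):
        with pytest.raises(ValueError):
            rank_candidates({})

    def test_top_k_truncation(self, h0208_scores):
        ranking = rank_candidates(aggregate(h0208_scores, "max"), "H0208")
        assert [str(s) for s in top_k(ranking, 1)] == ["A1B1"]
        two_cand = rank_candidates(aggregate(
            [rec("A2", "m0", 0.8), rec("A3", "m0", 0.7)], "max"))
        assert len(top_k(two_cand, 3)) == 2
        with pytest.raises(ValueError):
            top_k(ranking, 0)
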