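import pytest

from prestoi import ModelScoreRecord, load_casp16_table, parse_stoichiometry


@pytest.fixture(scope="session")
def casp16_records():
    return load_casp16_table()


def make_scores(target_id, candidate_max, n_models=5, spread=0.05):
    """Score records whose per-candidate AF-max equals the given values.

    Each candidate gets ``n_models`` records: one at its prescribed
    maximum and the rest stepped ``spread`` below it, so AF-max is exact
    and AF-avg stays strictly smaller.
    """
    records = []
    for cand_str, peak in candidate_max.items():
        cand = parse_stoichiometry(cand_str)
        for m in range(n_models):
            records.append(ModelScoreRecord(
                target_id=target_id, candidate=cand, model_id=f"m{m}",
                ranking_score=round(peak - (m * spread) / n_models, 6),
            ))
    return records


@pytest.fixture
def h0208_scores():
    """Nine-candidate score set for the hetero-dimer/tetramer ambiguity
    case: the true A1B1 peaks at 0.96, the tetramer A2B2 at 0.89."""
    peaks = {"A1B1": 0.96, "A2B2": 0.89, "A1B2": 0.80, "A2B1": 0.78,
             "A1B3": 0.70, "A3B1": 0.69, "A2B3": 0.66, "A3B2": 0.65,
             "A3B3": 0.60}
    return make_scores("H0208", peaks)


@pytest.fixture
def t0234o_scores():
    """Homo-multimer ranking where the trimer A3 peaks at 0.82."""
    peaks = {"A2": 0.74, "A3": 0.82, "A4": 0.71, "A5": 0.65,
             "A6": 0.77, "A7": 0.60, "A8": 0.58, "A9": 0.55}
    return make_scores("T0234o", peaks)


@pytest.fixture
def t0235o_scores():
    """Homo-multimer ranking where the hexamer A6 peaks at 0.88."""
    peaks = {"A2": 0.70, "A3": 0.76, "A4": 0.74, "A5": 0.80,
             "A6": 0.88, "A7": 0.72, "A8": 0.66, "A9": 0.62}
    return make_scores("T0235o", peaks)
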