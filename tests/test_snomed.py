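"""SNOMED CT loading, keyword filtering, reranking and attribution."""

import re

import numpy as np
import pandas as pd
import pytest

import phqscreen as pq
from phqscreen.embedding import embed, preprocess
from phqscreen.snomed import ATTRIBUTION_MESSAGE, diagnosis_keywords


def make_table(terms, tmp_path, actives=None, name="mini.tsv"):
    actives = actives or ["1"] * len(terms)
    lines = ["id\teffectiveTime\tactive\tmoduleId\tconceptId\tlanguageCode\ttypeId\tterm\tcaseSignificanceId"]
    for i, (term, active) in enumerate(zip(terms, actives)):
        lines.append(
            f"d{i}\t20240101\t{active}\t900000000000207008\t{1000 + i}\ten\t"
            f"900000000000013009\t{term}\t900000000000448009"
        )
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return pq.load_snomed(p)


# --- loading ----------------------------------------------------------------

def test_inactive_rows_are_dropped(tmp_path):
    table = make_table([f"term {i}" for i in range(10)], tmp_path,
                       actives=["1"] * 9 + ["0"])
    assert len(table) == 9


def test_header_only_file_loads_empty(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("conceptId\tterm\n", encoding="utf-8")
    assert len(pq.load_snomed(p)) == 0


def test_minimal_two_column_dialect_is_accepted(tmp_path):
    p = tmp_path / "two.tsv"
    p.write_text("conceptId\tterm\n366979004\tDepressed mood (finding)\n", encoding="utf-8")
    table = pq.load_snomed(p)
    assert table.iloc[0]["conceptId"] == "366979004"
    assert table.iloc[0]["term"] == "Depressed mood (finding)"


def test_missing_required_columns_named_in_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("id\tname\nx\ty\n", encoding="utf-8")
    with pytest.raises(pq.ValidationError, match="conceptId"):
        pq.load_snomed(p)


# --- keyword filtering ------------------------------------------------------

def test_keyword_filter_retains_any_keyword_hit(tmp_path, embedder, stopwords):
    table = make_table(
        ["Moderate major depression", "Severe depression", "Fracture of femur"],
        tmp_path,
    )
    hits = pq.keyword_filter("moderate depression", table, stopwords)
    assert list(hits["term"]) == ["Moderate major depression", "Severe depression"]


def test_keyword_filter_is_case_insensitive(tmp_path, stopwords):
    table = make_table(["Major depression"], tmp_path)
    assert len(pq.keyword_filter("DEPRESSION", table, stopwords)) == 1


def test_unknown_keyword_matches_nothing(snomed_table, stopwords):
    assert len(pq.keyword_filter("xyzzy", snomed_table, stopwords)) == 0


def test_word_boundaries_prevent_substring_keyword_hits(tmp_path, stopwords):
    table = make_table(["Major depression", "Pressing pain"], tmp_path)
    hits = pq.keyword_filter("press", table, stopwords)
    assert len(hits) == 0


def test_all_stopword_diagnosis_is_rejected(snomed_table, stopwords):
    with pytest.raises(pq.ValidationError, match="no usable keywords"):
        pq.keyword_filter("of the", snomed_table, stopwords)


# --- ranking ----------------------------------------------------------------

def test_identical_term_ranks_first_with_similarity_one(tmp_path, embedder, stopwords):
    table = make_table(["Severe depression", "moderate depression"], tmp_path)
    ranked = pq.rank_candidates("moderate depression", table, embedder, stopwords)
    assert ranked[0][0]["term"] == "moderate depression"
    assert ranked[0][1] == pytest.approx(1.0, abs=1e-9)


def test_singleton_candidate_is_rank_one(tmp_path, embedder, stopwords):
    table = make_table(["Fracture of femur"], tmp_path)
    ranked = pq.rank_candidates("depression", table, embedder, stopwords)
    assert len(ranked) == 1


def test_shared_tokens_dominate_ranking(tmp_path, embedder, stopwords):
    table = make_table(["Moderate major depression", "Severe depression"], tmp_path)
    ranked = pq.rank_candidates("moderate depression", table, embedder, stopwords)
    assert ranked[0][0]["term"] == "Moderate major depression"


def test_similarity_ties_break_by_shorter_term_then_conceptid(embedder, stopwords, tmp_path):
    # identical token content -> identical embeddings; shorter term wins
    table = make_table(["depressed  mood", "depressed mood"], tmp_path)
    ranked = pq.rank_candidates("depressed mood", table, embedder, stopwords)
    assert ranked[0][0]["term"] == "depressed mood"


def test_rank_requires_candidates(snomed_table, embedder, stopwords):
    with pytest.raises(pq.ValidationError):
        pq.rank_candidates("depression", snomed_table.iloc[0:0], embedder, stopwords)


# --- attribution ------------------------------------------------------------

def test_exact_term_query_returns_cited_concept(snomed_table, embedder, stopwords):
    m = pq.attribute("Depressed mood (finding)", snomed_table, embedder, stopwords)
    assert m.conceptId == "366979004"
    assert m.similarity == pytest.approx(1.0, abs=1e-9)


def test_moderate_depression_maps_to_cited_concept(snomed_table, embedder, stopwords):
    m = pq.attribute("moderate depression", snomed_table, embedder, stopwords)
    assert m.conceptId == "370143000"
    assert m.term == "Moderate major depression"


def test_major_depression_maps_to_its_term(snomed_table, embedder, stopwords):
    m = pq.attribute("major depression", snomed_table, embedder, stopwords)
    assert m.term == "Major depression"


def test_unmatchable_diagnosis_yields_nomatch(snomed_table, embedder, stopwords):
    result = pq.attribute("qqq", snomed_table, embedder, stopwords)
    assert isinstance(result, pq.NoMatch)
    assert result.to_record()["ConceptId"] is None


def test_match_record_carries_table_fields_and_message(snomed_table, embedder, stopwords):
    record = pq.attribute("major depression", snomed_table, embedder, stopwords).to_record()
    assert record["ModuleId"] == "900000000000207008"
    assert record["LanguageCode"] == "en"
    assert record["Message"] == ATTRIBUTION_MESSAGE
    assert isinstance(record["Similarity score"], float)


def test_adding_a_non_matching_row_never_changes_the_result(
    snomed_table, embedder, stopwords, tmp_path
):
    before = pq.attribute("moderate depression", snomed_table, embedder, stopwords)
    extra = pd.DataFrame([{c: "0" for c in snomed_table.columns}
                          | {"conceptId": "999", "term": "Gout"}])
    bigger = pd.concat([snomed_table, extra], ignore_index=True)
    after = pq.attribute("moderate depression", bigger, embedder, stopwords)
    assert (before.conceptId, before.similarity) == (after.conceptId, after.similarity)


def test_clinician_override_takes_precedence(snomed_table, embedder, stopwords):
    m = pq.attribute("moderate depression", snomed_table, embedder, stopwords,
                     overrides={"moderate depression": "366979004"})
    assert m.conceptId == "366979004"


def test_feedback_log_appends_jsonl(tmp_path):
    from phqscreen.snomed import log_feedback
    p = tmp_path / "feedback.jsonl"
    log_feedback(p, {"diagnosis": "x", "conceptId": "1"})
    log_feedback(p, {"diagnosis": "y", "conceptId": "2"})
    assert len(p.read_text().strip().splitlines()) == 2


# --- brute-force oracle equivalence ----------------------------------------

def oracle_attribute(diagnosis, table, embedder, stopwords):
    """Score every keyword-matching row; max by (sim, -len(term), -conceptId)."""
    keywords = diagnosis_keywords(diagnosis, stopwords)
    q = embed(preprocess(diagnosis, stopwords), embedder)
    best = None
    for _, row in table.iterrows():
        tokens = set(t for t in re.split(r"[^0-9a-z]+", row["term"].lower()) if t)
        if not any(kw in tokens for kw in keywords):
            continue
        v = embed(preprocess(row["term"], stopwords), embedder)
        sim = float(np.dot(q, v))
        # larger key wins: higher sim, shorter term, lexicographically smaller id
        key = (sim, -len(row["term"]),
               tuple(-ord(c) for c in row["conceptId"]) + (1,))
        if best is None or key > best[0]:
            best = (key, row["conceptId"])
    return None if best is None else best[1]


WORD_POOL = ["depression", "anxiety", "moderate", "severe", "mild", "major",
             "mood", "sleep", "pain", "disorder", "chronic", "acute", "episode",
             "recurrent", "fracture", "fatigue", "panic"]


def test_attribute_agrees_with_bruteforce_oracle(tmp_path, embedder, stopwords):
    rng = np.random.default_rng(42)
    terms = [
        " ".join(rng.choice(WORD_POOL, size=rng.integers(1, 4), replace=False)).capitalize()
        for _ in range(200)
    ]
    table = make_table(terms, tmp_path, name="random.tsv")
    for i in range(30):
        diagnosis = " ".join(rng.choice(WORD_POOL, size=rng.integers(1, 3), replace=False))
        expected = oracle_attribute(diagnosis, table, embedder, stopwords)
        got = pq.attribute(diagnosis, table, embedder, stopwords)
        if expected is None:
            assert isinstance(got, pq.NoMatch)
        else:
            assert got.conceptId == expected, diagnosis
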