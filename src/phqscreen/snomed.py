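"""SNOMED CT concept attribution: keyword filtering then cosine-similarity reranking.

A free-text diagnosis label (e.g. "moderate depression") is mapped to its
closest SNOMED CT concept in two stages: (1) candidate generation — the
diagnosis is split into content keywords and a word-boundary-anchored,
case-insensitive regex retains every description row whose term contains any
keyword; (2) reranking — the diagnosis and each candidate term are embedded
and candidates are ordered by cosine similarity.  The description table is an
RF2-style tab-separated file read locally, never via a network API.  An
optional clinician-overrides map is consulted before matching, and clinician
feedback can be appended to a JSONL log.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import embed, preprocess
from .errors import ValidationError

#: Fixed explanatory message attached to every system-generated attribution.
ATTRIBUTION_MESSAGE = (
    "This is system-generated diagnosis. More information can be found in the "
    "following link: https://www.snomed.org/get-snomed"
)

_RF2_COLUMNS = (
    "id", "effectiveTime", "active", "moduleId", "conceptId",
    "languageCode", "typeId", "term", "caseSignificanceId",
)


@dataclass
class SnomedMatch:
    """Attribution record: concept metadata + similarity + explanatory message."""

    conceptId: str
    term: str
    moduleId: str = ""
    languageCode: str = ""
    typeId: str = ""
    caseSignificanceId: str = ""
    similarity: float = 0.0
    message: str = ATTRIBUTION_MESSAGE

    def to_record(self) -> dict:
        """Rendered record with field names mirroring the RF2 description table."""
        return {
            "ModuleId": self.moduleId,
            "ConceptId": self.conceptId,
            "LanguageCode": self.languageCode,
            "TypeId": self.typeId,
            "CaseSignificanceId": self.caseSignificanceId,
            "Snomed_concept": self.term,
            "Similarity score": round(self.similarity, 2),
            "Message": self.message,
        }


@dataclass
class NoMatch:
    """Distinct no-match result (not an error): no keyword hit any term."""

    diagnosis: str
    reason: str = "no SNOMED term matched any diagnosis keyword"

    def to_record(self) -> dict:
        return {"ConceptId": None, "Snomed_concept": None, "Message": self.reason}


def load_snomed(path: str | Path) -> pd.DataFrame:
    """Load an RF2-style description table (TSV; at least conceptId and term).

    When an ``active`` column exists only active ('1') rows are retained.
    Terms are kept verbatim; matching lowercases on the fly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SNOMED description file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"conceptId", "term"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"SNOMED description file missing required columns: {sorted(missing)}"
        )
    if "active" in df.columns:
        df = df[df["active"] == "1"].reset_index(drop=True)
    bad = df[(df["conceptId"].str.fullmatch(r"\d+") != True) | (df["term"] == "")]  # noqa: E712
    if len(bad):
        raise ValidationError(
            f"rows with empty term or non-numeric conceptId: {bad.index.tolist()}"
        )
    return df


def diagnosis_keywords(diagnosis: str, stopwords=None) -> list[str]:
    """Lowercased content keywords of a diagnosis string (stop words removed)."""
    seq = preprocess(diagnosis, stopwords, cap=None)
    return list(seq.tokens)


def keyword_filter(
    diagnosis: str, table: pd.DataFrame, stopwords=None
) -> pd.DataFrame:
    """Rows whose term contains any diagnosis keyword (word-bounded, case-insensitive)."""
    keywords = diagnosis_keywords(diagnosis, stopwords)
    if not keywords:
        raise ValidationError(
            f"diagnosis {diagnosis!r} yields no usable keywords after stop-word removal"
        )
    pattern = re.compile(
        r"(?<![0-9A-Za-z])(?:" + "|".join(map(re.escape, keywords)) + r")(?![0-9A-Za-z])",
        re.IGNORECASE,
    )
    mask = table["term"].map(lambda t: bool(pattern.search(t)))
    return table[mask]


def rank_candidates(
    diagnosis: str, candidates: pd.DataFrame, embedder, stopwords=None
) -> list[tuple[pd.Series, float]]:
    """Order candidate rows by cosine similarity to the diagnosis, descending.

    Ties broken by shorter term, then lexicographically smaller conceptId —
    deterministic across platforms.
    """
    if len(candidates) == 0:
        raise ValidationError("rank_candidates requires at least one candidate")
    q = embed(preprocess(diagnosis, stopwords), embedder)
    scored = []
    for _, row in candidates.iterrows():
        v = embed(preprocess(row["term"], stopwords), embedder)
        sim = float(np.dot(q, v))  # both vectors are unit-norm (or zero)
        scored.append((row, sim))
    scored.sort(key=lambda rs: (-rs[1], len(rs[0]["term"]), rs[0]["conceptId"]))
    return scored


def load_overrides(path: str | Path) -> dict[str, str]:
    """Clinician overrides: JSON map of diagnosis string -> conceptId."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return {str(k).strip().lower(): str(v) for k, v in raw.items()}


def log_feedback(path: str | Path, record: dict) -> None:
    """Append one clinician-feedback record to a JSONL log."""
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def _row_to_match(row: pd.Series, similarity: float) -> SnomedMatch:
    return SnomedMatch(
        conceptId=row["conceptId"],
        term=row["term"],
        moduleId=row.get("moduleId", ""),
        languageCode=row.get("languageCode", ""),
        typeId=row.get("typeId", ""),
        caseSignificanceId=row.get("caseSignificanceId", ""),
        similarity=similarity,
    )


def attribute(
    diagnosis: str,
    table: pd.DataFrame,
    embedder,
    stopwords=None,
    overrides: dict[str, str] | None = None,
) -> SnomedMatch | NoMatch:
    """Map a diagnosis string to its closest SNOMED CT concept.

    Clinician overrides (diagnosis -> conceptId) take precedence over matching.
    Returns a NoMatch when no keyword hits any term.
    """
    if overrides:
        forced = overrides.get(diagnosis.strip().lower())
        if forced is not None:
            rows = table[table["conceptId"] == forced]
            if len(rows) == 0:
                raise ValidationError(
                    f"override conceptId {forced} not present in the SNOMED table"
                )
            row = rows.iloc[0]
            q = embed(preprocess(diagnosis, stopwords), embedder)
            v = embed(preprocess(row["term"], stopwords), embedder)
            return _row_to_match(row, float(np.dot(q, v)))
    candidates = keyword_filter(diagnosis, table, stopwords)
    if len(candidates) == 0:
        return NoMatch(diagnosis)
    ranked = rank_candidates(diagnosis, candidates, embedder, stopwords)
    row, sim = ranked[0]
    return _row_to_match(row, sim)
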