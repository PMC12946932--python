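"""Deterministic clinician-readable explanations and explanation-quality metrics.

Explanations are produced by fixed templates — a pure function of the
checklist, assessment and SNOMED attribution — so identical inputs yield
byte-identical reports; no sampling and no external model are involved.  An
external language model can be plugged in through ``narrative_hook`` but is
never part of the default path.  The module also implements the three
explanation-quality scores: cosine similarity, semantic similarity between two
texts, and a context-relevance score defined as content-token overlap between
the input and the explanation normalized by the input's content-token count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .classifier import Checklist
from .embedding import embed, preprocess
from .errors import ValidationError
from .ontology import ITEMS
from .scoring import SeverityAssessment, item_score
from .snomed import NoMatch, SnomedMatch

#: PHQ-9 response-scale wording per frequency value.
FREQUENCY_PHRASES = {
    0: "not at all",
    1: "several days",
    2: "more than half the days",
    3: "nearly every day",
}


@dataclass
class ExplanationReport:
    per_item: dict[str, str]
    narrative: str
    highlighted_terms: list[tuple[str, str, tuple[int, int]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_item": dict(self.per_item),
            "narrative": self.narrative,
            "highlighted_terms": [
                [item, term, [span[0], span[1]]]
                for item, term, span in self.highlighted_terms
            ],
        }

    def render_text(self) -> str:
        lines = [self.narrative, ""]
        for k in ITEMS:
            if k in self.per_item:
                lines.append(self.per_item[k])
        return "\n".join(lines)


def explain(
    checklist: Checklist,
    assessment: SeverityAssessment,
    match: SnomedMatch | NoMatch | None,
    narrative_hook: Callable[[str], str] | None = None,
) -> ExplanationReport:
    """Build the explanation report linking checklist items, cues, severity and concept.

    Raises ValidationError when the assessment is not derivable from the
    checklist (defence against mismatched inputs).  ``narrative_hook``, when
    given, may post-process the template narrative (e.g. an external language
    model); the default path is fully deterministic.
    """
    recomputed = {k: item_score(checklist.answers[k], checklist.cues[k]) for k in ITEMS}
    if recomputed != assessment.item_scores:
        raise ValidationError(
            "assessment item scores are not derivable from the checklist"
        )

    per_item: dict[str, str] = {}
    highlighted: list[tuple[str, str, tuple[int, int]]] = []
    for k in ITEMS:
        if checklist.answers[k] != "yes":
            continue
        cues = checklist.cues[k]
        conf = checklist.confidences[k]
        freq_phrase = FREQUENCY_PHRASES[assessment.item_scores[k]]
        if cues:
            terms = ", ".join(f"'{c.term}'" for c in cues)
            per_item[k] = (
                f"{k} marked present: detected {terms} [{freq_phrase}]; "
                f"confidence {conf:.2f}"
            )
            for c in cues:
                highlighted.append((k, c.term, (c.start, c.end)))
        else:
            per_item[k] = (
                f"{k} marked present: classifier confidence {conf:.2f} "
                f"[{freq_phrase}]"
            )

    elevated = [k for k in ITEMS if assessment.item_scores[k] > 0]
    parts = [
        f"PHQ-9 total score {assessment.total_score} — {assessment.diagnosis_label}."
    ]
    if elevated:
        parts.append("Elevated items: " + ", ".join(elevated) + ".")
    else:
        parts.append("No PHQ-9 symptoms detected.")
    if isinstance(match, SnomedMatch):
        parts.append(
            f"SNOMED CT attribution: {match.term} (conceptId {match.conceptId}, "
            f"similarity {match.similarity:.2f})."
        )
    else:
        parts.append("No SNOMED CT attribution available.")
    narrative = " ".join(parts)
    if narrative_hook is not None:
        narrative = narrative_hook(narrative)
    return ExplanationReport(per_item, narrative, highlighted)


def cosine_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """cos(A, B) = A.B / (||A|| ||B||); defined as 0 when either norm is 0."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise ValidationError(f"dimension mismatch: {A.shape} vs {B.shape}")
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(A, B) / (na * nb))


def semantic_similarity(text1: str, text2: str, embedder, stopwords=None) -> float:
    """Cosine similarity between the mean-pooled embeddings of two texts."""
    a = embed(preprocess(text1, stopwords), embedder)
    b = embed(preprocess(text2, stopwords), embedder)
    return cosine_similarity(a, b)


def context_relevance(input_text: str, explanation: str, stopwords=None) -> float:
    """Content-token overlap of explanation with input, over input's token count.

    Reads the relevance ratio as |tokens(explanation) ∩ tokens(input)| /
    |tokens(input)| on stop-word-free token sets; an input with no content
    tokens scores 0.  Always lands in [0, 1].
    """
    inp = set(preprocess(input_text, stopwords, cap=None).tokens)
    if not inp:
        return 0.0
    exp = set(preprocess(explanation, stopwords, cap=None).tokens)
    return len(inp & exp) / len(inp)
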