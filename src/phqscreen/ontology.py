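"""PHQ-9 symptom ontology: loading, validation, and cue matching in free text.

The ontology is a lexicon mapping surface phrases (``"loss of interest"``) to the
nine PHQ-9 items S1..S9, each with an integer frequency weight on the PHQ-9
response scale (0 = not at all .. 3 = nearly every day).  Cue matching is exact
phrase matching on normalized text: deterministic, auditable, and checkable
against a brute-force oracle.  Semantic expansion of the lexicon is assumed to
have happened when the ontology file was built, not at match time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import ValidationError

#: The nine PHQ-9 item identifiers, in questionnaire order.
ITEMS: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 10))

#: Temporal frequency modifiers (PHQ-9 response options) and their scale value.
FREQUENCY_MODIFIERS: dict[str, int] = {
    "nearly every day": 3,
    "more than half the days": 2,
    "several days": 1,
}

_SENTENCE_TERMINATORS = ".!?"
# every non-alphanumeric character except sentence terminators maps to a space
_PUNCT_RE = re.compile(r"[^\w\s.!?]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")
_SENT_RE = re.compile(r"[^.!?]+")


def normalize(text: str) -> str:
    """Normalize text for matching: lowercase, strip punctuation, collapse spaces.

    Sentence-terminating punctuation (``. ! ?``) is preserved so that sentence
    boundaries — which scope the temporal frequency modifiers — survive
    normalization, making :func:`match_cues` idempotent under it.
    """
    text = text.lower()
    text = _PUNCT_RE.sub(" ", text)
    text = _WS_RE.sub(" ", text).strip()
    # detach trailing spaces before terminators introduced by stripping, e.g. "day ."
    text = re.sub(r"\s+([.!?])", r"\1", text)
    return text


@dataclass(frozen=True)
class OntologyEntry:
    item_id: str
    term: str
    frequency_weight: int


@dataclass(frozen=True)
class CueMatch:
    """An occurrence of an ontology term in normalized text.

    ``char_span`` is a 0-based half-open ``[start, end)`` offset pair into the
    normalized text.  ``frequency_cue`` is the entry's weight, upgraded by any
    temporal modifier found in the same sentence.
    """

    item_id: str
    term: str
    start: int
    end: int
    frequency_cue: int

    @property
    def char_span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SymptomOntology:
    """Validated lexicon of (item, term, frequency_weight) entries."""

    entries: list[OntologyEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        terms_to_items: dict[str, set[str]] = {}
        for e in self.entries:
            if e.item_id not in ITEMS:
                raise ValidationError(f"unknown PHQ-9 item {e.item_id!r}")
            if not e.term or e.term != normalize(e.term):
                raise ValidationError(
                    f"term {e.term!r} is not normalized (lowercase, single-spaced)"
                )
            if e.frequency_weight not in (0, 1, 2, 3):
                raise ValidationError(
                    f"frequency_weight {e.frequency_weight} for {e.term!r} outside 0..3"
                )
            key = (e.item_id, e.term)
            if key in seen:
                raise ValidationError(f"duplicate ontology entry {key}")
            seen.add(key)
            terms_to_items.setdefault(e.term, set()).add(e.item_id)
        for term, items in terms_to_items.items():
            if len(items) > 1:
                warnings.warn(
                    f"ontology term {term!r} maps to multiple items {sorted(items)}",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[OntologyEntry]:
        return iter(self.entries)

    def items_covered(self) -> set[str]:
        return {e.item_id for e in self.entries}

    def terms_for(self, item_id: str) -> list[str]:
        return [e.term for e in self.entries if e.item_id == item_id]


def _coerce_item(raw: object, row: int) -> str:
    label = str(raw).strip().upper()
    if label in ITEMS:
        return label
    if label.isdigit() and 1 <= int(label) <= 9:
        return f"S{int(label)}"
    raise ValidationError(f"row {row}: unknown PHQ-9 item label {raw!r}")


def load_ontology(path: str | Path) -> SymptomOntology:
    """Load a symptom ontology from a CSV with columns item,term[,frequency_weight].

    ``item`` accepts ``S1``..``S9`` or bare integers 1-9.  Terms are lowercased
    and whitespace-normalized on load; a missing frequency_weight defaults to 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ontology file not found: {path}")
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = {"item", "term"} - set(df.columns)
    if missing:
        raise ValidationError(f"ontology CSV missing columns: {sorted(missing)}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        item = _coerce_item(getattr(row, "item"), i)
        raw_term = getattr(row, "term")
        if raw_term is None or pd.isna(raw_term):
            raise ValidationError(f"row {i}: empty term")
        term = normalize(str(raw_term)).strip(_SENTENCE_TERMINATORS).strip()
        if not term:
            raise ValidationError(f"row {i}: empty term")
        raw_w = getattr(row, "frequency_weight", None)
        if raw_w is None or (isinstance(raw_w, float) and pd.isna(raw_w)) or pd.isna(raw_w):
            weight = 1
        else:
            try:
                weight = int(str(raw_w).strip())
            except ValueError:
                raise ValidationError(f"row {i}: bad frequency_weight {raw_w!r}") from None
        entries.append(OntologyEntry(item, term, weight))
    return SymptomOntology(entries)


def default_ontology() -> SymptomOntology:
    """The packaged fixture ontology (3 terms per PHQ-9 item)."""
    with resources.as_file(
        resources.files("phqscreen.data").joinpath("phq9_ontology.csv")
    ) as p:
        return load_ontology(p)


def _term_occurrences(sentence: str, term: str) -> Iterable[int]:
    """Word-boundary-anchored start offsets of ``term`` within ``sentence``."""
    pattern = re.compile(
        r"(?<![0-9a-z])" + re.escape(term) + r"(?![0-9a-z])"
    )
    for m in pattern.finditer(sentence):
        yield m.start()


def _sentence_modifier(sentence: str) -> int:
    """Highest-valued temporal modifier present in the sentence, else 0."""
    best = 0
    for phrase, value in FREQUENCY_MODIFIERS.items():
        if phrase in sentence:
            best = max(best, value)
    return best


def match_cues(text: str, ontology: SymptomOntology) -> list[CueMatch]:
    """Find every non-overlapping longest-match ontology term in ``text``.

    The text is normalized first; matching scans left to right, longest match
    wins, ties broken by leftmost start then lexicographically smallest term.
    A term listed under several items yields one CueMatch per item at the same
    span.  Each match carries the entry's frequency weight, upgraded by the
    strongest temporal modifier in the same sentence.
    """
    norm = normalize(text)
    if not norm:
        return []
    out: list[CueMatch] = []
    for sent_m in _SENT_RE.finditer(norm):
        sentence = sent_m.group(0)
        offset = sent_m.start()
        modifier = _sentence_modifier(sentence)
        # gather all candidate occurrences of all terms in this sentence
        candidates: list[tuple[int, int, str, str, int]] = []
        for entry in ontology:
            for start in _term_occurrences(sentence, entry.term):
                candidates.append(
                    (start, start + len(entry.term), entry.term,
                     entry.item_id, entry.frequency_weight)
                )
        # longest match wins; ties by leftmost start, then smallest term
        candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2], c[3]))
        selected: list[tuple[int, int, str]] = []
        for start, end, term, item, weight in candidates:
            triple = (start, end, term)
            if triple not in selected:
                if any(start < e and s < end for s, e, _ in selected):
                    continue  # overlaps an already-selected (longer/earlier) match
                selected.append(triple)
            # a term listed under several items co-emits at the same span
            out.append(
                CueMatch(
                    item_id=item,
                    term=term,
                    start=offset + start,
                    end=offset + end,
                    frequency_cue=max(weight, modifier),
                )
            )
    out.sort(key=lambda m: (m.start, m.end, m.term, m.item_id))
    return out
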