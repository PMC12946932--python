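"""Synthetic annotated posts and a miniature SNOMED description table.

The generator emulates the schema of a public corpus of 2,000 Reddit posts with
binary yes/no annotations for the nine PHQ-9 items: each synthetic post plants
cue phrases drawn from the symptom ontology for its sampled positive items
(with optional temporal frequency modifiers) among neutral filler sentences
that are guaranteed free of ontology terms, so gold labels are exact by
construction.  It makes no attempt to mimic Reddit style, demographics or
annotator noise.  A companion writer produces a ~50-row RF2-style SNOMED
description table containing the clinically cited concepts plus distractors,
so the whole pipeline trains and tests offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .ontology import FREQUENCY_MODIFIERS, ITEMS, SymptomOntology

#: Sentence templates used to wrap a planted cue phrase.  Kept free of ontology
#: terms and modifier phrases (tests verify this against the packaged ontology).
CUE_TEMPLATES = (
    "lately i have been dealing with {}",
    "i keep running into {} these days",
    "my week has mostly been about {}",
    "honestly there has been a lot of {} for me",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults: up to 3 positive items per post (uniform over 0..3), a 0.9
    probability that a positive item plants a textual cue, a 0.5 probability
    that a planted cue carries a temporal modifier, and 1-3 filler sentences.
    """

    n_posts: int = 0
    seed: int = 0
    min_items_per_post: int = 0
    max_items_per_post: int = 3
    cue_rate: float = 0.9
    modifier_rate: float = 0.5
    filler_range: tuple[int, int] = (1, 3)
    force_items: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_posts < 0:
            raise ValidationError("n_posts must be >= 0")
        for name in ("cue_rate", "modifier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.min_items_per_post <= self.max_items_per_post <= 9:
            raise ValidationError(
                "need 0 <= min_items_per_post <= max_items_per_post <= 9"
            )


@dataclass
class SyntheticPost:
    """One generated post plus the generator's internal planting log."""

    text: str
    annotations: dict[str, str]
    planted: dict[str, str | None] = field(default_factory=dict)  # item -> cue term


def _filler_bank() -> list[str]:
    text = resources.files("phqscreen.data").joinpath("filler_sentences.txt").read_text(
        encoding="utf-8"
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def generate_posts(
    cfg: GeneratorConfig, ontology: SymptomOntology
) -> list[SyntheticPost]:
    """Generate annotated posts; identical cfg + seed give byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    fillers = _filler_bank()
    modifiers = sorted(FREQUENCY_MODIFIERS)  # deterministic order for sampling
    posts: list[SyntheticPost] = []
    for _ in range(cfg.n_posts):
        if cfg.force_items is not None:
            positives = list(cfg.force_items)
        else:
            k = int(rng.integers(cfg.min_items_per_post, cfg.max_items_per_post + 1))
            positives = sorted(rng.choice(ITEMS, size=k, replace=False)) if k else []
        sentences: list[str] = []
        planted: dict[str, str | None] = {}
        for item in positives:
            terms = ontology.terms_for(item)
            if not terms:
                raise ValidationError(
                    f"ontology has no terms for sampled item {item}"
                )
            if rng.random() < cfg.cue_rate:
                term = terms[int(rng.integers(0, len(terms)))]
                template = CUE_TEMPLATES[int(rng.integers(0, len(CUE_TEMPLATES)))]
                sentence = template.format(term)
                if rng.random() < cfg.modifier_rate:
                    sentence += " " + modifiers[int(rng.integers(0, len(modifiers)))]
                sentences.append(sentence)
                planted[item] = term
            else:
                planted[item] = None
        lo, hi = cfg.filler_range
        n_filler = int(rng.integers(lo, hi + 1))
        for _ in range(n_filler):
            sentences.append(fillers[int(rng.integers(0, len(fillers)))])
        order = rng.permutation(len(sentences))
        text = ". ".join(sentences[i] for i in order) + ("." if sentences else "")
        annotations = {k: ("yes" if k in positives else "no") for k in ITEMS}
        posts.append(SyntheticPost(text, annotations, planted))
    return posts


def posts_as_pairs(posts: list[SyntheticPost]) -> list[tuple[str, dict[str, str]]]:
    return [(p.text, p.annotations) for p in posts]


def write_posts_json(posts: list[SyntheticPost], path: str | Path) -> None:
    """Serialize posts in the pipeline's input schema (post_text + annotations)."""
    payload = [
        {"post_text": p.text, "annotations": p.annotations} for p in posts
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_posts_json(path: str | Path) -> list[tuple[str, dict[str, str]]]:
    """Read posts JSON: array of {"post_text": ..., "annotations": {...}} objects."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, list):
        raise ValidationError("posts JSON must be an array of objects")
    pairs = []
    for i, obj in enumerate(raw):
        if "post_text" not in obj:
            raise ValidationError(f"post {i} missing 'post_text'")
        pairs.append((str(obj["post_text"]), dict(obj.get("annotations", {}))))
    return pairs


# --- miniature SNOMED description table -----------------------------------

_MODULE = "900000000000207008"
_TYPE_SYN = "900000000000013009"
_TYPE_FSN = "900000000000003001"
_CASE = "900000000000448009"

#: (conceptId, term, active) rows for the fixture description table.  The two
#: clinically cited concepts — Depressed mood (finding) 366979004 and Moderate
#: major depression 370143000 — are included verbatim; the remainder are
#: depression/psychiatry neighbours and non-psychiatric distractors.  All ids
#: other than those two are synthetic placeholders.
FIXTURE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("366979004", "Depressed mood (finding)", "1"),
    ("370143000", "Moderate major depression", "1"),
    ("123456789", "Major depression", "1"),
    ("310495003", "Mild major depression", "1"),
    ("310497008", "Severe major depression", "1"),
    ("300706003", "Endogenous depression", "1"),
    ("301754002", "Reactive depression", "1"),
    ("320751009", "Major depression, recurrent episode", "1"),
    ("370145007", "Severe depression", "1"),
    ("832007005", "Masked depression", "1"),
    ("848324009", "Postpartum depression", "1"),
    ("191659001", "Atypical depressive disorder", "1"),
    ("191495003", "Depressive personality disorder", "1"),
    ("366979004", "Depressed mood", "1"),
    ("112080002", "Melancholia", "0"),
    ("192080009", "Depressive disorder NOS", "0"),
    ("197480006", "Anxiety disorder", "1"),
    ("218443309", "Generalized anxiety disorder", "1"),
    ("131941109", "Moderate anxiety", "1"),
    ("171341009", "Moderate pain", "1"),
    ("125605004", "Moderate asthma", "1"),
    ("230690007", "Severe asthma", "1"),
    ("134416001", "Mild anxiety", "1"),
    ("271737000", "Anemia", "1"),
    ("386661006", "Fever", "1"),
    ("271807003", "Skin rash", "1"),
    ("267036007", "Shortness of breath", "1"),
    ("267064002", "Sleep disorder", "1"),
    ("193462001", "Insomnia disorder", "1"),
    ("248274002", "Loss of appetite", "1"),
    ("271795006", "Malaise and fatigue", "1"),
    ("272022009", "Feeling irritable", "1"),
    ("247804008", "Poor concentration", "1"),
    ("102943000", "Chronic pain", "1"),
    ("71620000", "Fracture of femur", "1"),
    ("125666000", "Burn of skin", "1"),
    ("38341003", "Hypertensive disorder", "1"),
    ("44054006", "Diabetes mellitus type 2", "1"),
    ("195967001", "Asthma", "1"),
    ("37796009", "Migraine", "1"),
    ("82272006", "Common cold", "1"),
    ("74400008", "Appendicitis", "1"),
    ("61582004", "Allergic rhinitis", "1"),
    ("54150009", "Upper respiratory infection", "1"),
    ("49727002", "Cough", "1"),
    ("25064002", "Headache", "1"),
    ("62315008", "Diarrhea", "1"),
    ("422587007", "Nausea", "1"),
    ("271681002", "Stomach ache", "1"),
)


def generate_snomed_fixture(path: str | Path) -> Path:
    """Write the fixture RF2-style description table; returns the path."""
    path = Path(path)
    header = "\t".join(
        ("id", "effectiveTime", "active", "moduleId", "conceptId",
         "languageCode", "typeId", "term", "caseSignificanceId")
    )
    lines = [header]
    for i, (concept_id, term, active) in enumerate(FIXTURE_ROWS, start=1):
        type_id = _TYPE_FSN if term.endswith(")") else _TYPE_SYN
        lines.append(
            "\t".join(
                (f"d{i:06d}", "20240101", active, _MODULE, concept_id,
                 "en", type_id, term, _CASE)
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
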