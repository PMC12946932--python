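"""PHQ-9 severity scoring: item scores, total, severity band, diagnosis label.

Each PHQ-9 item is scored 0-3 by symptom frequency over the last two weeks
(0 = not at all, 3 = nearly every day); the total runs 0-27 and maps onto five
severity bands via the standard cut points: 0-4 minimal, 5-9 mild, 10-14
moderate, 15-19 moderately severe, 20-27 severe.  The checklist's annotations
are binary, so ordinal item scores come from the temporal frequency cues the
lexicon detects, defaulting to 1 (the lowest positive frequency) when a symptom
is present without a temporal modifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import Checklist
from .errors import ValidationError
from .ontology import ITEMS, CueMatch

#: Severity bands as closed integer intervals on the total score.
BANDS: tuple[tuple[int, int, str], ...] = (
    (0, 4, "minimal"),
    (5, 9, "mild"),
    (10, 14, "moderate"),
    (15, 19, "moderately severe"),
    (20, 27, "severe"),
)


@dataclass
class SeverityAssessment:
    item_scores: dict[str, int]
    total_score: int
    band: str
    diagnosis_label: str
    provenance: dict = field(default_factory=dict)


def item_score(answer: str, cues: list[CueMatch]) -> int:
    """Score a single item: "no" -> 0; "yes" -> max cue frequency, floored at 1."""
    if answer != "yes":
        return 0
    best = max((c.frequency_cue for c in cues), default=1)
    return max(1, best)


def band_for_total(total: int) -> str:
    for lo, hi, name in BANDS:
        if lo <= total <= hi:
            return name
    raise ValidationError(f"total score {total} outside 0..27")


def total_and_band(item_scores: dict[str, int]) -> SeverityAssessment:
    """Sum the nine item scores and map the total onto its severity band."""
    missing = set(ITEMS) - set(item_scores)
    if missing:
        raise ValidationError(f"item scores missing items: {sorted(missing)}")
    for k, s in item_scores.items():
        if s not in (0, 1, 2, 3):
            raise ValidationError(f"item {k} score {s} outside 0..3")
    total = sum(item_scores[k] for k in ITEMS)
    band = band_for_total(total)
    return SeverityAssessment(
        item_scores=dict(item_scores),
        total_score=total,
        band=band,
        diagnosis_label=f"{band} depression",
    )


def diagnose(checklist: Checklist) -> SeverityAssessment:
    """Score a complete checklist and attach per-item occurrence provenance."""
    scores = {k: item_score(checklist.answers[k], checklist.cues[k]) for k in ITEMS}
    assessment = total_and_band(scores)
    assessment.provenance = {
        "occurrence_counts": {
            k: checklist.emitted_counts.get(k, 0) + len(checklist.cues[k])
            for k in ITEMS
        },
        "cue_spans": {
            k: [[c.start, c.end] for c in checklist.cues[k]] for k in ITEMS
        },
        "elevated_items": [k for k in ITEMS if scores[k] > 0],
    }
    return assessment
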