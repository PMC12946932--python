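# Methods

## Pipeline model

`phqscreen` implements a staged screening pipeline: free text → PHQ-9 checklist
→ severity score and band → SNOMED CT attribution → deterministic explanation.
The stages are independent library functions composed by `phqscreen.assess`;
each stage's output is inspectable, and every "yes" decision carries its
provenance (classifier confidence, cue matches, or both).

### Cue matching (symptom ontology)

The ontology is a finished lexicon of (item, phrase, frequency-weight)
entries; matching is exact phrase match on normalized text. Normalization
lowercases, strips punctuation and collapses whitespace, but **retains the
sentence terminators `. ! ?`**: temporal frequency modifiers are scoped to the
sentence they occur in, so boundaries must survive normalization — this is
what makes `match_cues(normalize(t)) == match_cues(t)` hold. Overlap
resolution is maximal-munch: the longest candidate match wins globally, ties
broken by leftmost start, then lexicographically smallest term. A term listed
under two items co-emits one match per item at the same span (with a load-time
warning). Matching is deliberately free of stemming or embedding expansion:
semantic expansion is assumed to have happened when the lexicon was compiled,
keeping the matcher deterministic and testable against a brute-force
all-substrings oracle.

Temporal modifiers map to the PHQ-9 response scale — "nearly every day" → 3,
"more than half the days" → 2, "several days" → 1 — and *upgrade* the entry's
weight (`max(weight, modifier)`), never lower it.

### Embeddings

The default embedder is a deterministic feature-hashing embedder: each token
is framed as `^token$`, its character 3-grams are hashed (BLAKE2, fixed keys —
stable across platforms and runs) to signed buckets in a `d = 256` vector,
which is L2-normalized; a text embedding is the L2-normalized mean of its
token vectors (mean pooling). Preprocessing lowercases, strips punctuation,
removes stop words and truncates to 128 tokens; since mean pooling makes pad
tokens a no-op, "padding" to the 128-token contract is realized as truncation
only. The empty sequence maps to the zero vector, and cosine against a zero
vector is defined as 0.

The packaged stop-word list (~130 entries) contains function words only;
negations ("no", "not") and content-bearing words like "down" are deliberately
excluded so clinical signal survives. A sentence-transformer
(all-MiniLM-L6-v2, d = 384) can be selected via `embedder.name: minilm` when
the optional dependency is installed; it must satisfy the same contract. All
tests run against the reference embedder, which also serves the privacy goal:
no model download, no data leaving the machine.

### Checklist classifier

A two-layer network: input d → 128 ReLU → 9-way softmax, cross-entropy loss,
Adam (lr 0.001), 32 epochs. These four values are the published operating
point; batch size 16, He initialization and seeded shuffling are this
package's choices (the source is silent), and training is exactly reproducible
given the seed. Training pairs are (post embedding, item) — one pair per
positively annotated item, so multi-label posts contribute several pairs;
prediction is per sentence, and per-sentence argmax items are emitted only at
softmax probability ≥ τ = 0.55 (suppression is strictly below the threshold,
so p = 0.55 emits). There is no tenth "background" class: sub-threshold
suppression is the stated mechanism for non-symptom text.

Checklist assembly uses the union rule: item = yes iff (≥ 1 emitted
prediction) OR (≥ 1 cue match). The union is auditable — each yes records its
confidences and cue spans — and it degrades gracefully: a zero classifier
still yields correct lexicon-path answers.

### Severity scoring

Binary checklist answers are lifted to ordinal 0–3 item scores using the
detected frequency cues: no → 0; yes → max cue frequency, floored at 1 (the
most conservative positive score when no temporal modifier is present — the
only frequency signal available in free text is linguistic). The total (0–27)
maps to five bands via closed integer intervals [0,4], [5,9], [10,14],
[15,19], [20,27]; the diagnosis label is "<band> depression". No DSM-style
algorithmic diagnosis is attempted — the pipeline does not capture the
duration/functional-impairment criteria that would require.

### SNOMED CT attribution

The description table is an RF2-style TSV read locally (never via API); when
an `active` column is present only active rows are kept. Attribution is
candidate-generation-and-rerank: diagnosis → content keywords (stop words
removed; empty keyword sets are a validation error) → case-insensitive
word-boundary alternation over the `term` column (boundaries prevent "press"
matching "depression") → cosine rerank of the survivors. Ties break by
shorter term, then lexicographically smaller conceptId, so results are
deterministic across platforms. No keyword hit yields a `NoMatch` record,
distinct from an error. A clinician-overrides file (diagnosis → conceptId) is
consulted before matching, and feedback can be appended to a JSONL log;
fine-tuning from feedback is out of scope. Matching uses the primary term
column only — synonym/relationship traversal is not attempted.

### Explanations and their metrics

Explanations are fixed templates over the checklist, assessment and
attribution — a pure function, byte-identical across runs; an external
language model can be attached through `narrative_hook` but is never part of
the default path, which is also what keeps the layer hallucination-free and
testable. Every highlighted span indexes a real occurrence in the normalized
source text, and `explain` refuses an assessment that is not derivable from
its checklist.

Three explanation-quality scores are provided: cosine similarity
(A·B/‖A‖‖B‖), semantic similarity (cosine of two mean-pooled text
embeddings), and a context-relevance score. The relevance ratio's numerator
and denominator are fixed here as content-token set overlap normalized by the
input's content-token count — the simplest reading that is guaranteed to land
in [0, 1]; other readings are admissible, and this one is recorded as an
interpretation.

### Evaluation metrics

Every (post, item) pair contributes one confusion-matrix cell; accuracy,
precision, recall and F1 follow the standard formulas with zero-division
conventions returning 0, never NaN. The default single-number report is
micro-averaged (pooled over all 9×N decisions) because published
single-number tables for this task do not state their averaging convention;
macro and per-item views are always emitted alongside.

## Synthetic data generator

The generator emulates the schema of a 2,000-post public corpus of annotated
Reddit posts: each synthetic post samples 0–3 positive items (uniform), plants
an ontology cue phrase for each positive item with probability 0.9, attaches a
temporal modifier with probability 0.5, and mixes in 1–3 neutral filler
sentences drawn from a packaged bank that is verified (by test) to contain no
ontology term or modifier phrase — so gold labels are exact by construction.
All randomness flows through one named, explicitly seeded generator; identical
config + seed give byte-identical corpora.

What the generator does *not* emulate: Reddit linguistic style and topical
drift, annotator disagreement, paraphrased or implicit symptom expression,
negated symptoms, and label noise. Passing the synthetic recovery tests
therefore demonstrates that the pipeline's machinery is correct under its own
assumptions — not that real-corpus performance figures transfer. A positive
item without a planted cue (10% of positives) leaves no textual trace, which
caps attainable recall near 0.9 and keeps the recovery task honest.

The SNOMED fixture is a ~50-row description table containing the two
clinically cited concepts (Depressed mood (finding), 366979004; Moderate major
depression, 370143000) with their real identifiers, psychiatric neighbours and
non-psychiatric distractors under synthetic placeholder ids, and two inactive
rows to exercise the active filter.

## Numerical and design choices

- Reference-embedder dimension 256: large enough that 3-gram hash collisions
  are rare over the lexicon's vocabulary, small enough to train in seconds.
- Threshold boundary: emission at exactly τ (suppression is strictly below).
- Severity intervals are closed on integers; the five bands partition
  {0,…,27} exactly (tested exhaustively).
- Tie-breaks everywhere are total orders (term length, lexicographic ids,
  leftmost spans) so no result depends on dict/iteration order.
- Model files are `.npz` containers of little-endian float64 arrays plus
  JSON-encoded hyperparameters.
- Floats in the assessment document are rounded to 6 decimals and key order is
  fixed, making `assess` output byte-identical for identical inputs.
- Problem sizes in tests and examples — 500 training / 100 evaluation posts,
  5 seeds for recovery, 1,000-row random tables and 100 random queries for the
  attribution-oracle check — were chosen as the smallest sizes at which the
  checked properties are stable.

## Known limitations

- Exact-phrase cue matching misses paraphrase and misspelling; recall on real
  text depends entirely on lexicon coverage.
- Negation is not modelled ("I never feel down" would match "feel down"-type
  cues if such a phrase were in the lexicon; the packaged lexicon's phrases
  are chosen to make this unlikely, not impossible).
- Post-level training pairs with sentence-level prediction is a deliberate
  granularity mismatch; it works because cue phrases dominate both, but
  transformer embeddings of long multi-topic posts would dilute it.
- The severity score is a screening aid derived from linguistic frequency
  cues, not a clinical assessment; bands are reported with that caveat.
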