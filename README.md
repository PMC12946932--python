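# phqscreen

Depression screening support from free text. `phqscreen` turns a natural-language
account of someone's mental state into a structured, explainable assessment:

1. **PHQ-9 checklist generation** — each sentence is embedded (mean-pooled token
   vectors) and classified by a feedforward softmax network (128 ReLU hidden
   units, 9 outputs, one per PHQ-9 item S1–S9); predictions with softmax
   probability below the confidence threshold τ = 0.55 are suppressed. In
   parallel, a symptom-ontology lexicon detects cue phrases ("loss of
   interest" → S1). An item is marked *yes* iff the classifier emits it **or**
   a cue matches, so every *yes* carries its provenance.
2. **Severity scoring** — item scores on the 0–3 PHQ-9 frequency scale come
   from temporal modifier phrases ("nearly every day" → 3, "more than half the
   days" → 2, "several days" → 1; present without modifier → 1). The total
   T = Σᵢ sᵢ ∈ [0, 27] maps to a severity band by the standard cut points
   0–4 minimal, 5–9 mild, 10–14 moderate, 15–19 moderately severe, 20–27 severe.
3. **SNOMED CT attribution** — the diagnosis label (e.g. "moderate depression")
   is split into keywords; a word-boundary regex filters an RF2-style
   description table, and candidates are reranked by cosine similarity
   cos(A, B) = A·B/(‖A‖‖B‖) between diagnosis and term embeddings. The top
   concept (e.g. *Moderate major depression*, conceptId 370143000) is returned
   with its metadata and similarity score.
4. **Deterministic explanations** — fixed templates link each *yes* item to its
   highlighted cue spans, the severity band, and the attributed concept;
   identical inputs give byte-identical reports.
5. **Evaluation** — pooled (post, item) confusion matrices and
   accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
   recall = TP/(TP+FN), F1 = 2PR/(P+R), in micro/macro/per-item modes, plus
   cosine/semantic-similarity and context-relevance scores for explanations.

Everything runs locally and offline: the default embedder is a deterministic
feature-hashed character-3-gram embedder (a sentence-transformer can be plugged
in via config), and a synthetic-corpus generator emulates the annotated-post
schema (binary yes/no labels for S1–S9) so the pipeline trains and tests
without any external download. The package is aimed at clinical-NLP
researchers and tool builders; it is **not** a diagnostic device.

## Worked example

```bash
python examples/01_checklist_and_severity.py
```

```
input: lately i have been dealing with loss of interest nearly every day. i keep running into trouble sleeping more than half the days. the bus was late again this morning.
yes items: ['S1', 'S3']
item scores: {'S1': 3, 'S3': 2}
total: 5 | band: mild
narrative: PHQ-9 total score 5 — mild depression. Elevated items: S1, S3. SNOMED CT attribution: Mild major depression (conceptId 310495003, similarity 0.82).
```

"loss of interest" triggers S1 with frequency 3 (*nearly every day*), "trouble
sleeping" triggers S3 with frequency 2 (*more than half the days*); the total
5 lands in the mild band, and the diagnosis label is linked to its closest
SNOMED CT concept. `examples/02_snomed_linking.py` shows the attribution layer
alone (exact-term queries score similarity 1.0; unmatchable strings yield a
`NoMatch` record), and `examples/03_evaluation_metrics.py` trains on 500
synthetic posts and evaluates 100 fresh ones (micro-F1 ≈ 0.95 under the
default generator conditions).

## Command line

```bash
phqscreen simulate --n 500 --seed 7 --out posts.json
phqscreen train --posts posts.json --out model.npz --seed 7
phqscreen fixtures-snomed --out snomed.tsv
phqscreen assess --text-file input.txt --model model.npz --snomed snomed.tsv
phqscreen evaluate --posts posts.json --model model.npz
phqscreen link --diagnosis "moderate depression" --snomed snomed.tsv
```

Exit codes: 0 success, 2 validation error, 3 I/O error.

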