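"""Evaluate checklist generation against gold annotations.

Trains on 500 synthetic posts, generates checklists for 100 fresh posts, and
reports micro/macro accuracy, precision, recall and F1 from the pooled
(post, item) confusion matrix, plus the explanation-quality scores for one
input/explanation pair.
"""

import phqscreen as pq
from phqscreen.synthetic import GeneratorConfig, generate_posts, posts_as_pairs

ontology = pq.default_ontology()
embedder = pq.get_embedder("reference")

train_posts = generate_posts(GeneratorConfig(n_posts=500, seed=1), ontology)
test_posts = generate_posts(GeneratorConfig(n_posts=100, seed=2), ontology)
model = pq.train(posts_as_pairs(train_posts), embedder, pq.Hyperparams(seed=1))

predicted = [pq.generate_checklist(p.text, model, ontology, embedder)
             for p in test_posts]
report = pq.evaluate_checklists(predicted, [p.annotations for p in test_posts])

print("confusion:", report["confusion"])
print("micro:", {k: round(v, 3) for k, v in report["micro"].items() if k != "mode"})
print("macro:", {k: round(v, 3) for k, v in report["macro"].items() if k != "mode"})

text = "lately i have been dealing with feeling down nearly every day."
checklist = predicted[0]
sim = pq.semantic_similarity(text, "the patient reports feeling down nearly every day",
                             embedder)
crs = pq.context_relevance(text, "detected 'feeling down' [nearly every day]")
print(f"semantic similarity: {sim:.3f} | context relevance: {crs:.3f}")
# micro metrics pool all 9x100 yes/no decisions into one confusion matrix;
# the context-relevance score is the fraction of the input's content tokens
# that the explanation reuses.
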