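"""Feedforward softmax classifier assigning sentences to PHQ-9 items.

Architecture: input layer matching the embedding dimension, one fully connected
hidden layer of 128 ReLU units, and a 9-way softmax output — one class per
PHQ-9 item.  Trained with mini-batch Adam (lr 0.001) on cross-entropy loss for
32 epochs.  At inference a sentence's argmax item is emitted only when its
softmax probability reaches the confidence threshold tau = 0.55; strictly lower
probabilities are suppressed to limit false positives.  The final checklist is
the union of classifier-emitted items and lexicon cue matches, so every "yes"
carries its provenance (model confidence, matched cues, or both).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embedding import TokenSequence, embed, preprocess
from .errors import ConfigurationError, ValidationError
from .ontology import ITEMS, CueMatch, SymptomOntology, match_cues

#: Softmax confidence threshold below which predictions are suppressed.
CONFIDENCE_THRESHOLD = 0.55

_HIDDEN = 128
_N_CLASSES = 9


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters.

    Learning rate, epoch count, hidden width and the confidence threshold are
    the published operating point; batch size and initialization are this
    package's choices (see docs/methods.md).
    """

    learning_rate: float = 0.001
    epochs: int = 32
    batch_size: int = 16
    confidence_threshold: float = CONFIDENCE_THRESHOLD
    seed: int = 0
    hidden: int = _HIDDEN


@dataclass(frozen=True)
class ItemPrediction:
    item_id: str
    probability: float
    emitted: bool
    sentence: str = ""


@dataclass
class Checklist:
    """Binary PHQ-9 checklist with confidences and supporting cues per item."""

    answers: dict[str, str]                     # S1..S9 -> "yes" | "no"
    confidences: dict[str, float]               # max emitted probability, 0 if none
    cues: dict[str, list[CueMatch]]             # lexicon matches per item
    emitted_counts: dict[str, int] = field(default_factory=dict)

    def yes_items(self) -> list[str]:
        return [k for k in ITEMS if self.answers[k] == "yes"]


def is_emitted(probability: float, threshold: float = CONFIDENCE_THRESHOLD) -> bool:
    """Emission rule: suppression is strictly below the threshold, so p == tau emits."""
    return probability >= threshold


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def split_sentences(text: str) -> list[str]:
    """Split raw text into sentences on . ! ? (non-empty fragments)."""
    import re

    return [s.strip() for s in re.split(r"[.!?]+", text) if s.strip()]


@dataclass
class ClassifierModel:
    """Weights + hyperparameters of the trained 2-layer network."""

    W1: np.ndarray  # (d, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden, 9)
    b2: np.ndarray  # (9,)
    hyperparams: Hyperparams = field(default_factory=Hyperparams)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Softmax probabilities, shape (n, 9); accepts a single vector too."""
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.input_dim:
            raise ConfigurationError(
                f"embedding dim {X.shape[1]} does not match model input dim {self.input_dim}"
            )
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        P = softmax(H @ self.W2 + self.b2)
        return P[0] if single else P

    def save(self, path: str | Path) -> None:
        """Serialize to a single portable .npz file (float64 weights + JSON hyperparams)."""
        hp = json.dumps(self.hyperparams.__dict__)
        np.savez(
            path,
            W1=self.W1.astype("<f8"),
            b1=self.b1.astype("<f8"),
            W2=self.W2.astype("<f8"),
            b2=self.b2.astype("<f8"),
            hyperparams=np.frombuffer(hp.encode("utf-8"), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with np.load(path) as data:
            hp = json.loads(bytes(data["hyperparams"]).decode("utf-8"))
            return cls(
                W1=data["W1"], b1=data["b1"], W2=data["W2"], b2=data["b2"],
                hyperparams=Hyperparams(**hp),
            )


def _training_pairs(
    posts: list[tuple[str, dict[str, str]]], embedder, stopwords=None
) -> tuple[np.ndarray, np.ndarray]:
    """One (post embedding, item index) pair per positive annotation."""
    X, y = [], []
    for text, annotations in posts:
        positives = [k for k in ITEMS if str(annotations.get(k, "no")).lower() == "yes"]
        if not positives:
            continue
        vec = embed(preprocess(text, stopwords), embedder)
        for item in positives:
            X.append(vec)
            y.append(ITEMS.index(item))
    if not X:
        raise ValidationError("no positively annotated posts in training data")
    return np.stack(X), np.asarray(y, dtype=np.int64)


def train(
    posts: list[tuple[str, dict[str, str]]],
    embedder,
    hyperparams: Hyperparams | None = None,
    stopwords=None,
) -> ClassifierModel:
    """Train the checklist classifier on annotated posts.

    Each post contributes one training pair per positively annotated item
    (multi-label posts yield several pairs).  Mini-batch Adam on cross-entropy,
    He-initialized, shuffled with a seeded generator: training is reproducible
    given the seed.  Refuses single-class data with a diagnostic.
    """
    hp = hyperparams or Hyperparams()
    X, y = _training_pairs(posts, embedder, stopwords)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError(
            f"training data contains a single item class ({ITEMS[classes[0]]}); "
            "at least two distinct PHQ-9 items are required"
        )
    d = X.shape[1]
    if d != embedder.dim:
        raise ConfigurationError(
            f"embedding dim {d} does not match embedder dim {embedder.dim}"
        )
    rng = np.random.default_rng(hp.seed)
    # He initialization for the ReLU layer, scaled-normal for the softmax layer
    W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, hp.hidden))
    b1 = np.zeros(hp.hidden)
    W2 = rng.normal(0.0, np.sqrt(1.0 / hp.hidden), size=(hp.hidden, _N_CLASSES))
    b2 = np.zeros(_N_CLASSES)

    params = [W1, b1, W2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    Y = np.eye(_N_CLASSES)[y]

    for _ in range(hp.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = X[idx], Y[idx]
            # forward
            Z1 = xb @ W1 + b1
            H = np.maximum(Z1, 0.0)
            P = softmax(H @ W2 + b2)
            # backward (cross-entropy + softmax)
            dZ2 = (P - yb) / len(idx)
            grads = [None] * 4
            grads[2] = H.T @ dZ2
            grads[3] = dZ2.sum(axis=0)
            dH = dZ2 @ W2.T
            dZ1 = dH * (Z1 > 0)
            grads[0] = xb.T @ dZ1
            grads[1] = dZ1.sum(axis=0)
            # Adam update
            t += 1
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                p -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)

    return ClassifierModel(W1, b1, W2, b2, hp)


def predict_items(
    text: str, model: ClassifierModel, embedder, stopwords=None
) -> list[ItemPrediction]:
    """Per-sentence argmax predictions with threshold-based emission.

    Each sentence yields one ItemPrediction; ``emitted`` is true iff the argmax
    probability reaches the confidence threshold.
    """
    tau = model.hyperparams.confidence_threshold
    predictions = []
    for sentence in split_sentences(text):
        vec = embed(preprocess(sentence, stopwords), embedder)
        probs = model.forward(vec)
        k = int(np.argmax(probs))
        p = float(probs[k])
        predictions.append(
            ItemPrediction(ITEMS[k], p, is_emitted(p, tau), sentence=sentence)
        )
    return predictions


def generate_checklist(
    text: str,
    model: ClassifierModel,
    ontology: SymptomOntology,
    embedder,
    stopwords=None,
) -> Checklist:
    """Assemble the binary PHQ-9 checklist from classifier and lexicon signals.

    Union rule: an item is "yes" iff it has at least one emitted classifier
    prediction or at least one ontology cue match.  Confidence is the max
    emitted probability for the item (0 when the item is lexicon-only).
    """
    predictions = predict_items(text, model, embedder, stopwords)
    cues = match_cues(text, ontology)
    cues_by_item: dict[str, list[CueMatch]] = {k: [] for k in ITEMS}
    for c in cues:
        cues_by_item[c.item_id].append(c)
    answers, confidences, emitted_counts = {}, {}, {}
    for k in ITEMS:
        emitted = [p for p in predictions if p.item_id == k and p.emitted]
        yes = bool(emitted) or bool(cues_by_item[k])
        answers[k] = "yes" if yes else "no"
        confidences[k] = max((p.probability for p in emitted), default=0.0)
        emitted_counts[k] = len(emitted)
    return Checklist(answers, confidences, cues_by_item, emitted_counts)
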