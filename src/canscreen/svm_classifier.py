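"""Sentence-level CAN topic classifier: n-gram features + linear SVM.

Features are binary presence indicators for unigrams, bigrams and trigrams
over lowercased word tokens; the vocabulary is built from the training
partition only. The classifier is a linear-kernel support-vector machine
(libsvm backend via scikit-learn); decisions threshold the signed distance
to the separating hyperplane at 0.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.svm import SVC

from ._text import phrase_words

__all__ = [
    "NGramVocabulary",
    "SentenceDataset",
    "build_vocabulary",
    "vectorize",
    "SVMModel",
    "train",
    "predict",
    "decision_function",
    "save_model",
    "load_model",
    "stratified_split",
    "ClassReport",
    "per_class_report",
]


@dataclass(frozen=True)
class NGramVocabulary:
    """Ordered n-gram -> column mapping, built from training sentences only."""

    index: dict  # ngram string -> dense column index 0..V-1
    n_range: tuple[int, int] = (1, 3)
    built_from: str = ""

    def __len__(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class SentenceDataset:
    """Labeled sentences (CAN = 1, non-CAN = 0) with a partition tag."""

    sentences: tuple[str, ...]
    labels: tuple[int, ...]
    partition: str = ""

    def __post_init__(self) -> None:
        if len(self.sentences) != len(self.labels):
            raise ValueError("sentences and labels differ in length")
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.sentences)


def _ngrams(words: Sequence[str], n_range: tuple[int, int]):
    lo, hi = n_range
    for n in range(lo, hi + 1):
        for i in range(len(words) - n + 1):
            yield "_".join(words[i : i + n])


def build_vocabulary(
    train_sentences: Sequence[str],
    n_range: tuple[int, int] = (1, 3),
    min_count: int = 1,
    built_from: str = "train",
) -> NGramVocabulary:
    """First-occurrence-ordered n-gram vocabulary over lowercased tokens.

    ``min_count`` filters rare n-grams by corpus frequency; an empty
    resulting vocabulary is an error.
    """
    if not any(s.strip() for s in train_sentences):
        raise ValueError("cannot build a vocabulary from an empty corpus")
    order: list[str] = []
    counts: dict[str, int] = {}
    for sentence in train_sentences:
        for gram in _ngrams(phrase_words(sentence), n_range):
            if gram not in counts:
                counts[gram] = 0
                order.append(gram)
            counts[gram] += 1
    kept = [g for g in order if counts[g] >= min_count]
    if not kept:
        raise ValueError(f"vocabulary is empty at min_count={min_count}")
    return NGramVocabulary({g: i for i, g in enumerate(kept)}, n_range, built_from)


def vectorize(sentences: Sequence[str], vocab: NGramVocabulary) -> sp.csr_matrix:
    """Binary-presence sparse feature matrix; OOV n-grams are ignored."""
    indptr = [0]
    indices: list[int] = []
    for sentence in sentences:
        cols = {
            vocab.index[g]
            for g in _ngrams(phrase_words(sentence), vocab.n_range)
            if g in vocab.index
        }
        indices.extend(sorted(cols))
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.float64)
    return sp.csr_matrix(
        (data, np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
        shape=(len(sentences), len(vocab)),
    )


@dataclass
class SVMModel:
    """A trained linear SVM as a portable (vocabulary, weights, bias) bundle."""

    vocab: NGramVocabulary
    weights: np.ndarray
    bias: float
    C: float = 1.0


def train(dataset: SentenceDataset, vocab: NGramVocabulary, C: float = 1.0) -> SVMModel:
    """Fit a linear-kernel SVM (libsvm backend). Both classes must be present."""
    labels = np.asarray(dataset.labels)
    if len(set(dataset.labels)) < 2:
        raise ValueError("training set must contain both classes")
    X = vectorize(dataset.sentences, vocab)
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, labels)
    weights = np.asarray(clf.coef_.todense() if sp.issparse(clf.coef_) else clf.coef_).ravel()
    return SVMModel(vocab, weights, float(clf.intercept_[0]), C)


def decision_function(model: SVMModel, sentences: Sequence[str]) -> np.ndarray:
    X = vectorize(sentences, model.vocab)
    return np.asarray(X @ model.weights).ravel() + model.bias


def predict(model: SVMModel, sentences: Sequence[str]) -> np.ndarray:
    """Deterministic labels: 1 iff the decision value exceeds 0."""
    return (decision_function(model, sentences) > 0).astype(int)


def save_model(model: SVMModel, path: str | Path) -> None:
    ordered = sorted(model.vocab.index.items(), key=lambda kv: kv[1])
    bundle = {
        "vocabulary": [g for g, _ in ordered],
        "n_range": list(model.vocab.n_range),
        "built_from": model.vocab.built_from,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "C": model.C,
    }
    Path(path).write_text(json.dumps(bundle), encoding="utf-8")


def load_model(path: str | Path) -> SVMModel:
    bundle = json.loads(Path(path).read_text(encoding="utf-8"))
    vocab = NGramVocabulary(
        {g: i for i, g in enumerate(bundle["vocabulary"])},
        tuple(bundle["n_range"]),
        bundle.get("built_from", ""),
    )
    return SVMModel(vocab, np.asarray(bundle["weights"], dtype=float), float(bundle["bias"]), float(bundle["C"]))


def stratified_split(
    dataset: SentenceDataset, n_test: int, seed: int = 0
) -> tuple[SentenceDataset, SentenceDataset]:
    """Seeded split preserving class proportions (largest-remainder
    allocation of ``n_test`` across classes). Each class must keep at least
    one example in both partitions."""
    N = len(dataset)
    if not 0 < n_test < N:
        raise ValueError(f"n_test must lie in (0, {N}), got {n_test}")
    by_class: dict[int, list[int]] = {0: [], 1: []}
    for i, label in enumerate(dataset.labels):
        by_class[label].append(i)
    present = [c for c in (0, 1) if by_class[c]]
    quotas = {c: n_test * len(by_class[c]) / N for c in present}
    counts = {c: int(quotas[c]) for c in present}
    remainder = n_test - sum(counts.values())
    for c in sorted(present, key=lambda c: quotas[c] - counts[c], reverse=True)[:remainder]:
        counts[c] += 1
    rng = random.Random(seed)
    test_idx: set[int] = set()
    for c in present:
        n_c = counts[c]
        if n_c < 1 or len(by_class[c]) - n_c < 1:
            raise ValueError(
                f"stratification infeasible: class {c} would have an empty partition"
            )
        test_idx.update(rng.sample(by_class[c], n_c))
    train_i = [i for i in range(N) if i not in test_idx]
    test_i = [i for i in range(N) if i in test_idx]

    def subset(idx: list[int], tag: str) -> SentenceDataset:
        return SentenceDataset(
            tuple(dataset.sentences[i] for i in idx),
            tuple(dataset.labels[i] for i in idx),
            tag,
        )

    return subset(train_i, "train"), subset(test_i, "test")


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


@dataclass(frozen=True)
class ClassReport:
    """Per-class predictive values plus sensitivity and specificity.

    Undefined ratios (zero denominator) are ``None`` — reported as
    not-available, never as zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def can_predictive_value(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def non_can_predictive_value(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def sensitivity(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fp)

    def pct(self, value: Optional[float], decimals: int = 0) -> Optional[float]:
        """Percentage rounded half-up; passes None through."""
        if value is None:
            return None
        q = Decimal(1).scaleb(-decimals)
        return float((Decimal(str(value)) * 100).quantize(q, rounding=ROUND_HALF_UP))


def per_class_report(pred: Sequence[int], gold: Sequence[int]) -> ClassReport:
    """Confusion-derived report; CAN = positive class (1)."""
    if len(pred) == 0 or len(gold) == 0:
        raise ValueError("label vectors must be non-empty")
    if len(pred) != len(gold):
        raise ValueError("pred and gold differ in length")
    tp = sum(1 for p, g in zip(pred, gold) if p == 1 and g == 1)
    fp = sum(1 for p, g in zip(pred, gold) if p == 1 and g == 0)
    tn = sum(1 for p, g in zip(pred, gold) if p == 0 and g == 0)
    fn = sum(1 for p, g in zip(pred, gold) if p == 0 and g == 1)
    return ClassReport(tp, fp, tn, fn)
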