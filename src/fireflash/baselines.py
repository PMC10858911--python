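"""Reference-based baseline classifiers and the 3-feature SVM.

Three template-matching scores compare a binary flash sequence ``(a_m)`` of
length M against a per-species reference ``(b_n)`` of length N:

* Jaccard index — intersection ``sum_{i<=min(M,N)} a_i b_i`` over union
  ``sum a_m + sum b_n``. Note the union is the *summed* on-mass of both
  sequences, so two identical binary sequences score 0.5, not 1.
* dot product — the intersection sum alone;
* dynamic time warping — the classic |a_i - b_j| local-cost dynamic program,
  no window constraint.

Each score vector is softmaxed into per-species probabilities (distances are
negated first so that closer means more probable) and the predicted species
is the arg max. The SVM instead classifies the 3-vector (number of flashes,
mean flash duration, mean inter-flash gap) with an RBF kernel on
standardized features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from fireflash.references import ReferencePattern
from fireflash.sequences import FlashSequence, sequence_stats

METRICS = ("jaccard", "dot", "dtw")


@dataclass
class ClassifierOutput:
    """Per-species probabilities plus the arg-max prediction."""

    probabilities: dict[str, float]
    predicted: str

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        best = max(self.probabilities.values())
        if self.probabilities[self.predicted] != best:
            raise ValueError("predicted must be the arg max probability")


def _values(x) -> np.ndarray:
    if isinstance(x, FlashSequence):
        return x.bits.astype(float)
    if isinstance(x, ReferencePattern):
        return x.values
    return np.asarray(x, dtype=float)


def jaccard_score(a, r) -> float:
    """Summed-mass Jaccard index between a sequence and a reference.

    Intersection and union follow the on-mass definitions above; an all-zero
    union returns 0. Bounded by 0.5 for binary inputs.
    """
    av, rv = _values(a), _values(r)
    if av.size == 0 or rv.size == 0:
        raise ValueError("sequences must be non-empty")
    m = min(av.size, rv.size)
    inter = float(av[:m] @ rv[:m])
    union = float(av.sum() + rv.sum())
    return inter / union if union > 0 else 0.0


def dot_score(a, r) -> float:
    """Dot product over the overlapping prefix of the two series."""
    av, rv = _values(a), _values(r)
    if av.size == 0 or rv.size == 0:
        raise ValueError("sequences must be non-empty")
    m = min(av.size, rv.size)
    return float(av[:m] @ rv[:m])


def dtw_distance(a, r) -> float:
    """Dynamic time warping distance with local cost |a_i - r_j|.

    Full-path dynamic program without a window constraint; symmetric, and 0
    for identical inputs.
    """
    av, rv = _values(a), _values(r)
    if av.size == 0 or rv.size == 0:
        raise ValueError("sequences must be non-empty")
    n = rv.size
    prev = np.full(n + 1, np.inf)
    prev[0] = 0.0
    for x in av:
        cur = np.empty(n + 1)
        cur[0] = np.inf
        cost = np.abs(x - rv)
        # cur[j] = cost[j-1] + min(prev[j], prev[j-1], cur[j-1]) — the serial
        # dependence on cur[j-1] needs an explicit loop
        best_prev = np.minimum(prev[1:], prev[:-1])
        run = np.inf
        for j in range(n):
            run = cost[j] + min(best_prev[j], run)
            cur[j + 1] = run
        prev = cur
    return float(prev[n])


def softmax(scores, distance: bool = False) -> np.ndarray:
    """Numerically stable softmax; distances are negated before exponentiation."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if distance:
        s = -s
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


def classify_by_reference(seq: FlashSequence,
                          refs: Mapping[str, ReferencePattern],
                          metric: str = "jaccard") -> ClassifierOutput:
    """Score a sequence against every species reference and softmax the scores.

    ``metric`` is one of ``jaccard``, ``dot`` (similarities) or ``dtw``
    (a distance, negated before softmax). Ties break toward the lowest
    label-encoded species (sorted name order).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if len(refs) < 2:
        raise ValueError("need at least two references to classify")
    species = sorted(refs)
    fn = {"jaccard": jaccard_score, "dot": dot_score, "dtw": dtw_distance}[metric]
    scores = np.array([fn(seq, refs[sp]) for sp in species])
    probs = softmax(scores, distance=(metric == "dtw"))
    predicted = species[int(np.argmax(probs))]
    return ClassifierOutput(dict(zip(species, probs)), predicted)


def svm_features(seq: FlashSequence) -> np.ndarray:
    """The 3-vector (n_flashes, mean flash duration s, mean inter-flash gap s)."""
    stats = sequence_stats(seq)
    if stats.n_flashes < 2:
        raise ValueError("SVM features require >= 2 flashes (gap undefined otherwise)")
    return np.array([
        stats.n_flashes,
        float(np.mean(stats.flash_durations_s)),
        float(np.mean(stats.gaps_s)),
    ])


class SVMClassifier:
    """RBF-kernel SVM over the 3 flash-pattern features, with standardization.

    Probabilities come from Platt scaling with pairwise coupling (sklearn's
    ``probability=True``); the predicted species is the arg max probability.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale", seed: int = 0):
        self.pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
                        random_state=seed)),
        ])
        self.classes_: list[str] | None = None

    def fit(self, features: np.ndarray, labels: Sequence[str]) -> "SVMClassifier":
        labels = list(labels)
        if len(set(labels)) < 2:
            raise ValueError("need at least two classes to train an SVM")
        self.pipeline.fit(np.asarray(features, dtype=float), labels)
        self.classes_ = list(self.pipeline.classes_)
        return self

    def fit_sequences(self, seqs: Sequence[FlashSequence]) -> "SVMClassifier":
        feats = np.array([svm_features(s) for s in seqs])
        return self.fit(feats, [s.species for s in seqs])

    def predict(self, features: np.ndarray) -> list[ClassifierOutput]:
        if self.classes_ is None:
            raise ValueError("classifier is not fitted")
        proba = self.pipeline.predict_proba(np.asarray(features, dtype=float))
        proba = proba / proba.sum(axis=1, keepdims=True)
        out = []
        for p in proba:
            probs = dict(zip(self.classes_, p))
            out.append(ClassifierOutput(probs, self.classes_[int(np.argmax(p))]))
        return out

    def predict_sequences(self, seqs: Sequence[FlashSequence]) -> list[ClassifierOutput]:
        return self.predict(np.array([svm_features(s) for s in seqs]))


def train_svm(features: np.ndarray, labels: Sequence[str], *,
              C: float = 1.0, gamma: str | float = "scale",
              seed: int = 0) -> SVMClassifier:
    """Fit an :class:`SVMClassifier` on a feature matrix (one row per sequence)."""
    return SVMClassifier(C=C, gamma=gamma, seed=seed).fit(features, labels)


def predict_svm(model: SVMClassifier, features: np.ndarray) -> list[ClassifierOutput]:
    return model.predict(features)
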