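"""Evaluation protocols: stratified cross-validation with undersampling,
weighted metrics, confusion matrices, ROC curves, and artificial sympatry.

The cross-validation protocol mirrors the study design: 60 stratified folds,
each splitting the data 90/10 (train/test) while preserving class ratios;
severe class imbalance is handled by random undersampling of the training
pool to the minority-class count, a validation set is carved from the
equalized pool, and all data left out of the equalized train/val sets joins
the test pool. The artificial-sympatry experiment mixes two species'
held-out sequences at controlled proportions (out of 400 total) and measures
each species' identification rate (mean true-positive rate) over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from fireflash.baselines import ClassifierOutput
from fireflash.sequences import SequenceDataset


@dataclass
class FoldSpec:
    """60 stratified 90/10 folds with train/val undersampled to equal class counts."""

    k: int = 60
    train_fraction: float = 0.9
    val_fraction: float = 0.1  # of the equalized train pool

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.train_fraction < 1 or not 0 < self.val_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")


#: the five held-out recording days for the sympatry experiments, keyed by
#: dataset code; the two remaining study species (P. bethaniensis,
#: P. forresti) have too few recordings to hold one out.
DEFAULT_HOLDOUT = {
    "s0524uf": "P. frontalis",
    "s0613ic": "P. carolinus",
    "s1602io": "P. obscurellus",
    "s1809ik": "P. knulli",
    "s2624bw": "B. wickershamorum",
}


@dataclass
class HoldoutSpec:
    """Held-out recording days (dataset code -> species) excluded from training."""

    recordings: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_HOLDOUT))

    @property
    def species(self) -> list[str]:
        return sorted(set(self.recordings.values()))


@dataclass
class SympatryResult:
    """Identification rate per ordered (focal, background) pair and proportion."""

    rates: dict[tuple[str, str], dict[float, float]]

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.rates)


def stratified_fold_indices(labels: Sequence[int], spec: FoldSpec,
                            seed: int = 0):
    """Yield (train_idx, val_idx, test_idx) index triples for each fold.

    Folds come from a repeated stratified k-fold scheme (k/6 repeats of
    10-fold when the test fraction is 10%), which guarantees every sequence
    appears in testing and in training across folds but never both within a
    fold. Within a fold the training pool is randomly undersampled without
    replacement to the minority-class count, a stratified validation split is
    carved from the equalized pool, and all remaining sequences join the test
    side.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n_splits = int(round(1.0 / (1.0 - spec.train_fraction)))
    if spec.k % n_splits != 0:
        raise ValueError(
            f"k={spec.k} must be a multiple of {n_splits} "
            f"(the inverse test fraction) for full test coverage")
    if counts.min() < n_splits:
        raise ValueError("every class needs at least one sequence per test split")
    rng = np.random.default_rng(seed)
    rskf = RepeatedStratifiedKFold(n_splits=n_splits,
                                   n_repeats=spec.k // n_splits,
                                   random_state=int(rng.integers(2 ** 31)))
    for train_pool, test_idx in rskf.split(np.zeros(len(labels)), labels):
        pool_labels = labels[train_pool]
        minority = min(np.sum(pool_labels == c) for c in classes)
        picked = []
        for c in classes:
            members = train_pool[pool_labels == c]
            picked.append(rng.choice(members, size=minority, replace=False))
        equalized = np.concatenate(picked)
        leftovers = np.setdiff1d(train_pool, equalized)
        train_idx, val_idx = train_test_split(
            equalized, test_size=spec.val_fraction,
            stratify=labels[equalized],
            random_state=int(rng.integers(2 ** 31)))
        yield (np.sort(train_idx), np.sort(val_idx),
               np.sort(np.concatenate([test_idx, leftovers])))


def stratified_folds(ds: SequenceDataset, spec: FoldSpec | None = None,
                     seed: int = 0):
    """Yield (train, val, test) :class:`SequenceDataset` triples per fold."""
    spec = spec or FoldSpec()
    for tr, va, te in stratified_fold_indices(ds.labels(), spec, seed=seed):
        yield ds.subset(tr), ds.subset(va), ds.subset(te)


def weighted_metrics(preds: Sequence[str], labels: Sequence[str]):
    """Support-weighted precision and recall plus overall accuracy."""
    preds, labels = list(preds), list(labels)
    if not preds or len(preds) != len(labels):
        raise ValueError("preds and labels must be equal-length and non-empty")
    return (
        float(precision_score(labels, preds, average="weighted", zero_division=0)),
        float(recall_score(labels, preds, average="weighted", zero_division=0)),
        float(accuracy_score(labels, preds)),
    )


def confusion_matrix(preds: Sequence[str], labels: Sequence[str],
                     label_order: Sequence[str] | None = None) -> np.ndarray:
    """Row-normalized confusion matrix; the diagonal is per-class recall."""
    if label_order is None:
        label_order = sorted(set(labels) | set(preds))
    return _sk_confusion(list(labels), list(preds), labels=list(label_order),
                         normalize="true")


def roc_curves(probabilities: Mapping[str, np.ndarray] | np.ndarray,
               labels: Sequence[str],
               species_order: Sequence[str] | None = None):
    """One-vs-rest ROC per species from the species' probability as score.

    ``probabilities`` is either a (n, k) array in ``species_order`` or a
    mapping species -> score vector. Returns {species: (fpr, tpr, auc)};
    species with no positive examples are reported as None.
    """
    labels = np.asarray(list(labels))
    if isinstance(probabilities, Mapping):
        prob_map = {sp: np.asarray(v, dtype=float) for sp, v in probabilities.items()}
    else:
        probabilities = np.asarray(probabilities, dtype=float)
        if species_order is None:
            raise ValueError("species_order is required with an array of probabilities")
        prob_map = {sp: probabilities[:, i] for i, sp in enumerate(species_order)}
    out = {}
    for sp, scores in prob_map.items():
        positives = labels == sp
        if not positives.any() or positives.all():
            out[sp] = None
            continue
        fpr, tpr, _ = _sk_roc_curve(positives.astype(int), scores)
        out[sp] = (fpr, tpr, float(roc_auc_score(positives.astype(int), scores)))
    return out


def sympatric_composition(p: float, total: int = 400) -> tuple[int, int]:
    """Sequence counts (focal, background) of a mixed set at proportion ``p``."""
    if not 0 < p <= 0.5:
        raise ValueError("proportion must lie in (0, 0.5]")
    n_focal = int(round(p * total))
    if n_focal < 1:
        raise ValueError(f"proportion {p} yields < 1 focal sequence")
    return n_focal, total - n_focal


def compose_sympatric_set(focal: SequenceDataset, background: SequenceDataset,
                          p: float, total: int = 400,
                          rng: np.random.Generator | None = None) -> SequenceDataset:
    """Sample one mixed two-species test set at proportion ``p`` of the focal."""
    rng = rng or np.random.default_rng()
    n_focal, n_bg = sympatric_composition(p, total)
    f_idx = rng.choice(len(focal), size=n_focal, replace=len(focal) < n_focal)
    b_idx = rng.choice(len(background), size=n_bg, replace=len(background) < n_bg)
    seqs = [focal.sequences[i] for i in f_idx] + [background.sequences[i] for i in b_idx]
    return SequenceDataset(seqs)


def sympatry_experiment(model,
                        holdout: Mapping[str, SequenceDataset],
                        proportions: Sequence[float] = (0.005, 0.01, 0.05, 0.1,
                                                        0.2, 0.3, 0.4, 0.5),
                        n_iter: int = 500,
                        total: int = 400,
                        seed: int = 0) -> SympatryResult:
    """Mix pairs of held-out species at controlled proportions and measure
    each species' identification rate.

    For every ordered pair (focal, background) of held-out species and each
    proportion p, a test set of ``total`` sequences is assembled from
    round(p * total) focal and the rest background sequences, sampled
    uniformly (with replacement when a held-out day is smaller than the
    request); the focal species' true-positive rate is averaged over
    ``n_iter`` iterations.

    The classifier is deterministic, so each held-out sequence is classified
    once up front and iterations resample the cached predictions — the
    resulting rates are identical in distribution to reclassifying every
    sampled set.
    """
    if total < 2:
        raise ValueError("total must be >= 2")
    for p in proportions:
        if not 0 < p <= 0.5:
            raise ValueError("proportions must lie in (0, 0.5]")
        if int(round(p * total)) < 1:
            raise ValueError(f"proportion {p} yields < 1 focal sequence")
    rng = np.random.default_rng(seed)
    species = sorted(holdout)
    hits: dict[str, np.ndarray] = {}
    for sp in species:
        ds = holdout[sp]
        if len(ds) == 0:
            raise ValueError(f"held-out set for {sp} is empty")
        preds = model.predict(ds)
        hits[sp] = np.array([out.predicted == sp for out in preds], dtype=float)
    rates: dict[tuple[str, str], dict[float, float]] = {}
    for focal in species:
        for background in species:
            if focal == background:
                continue
            per_p: dict[float, float] = {}
            for p in proportions:
                n_focal = int(round(p * total))
                replace = hits[focal].size < n_focal
                vals = np.empty(n_iter)
                for it in range(n_iter):
                    f_idx = rng.choice(hits[focal].size, size=n_focal,
                                       replace=replace)
                    vals[it] = hits[focal][f_idx].mean()
                per_p[p] = float(vals.mean())
            rates[(focal, background)] = per_p
    return SympatryResult(rates)
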