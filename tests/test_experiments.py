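"""Tests for cross-validation folds, evaluation metrics and artificial sympatry."""

import numpy as np
import pytest

from fireflash import FlashSequence, SequenceDataset
from fireflash.baselines import ClassifierOutput
from fireflash.experiments import (
    DEFAULT_HOLDOUT,
    FoldSpec,
    HoldoutSpec,
    compose_sympatric_set,
    confusion_matrix,
    roc_curves,
    stratified_fold_indices,
    stratified_folds,
    sympatric_composition,
    sympatry_experiment,
    weighted_metrics,
)


def make_labeled(counts: dict[str, int]) -> SequenceDataset:
    seqs = []
    for sp, n in counts.items():
        seqs.extend(FlashSequence([1, 0, 0, 0, 1], species=sp) for _ in range(n))
    return SequenceDataset(seqs)


class TestStratifiedFolds:
    def test_fold_invariants(self):
        labels = np.array([0] * 500 + [1] * 100)
        spec = FoldSpec(k=60)
        train_seen = np.zeros(600, dtype=int)
        test_seen = np.zeros(600, dtype=int)
        folds = list(stratified_fold_indices(labels, spec, seed=0))
        assert len(folds) == 60
        for tr, va, te in folds:
            assert not set(tr) & set(te)
            assert not set(va) & set(te)
            assert not set(tr) & set(va)
            # equalized class counts in the train+val pool
            pool = np.concatenate([tr, va])
            c0, c1 = np.sum(labels[pool] == 0), np.sum(labels[pool] == 1)
            assert c0 == c1
            train_seen[pool] += 1
            test_seen[te] += 1
        assert (train_seen >= 1).all()
        assert (test_seen >= 1).all()

    def test_exactly_equal_train_class_counts(self):
        labels = np.array([0] * 200 + [1] * 40 + [2] * 120)
        for tr, va, te in stratified_fold_indices(labels, FoldSpec(k=10), seed=1):
            pool = np.concatenate([tr, va])
            _, counts = np.unique(labels[pool], return_counts=True)
            assert len(set(counts)) == 1

    def test_class_smaller_than_fold_count_rejected(self):
        labels = np.array([0] * 50 + [1] * 5)
        with pytest.raises(ValueError):
            list(stratified_fold_indices(labels, FoldSpec(k=10), seed=0))

    def test_dataset_wrapper_yields_datasets(self):
        ds = make_labeled({"a": 40, "b": 20})
        train, val, test = next(iter(stratified_folds(ds, FoldSpec(k=10), seed=0)))
        assert train.label_map == ds.label_map
        assert len(train) + len(val) + len(test) == len(ds)


class TestWeightedMetrics:
    def test_hand_computed_example(self):
        prec, rec, acc = weighted_metrics(["A", "B", "B", "B"], ["A", "A", "B", "B"])
        assert prec == pytest.approx(0.83333333)
        assert rec == pytest.approx(0.75)
        assert acc == pytest.approx(0.75)

    def test_perfect_predictions(self):
        assert weighted_metrics(["A", "B"], ["A", "B"]) == pytest.approx((1, 1, 1))

    def test_single_class_predictions_on_balanced_labels(self):
        _, rec, acc = weighted_metrics(["A"] * 4, ["A", "A", "B", "B"])
        assert rec == pytest.approx(0.5)
        assert acc == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics([], [])

    def test_matches_tally_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        for _ in range(30):
            n = int(rng.integers(2, 51))
            labels = [classes[i] for i in rng.integers(0, 3, n)]
            preds = [classes[i] for i in rng.integers(0, 3, n)]
            prec, rec, acc = weighted_metrics(preds, labels)
            # brute-force per-class tally
            e_prec = e_rec = 0.0
            for c in classes:
                support = sum(l == c for l in labels)
                if support == 0:
                    continue
                tp = sum(p == c and l == c for p, l in zip(preds, labels))
                pp = sum(p == c for p in preds)
                e_prec += support * (tp / pp if pp else 0.0)
                e_rec += support * tp / support
            assert prec == pytest.approx(e_prec / n)
            assert rec == pytest.approx(e_rec / n)
            assert acc == pytest.approx(np.mean([p == l for p, l in zip(preds, labels)]))


class TestConfusionMatrix:
    def test_perfect_is_identity(self):
        m = confusion_matrix(["A", "B"], ["A", "B"], label_order=["A", "B"])
        assert np.array_equal(m, np.eye(2))

    def test_hand_example(self):
        m = confusion_matrix(["B", "A", "B"], ["A", "A", "B"], label_order=["A", "B"])
        assert m[0] == pytest.approx([0.5, 0.5])
        assert m[1] == pytest.approx([0.0, 1.0])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        labels = [str(i) for i in rng.integers(0, 4, 40)]
        preds = [str(i) for i in rng.integers(0, 4, 40)]
        m = confusion_matrix(preds, labels)
        present = sorted(set(labels) | set(preds))
        for i, sp in enumerate(present):
            if sp in labels:
                assert m[i].sum() == pytest.approx(1.0)


class TestROC:
    def test_perfect_ranking_auc_one(self):
        labels = ["x"] * 5 + ["y"] * 5
        scores = {"x": np.r_[np.ones(5), np.zeros(5)],
                  "y": np.r_[np.zeros(5), np.ones(5)]}
        curves = roc_curves(scores, labels)
        assert curves["x"][2] == pytest.approx(1.0)
        assert curves["y"][2] == pytest.approx(1.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        labels = ["x" if b else "y" for b in rng.integers(0, 2, 2000)]
        scores = {"x": rng.uniform(size=2000)}
        _, _, auc = roc_curves(scores, labels)["x"]
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_curves_monotone(self):
        rng = np.random.default_rng(4)
        labels = ["x" if b else "y" for b in rng.integers(0, 2, 100)]
        fpr, tpr, _ = roc_curves({"x": rng.uniform(size=100)}, labels)["x"]
        assert (np.diff(fpr) >= 0).all()
        assert (np.diff(tpr) >= 0).all()

    def test_missing_positives_reported_as_none(self):
        curves = roc_curves({"x": np.array([0.1, 0.9]), "z": np.array([0.5, 0.5])},
                            ["x", "x"])
        assert curves["x"] is None  # no negatives either
        assert curves["z"] is None


class LengthStub:
    """Deterministic stand-in classifier: species by sequence length threshold."""

    def __init__(self, thresholds: dict[str, tuple[float, float]]):
        self.thresholds = thresholds

    def predict(self, ds):
        out = []
        species = sorted(self.thresholds)
        for s in ds:
            pred = min(species,
                       key=lambda sp: abs(len(s) - self.thresholds[sp][0]))
            probs = {sp: (0.9 if sp == pred else 0.1 / (len(species) - 1))
                     for sp in species}
            out.append(ClassifierOutput(probs, pred))
        return out


class TestSympatry:
    def test_printed_compositions(self):
        assert sympatric_composition(0.005, 400) == (2, 398)
        assert sympatric_composition(0.5, 400) == (200, 200)

    def test_too_small_proportion_rejected(self):
        with pytest.raises(ValueError):
            sympatric_composition(0.001, 400)

    def test_default_holdout_covers_five_species(self):
        spec = HoldoutSpec()
        assert len(spec.recordings) == 5
        assert sorted(DEFAULT_HOLDOUT.values()) == spec.species
        # the two data-poor species are never held out
        assert "P. bethaniensis" not in spec.species
        assert "P. forresti" not in spec.species

    def test_composed_set_sizes(self):
        pool_a = SequenceDataset([FlashSequence([1, 0, 0, 0, 1], species="a")] * 10)
        pool_b = SequenceDataset([FlashSequence([1] * 30, species="b")] * 10)
        mixed = compose_sympatric_set(pool_a, pool_b, 0.005, total=400,
                                      rng=np.random.default_rng(0))
        counts = mixed.counts()
        assert counts == {"a": 2, "b": 398}

    def test_twenty_ordered_pairs_for_five_species(self):
        pools = {}
        for i, sp in enumerate(sorted(DEFAULT_HOLDOUT.values())):
            length = 10 + 20 * i
            pools[sp] = SequenceDataset(
                [FlashSequence([1] + [0] * (length - 2) + [1], species=sp)] * 5)
        stub = LengthStub({sp: (10 + 20 * i, 0)
                           for i, sp in enumerate(sorted(pools))})
        result = sympatry_experiment(stub, pools, proportions=(0.05, 0.5),
                                     n_iter=3, total=40, seed=0)
        assert len(result.pairs()) == 20
        for rates in result.rates.values():
            for r in rates.values():
                assert 0.0 <= r <= 1.0
        # the stub is perfect on these disjoint lengths
        assert all(r == 1.0 for rates in result.rates.values()
                   for r in rates.values())
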