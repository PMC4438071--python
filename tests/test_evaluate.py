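"""Cross-validation folds and SVM accuracy harness."""

import numpy as np
import pytest

from stlbp import (
    Corpus,
    CVScheme,
    KernelSpec,
    Sample,
    cross_validated_accuracy,
    make_folds,
)


def _clustered_corpus(
    n_subjects=8, per_subject=3, n_classes=3, dim=12, sep=10.0, seed=0
):
    """Widely separated class clusters; subject id varies independently."""
    rng = np.random.default_rng(seed)
    samples, g = [], 0
    for subj in range(n_subjects):
        for v in range(per_subject):
            cls = g % n_classes
            center = np.zeros(dim)
            center[cls] = sep
            samples.append(
                Sample(
                    f"s{subj:02d}_v{v}",
                    f"subj{subj:02d}",
                    f"c{cls}",
                    center + rng.normal(0, 0.1, dim),
                )
            )
            g += 1
    return Corpus(samples)


class TestMakeFolds:
    def test_lovo_one_fold_per_sample(self):
        corpus = _clustered_corpus()
        folds = make_folds(corpus, CVScheme("lovo"))
        assert len(folds) == len(corpus)
        tested = [t for _, test in folds for t in test]
        assert sorted(tested) == sorted(s.sample_id for s in corpus.samples)

    def test_loso_one_fold_per_subject_and_disjoint(self):
        corpus = _clustered_corpus(n_subjects=6)
        folds = make_folds(corpus, CVScheme("loso"))
        assert len(folds) == 6
        subj_of = {s.sample_id: s.subject_id for s in corpus.samples}
        for train, test in folds:
            assert not set(train) & set(test)
            assert len({subj_of[i] for i in test}) == 1
            assert {subj_of[i] for i in test}.isdisjoint({subj_of[i] for i in train})
        tested = [t for _, test in folds for t in test]
        assert sorted(tested) == sorted(s.sample_id for s in corpus.samples)

    def test_every_sample_in_complement_train_sets(self):
        corpus = _clustered_corpus(n_subjects=4, per_subject=2)
        folds = make_folds(corpus, CVScheme("lovo"))
        for sid in (s.sample_id for s in corpus.samples):
            appearances = sum(sid in train for train, _ in folds)
            assert appearances == len(folds) - 1

    def test_single_subject_loso_rejected(self):
        corpus = _clustered_corpus(n_subjects=1)
        with pytest.raises(ValueError):
            make_folds(corpus, CVScheme("loso"))


class TestAccuracy:
    @pytest.mark.parametrize("kind", ["linear", "rbf", "poly"])
    @pytest.mark.parametrize("mode", ["lovo", "loso"])
    def test_separable_clusters_are_perfect(self, kind, mode):
        corpus = _clustered_corpus()
        rep = cross_validated_accuracy(
            corpus, CVScheme(mode), KernelSpec(kind), seed=0
        )
        assert rep.accuracy == 1.0
        assert len(rep.predictions) == len(corpus)

    def test_permuted_labels_near_chance(self):
        corpus = _clustered_corpus(n_subjects=10, per_subject=3)
        rng = np.random.default_rng(7)
        labels = rng.permutation([s.label for s in corpus.samples])
        shuffled = Corpus(
            [
                Sample(s.sample_id, s.subject_id, lab, s.features)
                for s, lab in zip(corpus.samples, labels)
            ]
        )
        rep = cross_validated_accuracy(
            shuffled, CVScheme("loso"), KernelSpec("linear"), seed=0
        )
        n = len(corpus)
        band = 3.5 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(rep.accuracy - 1 / 3) < band

    def test_repeat_run_is_identical(self):
        corpus = _clustered_corpus()
        a = cross_validated_accuracy(corpus, CVScheme("loso"), KernelSpec("rbf"), 3)
        b = cross_validated_accuracy(corpus, CVScheme("loso"), KernelSpec("rbf"), 3)
        assert a.accuracy == b.accuracy
        assert a.predictions.equals(b.predictions)

    def test_sample_order_invariance(self):
        corpus = _clustered_corpus()
        reordered = Corpus(list(reversed(corpus.samples)))
        a = cross_validated_accuracy(corpus, CVScheme("loso"), KernelSpec(), 0)
        b = cross_validated_accuracy(reordered, CVScheme("loso"), KernelSpec(), 0)
        assert a.accuracy == b.accuracy

    def test_fold_missing_class_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        samples = [
            Sample("a0", "A", "x", rng.random(4)),
            Sample("a1", "A", "x", rng.random(4)),
            Sample("b0", "B", "x", rng.random(4)),
            Sample("b1", "B", "y", rng.random(4)),
        ]
        corpus = Corpus(samples)
        with pytest.warns(UserWarning, match="single class"):
            rep = cross_validated_accuracy(
                corpus, CVScheme("loso"), KernelSpec(), 0
            )
        # the fold testing subject B trains on A only (all class x) -> skipped
        assert rep.skipped_folds == [1]
        assert set(rep.predictions["subject_id"]) == {"A"}

    def test_confusion_matrix_totals(self):
        corpus = _clustered_corpus()
        rep = cross_validated_accuracy(corpus, CVScheme("lovo"), KernelSpec(), 0)
        assert rep.confusion.to_numpy().sum() == len(corpus)
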