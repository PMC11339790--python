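"""Splitting, metrics, and the training loop on a small learnable problem."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retiqa import synth
from retiqa.model import ModelSpec, build_variant
from retiqa.train_eval import (EvalResult, Hyperparams, UndefinedAUCError,
                               binarize, evaluate, kfold_stratified,
                               load_checkpoint, save_checkpoint,
                               stratified_split, train_model)


def table_with(n_good, n_poor, item="overall"):
    return pd.DataFrame({item: [1] * n_good + [0] * n_poor})


class TestStratifiedSplit:
    def test_per_stratum_rounding(self):
        split = stratified_split(table_with(60, 40), 0.8, "overall", seed=0)
        y = table_with(60, 40)["overall"].to_numpy()
        assert len(split.train_indices) == 80
        assert y[split.train_indices].sum() == 48          # 0.8 * 60 good
        assert (y[split.train_indices] == 0).sum() == 32   # 0.8 * 40 poor

    def test_partition_property(self):
        split = stratified_split(table_with(30, 20), 0.8, seed=1)
        union = np.union1d(split.train_indices, split.test_indices)
        np.testing.assert_array_equal(union, np.arange(50))
        assert len(np.intersect1d(split.train_indices, split.test_indices)) == 0

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            stratified_split(table_with(10, 10), 1.0)

    def test_same_seed_reproducible(self):
        a = stratified_split(table_with(30, 20), seed=5)
        b = stratified_split(table_with(30, 20), seed=5)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            stratified_split(table_with(50, 1))


class TestKFold:
    def test_five_disjoint_exhaustive_folds(self):
        folds = kfold_stratified(table_with(50, 50), k=5, seed=0)
        assert len(folds) == 5
        tests = [set(f.test_indices.tolist()) for f in folds]
        for i in range(5):
            assert len(tests[i]) == 20
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]
        assert set().union(*tests) == set(range(100))

    def test_fold_class_balance_within_one_sample(self):
        y = table_with(50, 50)["overall"].to_numpy()
        for f in kfold_stratified(table_with(50, 50), k=5, seed=2):
            good = y[f.test_indices].sum()
            assert 9 <= good <= 11

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="5-fold"):
            kfold_stratified(table_with(96, 4), k=5)


class TestBinarizeEvaluate:
    def test_threshold_is_strict(self):
        np.testing.assert_array_equal(
            binarize([0.51, 0.49, 0.5], 0.5), [1, 0, 0])

    def test_threshold_zero_all_positive(self):
        np.testing.assert_array_equal(binarize([0.1, 0.9], 0.0), [1, 1])

    def test_separated_scores_auc_one(self):
        res = evaluate([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.accuracy == 1.0

    def test_constant_scores_auc_half(self):
        res = evaluate([0.4] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_statistic(self):
        rng = np.random.default_rng(30)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        res = evaluate(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided").statistic
        n1, n0 = labels.sum(), (1 - labels).sum()
        assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-10)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = evaluate(scores, labels).auc
        b = evaluate(1 / (1 + np.exp(-7 * (scores - 0.3))), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_roc_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(9)
        res = evaluate(rng.random(50), rng.integers(0, 2, 50))
        pts = res.roc_points
        np.testing.assert_array_equal(pts[0], [0, 0])
        np.testing.assert_array_equal(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_raises_but_carries_accuracy(self):
        with pytest.raises(UndefinedAUCError) as exc:
            evaluate([0.9, 0.8], [1, 1])
        assert exc.value.accuracy == 1.0

    def test_accuracy_of_uninformative_scorer_tracks_prevalence(self):
        rng = np.random.default_rng(10)
        labels = (rng.random(4000) < 0.7).astype(int)
        scores = rng.random(4000) * 0.4  # always below threshold -> predict 0
        res_acc = (binarize(scores, 0.5) == labels).mean()
        assert res_acc == pytest.approx(0.3, abs=0.03)


@pytest.fixture(scope="module")
def tiny_blur_problem():
    imgs, labels = synth.make_blur_benchmark(n=48, side=64, seed=3)
    return imgs, labels


class TestTraining:
    def test_history_length_best_selection_and_reproducibility(self, tiny_blur_problem, tmp_path):
        imgs, labels = tiny_blur_problem
        tr = (imgs[:32], labels[:32])
        te = (imgs[32:], labels[32:])
        hp = Hyperparams(epochs=3, seed=1)

        def run():
            model = build_variant(ModelSpec(variant="BL", backbone="reduced",
                                            seed=1))
            return model, *train_model(model, tr, te, hp)

        model, state, hist = run()
        assert len(hist) == 3
        assert max(h["test_accuracy"] for h in hist) == \
            max(h["test_accuracy"] for h in hist[:])  # selection rule
        # loss decreases over the first epochs on this learnable problem
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]
        _, _, hist2 = run()
        for a, b in zip(hist, hist2):
            assert a["train_loss"] == pytest.approx(b["train_loss"], abs=1e-4)
        # checkpoint round-trip preserves predictions
        ckpt = tmp_path / "m.npz"
        save_checkpoint(ckpt, model, hist)
        from retiqa.nn import Tensor
        restored, hist3 = load_checkpoint(ckpt)
        assert hist3 == hist
        p0 = model.predict(Tensor(te[0][:4])).probability
        p1 = restored.predict(Tensor(te[0][:4])).probability
        np.testing.assert_allclose(p0, p1, atol=1e-6)

    def test_empty_data_rejected(self, tiny_blur_problem):
        imgs, labels = tiny_blur_problem
        model = build_variant(ModelSpec(variant="BL", backbone="reduced"))
        with pytest.raises(ValueError, match="nonempty"):
            train_model(model, (imgs[:0], labels[:0]), (imgs, labels),
                        Hyperparams(epochs=1))

    def test_lr_ratio_default_one_to_ten(self):
        hp = Hyperparams()
        assert hp.lr_backbone == pytest.approx(hp.lr_new / 10)
        assert hp.batch_size == 8 and hp.epochs == 20
        assert hp.weight_decay == 5e-4 and hp.threshold == 0.5
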