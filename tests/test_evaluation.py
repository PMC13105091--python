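import numpy as np
import pytest
import scipy.stats
import sklearn.metrics

from lorax.data_model import ValidationError
from lorax.evaluation import (
    apply_tier_weights,
    compare_models,
    compute_metrics,
    make_splits,
    matthews_corrcoef,
    naive_baseline,
    r2_score,
)
from lorax.synthetic_data import gen_panel, gen_sparse_screen, planted_bilinear


# ---------------------------------------------------------------------------
# Splits


class TestMakeSplits:
    def test_random_folds_cover_and_are_disjoint(self):
        ds, _ = gen_panel(20, 5, planted_bilinear(seed=0), seed=0)
        split = make_splits(ds, "random", k=5, seed=1)
        all_test = np.concatenate([f.test_idx for f in split])
        assert sorted(all_test) == list(range(100))
        for f in split:
            parts = [f.train_idx, f.val_idx, f.test_idx]
            assert len(np.concatenate(parts)) == len(set(np.concatenate(parts)))

    def test_unseen_odorant_entity_exclusion(self):
        ds, _ = gen_panel(15, 6, planted_bilinear(seed=0), seed=0)
        split = make_splits(ds, "unseen_odorant", k=4, seed=2)
        for f in split:
            test_ods = {ds.interactions[i].odorant_id for i in f.test_idx}
            trainval_ods = {
                ds.interactions[i].odorant_id
                for i in np.concatenate([f.train_idx, f.val_idx])
            }
            assert not test_ods & trainval_ods

    def test_same_seed_reproduces_splits(self):
        ds, _ = gen_panel(12, 5, planted_bilinear(seed=0), seed=0)
        a = make_splits(ds, "unseen_receptor", k=3, seed=9)
        b = make_splits(ds, "unseen_receptor", k=3, seed=9)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.train_idx, fb.train_idx)
            assert np.array_equal(fa.test_idx, fb.test_idx)

    def test_too_few_entities_error(self):
        ds, _ = gen_panel(10, 3, planted_bilinear(seed=0), seed=0)
        with pytest.raises(ValidationError, match="entities"):
            make_splits(ds, "unseen_receptor", k=5, seed=0)

    def test_invariants_across_random_configurations(self):
        """Disjointness, coverage and entity exclusion over 100 random configs."""
        rng = np.random.default_rng(7)
        scenarios = ["random", "unseen_odorant", "unseen_receptor"]
        for trial in range(100):
            n_od = int(rng.integers(8, 16))
            n_rec = int(rng.integers(4, 9))
            k = int(rng.integers(2, 5))
            scenario = scenarios[int(rng.integers(0, 3))]
            ds, _ = gen_panel(n_od, n_rec, planted_bilinear(seed=trial), seed=trial)
            split = make_splits(ds, scenario, k=k, seed=trial,
                                val_fraction=float(rng.uniform(0.05, 0.3)))
            n = len(ds.interactions)
            all_test = np.concatenate([f.test_idx for f in split])
            assert sorted(all_test) == list(range(n)), "test folds must cover"
            for f in split:
                combined = np.concatenate([f.train_idx, f.val_idx, f.test_idx])
                assert len(combined) == n == len(set(combined)), "partition"
                if scenario != "random":
                    key = "odorant_id" if scenario == "unseen_odorant" else "receptor_id"
                    test_e = {getattr(ds.interactions[i], key) for i in f.test_idx}
                    other = np.concatenate([f.train_idx, f.val_idx])
                    other_e = {getattr(ds.interactions[i], key) for i in other}
                    assert not test_e & other_e, "entity leakage"


# ---------------------------------------------------------------------------
# Metrics


class TestComputeMetrics:
    def test_perfect_predictions(self):
        rep = compute_metrics([0, 1, 1, 0], [0.1, 0.9, 0.8, 0.2], "classification")
        assert rep.mcc == 1.0 and rep.f_score == 1.0
        assert compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "regression").r2 == 1.0

    def test_balanced_confusion_gives_zero_mcc(self):
        # (TP, FP, FN, TN) = (1, 1, 1, 1)
        y = [1, 0, 1, 0]
        p = [0.9, 0.9, 0.1, 0.1]
        assert compute_metrics(y, p, "classification").mcc == 0.0

    def test_worked_confusion_8_2_1_9(self):
        y = [1] * 9 + [0] * 11
        p = [0.9] * 8 + [0.1] * 1 + [0.9] * 2 + [0.1] * 9  # TP=8, FN=1, FP=2, TN=9
        rep = compute_metrics(y, p, "classification")
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(8 / 9)
        # closed form evaluated independently
        expected = (8 * 9 - 2 * 1) / np.sqrt(10 * 9 * 11 * 10)
        assert rep.mcc == pytest.approx(expected, abs=1e-12)
        assert rep.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_single_class_flags_missing_auroc(self):
        rep = compute_metrics([1, 1, 1], [0.2, 0.9, 0.5], "classification")
        assert rep.auroc is None and rep.avep is None
        assert any("single-class" in f for f in rep.flags)

    def test_agrees_with_independent_implementations_on_random_vectors(self):
        """Dual-route check on 1,000 random prediction vectors (<= 1e-8)."""
        rng = np.random.default_rng(123)
        for _ in range(500):  # regression
            n = int(rng.integers(5, 40))
            y = rng.standard_normal(n)
            p = rng.standard_normal(n)
            assert r2_score(y, p) == pytest.approx(
                sklearn.metrics.r2_score(y, p), abs=1e-8
            )
        for _ in range(500):  # classification
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.random(n)
            rep = compute_metrics(y, p, "classification")
            yh = (p >= 0.5).astype(int)
            assert rep.mcc == pytest.approx(
                sklearn.metrics.matthews_corrcoef(y, yh), abs=1e-8
            )
            # AUROC via the rank-statistic formulation (independent of sklearn)
            ranks = scipy.stats.rankdata(p)
            n1 = y.sum()
            auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * (n - n1))
            assert rep.auroc == pytest.approx(auc, abs=1e-8)
            # AveP by direct step-interpolated summation
            order = np.argsort(-p, kind="stable")
            ys = y[order]
            tp = np.cumsum(ys)
            prec = tp / np.arange(1, n + 1)
            rec = tp / n1
            drec = np.diff(np.concatenate([[0.0], rec]))
            assert rep.avep == pytest.approx(float((prec * drec).sum()), abs=1e-8)

    def test_mcc_zero_denominator_convention(self):
        assert matthews_corrcoef([1, 1], [1, 1]) == 0.0
        assert matthews_corrcoef([0, 1], [0, 0]) == 0.0


class TestNaiveBaseline:
    def test_equal_means_give_zero(self):
        assert naive_baseline([0.0, 0.0], [1.0, -1.0]).r2 == pytest.approx(0.0)

    def test_hand_checked_example(self):
        rep = naive_baseline([5.0, 5.0], [0.0, 1.0, 2.0])
        assert rep.r2 == pytest.approx(1 - (25 + 16 + 9) / 2)  # = -24

    def test_empty_train_errors(self):
        with pytest.raises(ValidationError, match="empty"):
            naive_baseline([], [1.0, 2.0])


class TestTierWeights:
    def _screen(self):
        ds, _ = gen_sparse_screen(20, 10, density=0.4, positive_rate=0.3,
                                  tiers={"ec50": 0.3, "primary": 0.7}, seed=5)
        return ds

    def test_weights_assigned_per_record(self):
        ds = apply_tier_weights(self._screen(), {"ec50": 1.0, "primary": 0.3})
        for it in ds.interactions:
            assert it.weight == (1.0 if it.tier == "ec50" else 0.3)

    def test_all_ones_is_neutral(self):
        base = self._screen()
        ds = apply_tier_weights(base, {"ec50": 1.0, "primary": 1.0})
        assert np.array_equal(ds.weights(), base.weights())

    def test_unmapped_tier_and_negative_weight_errors(self):
        with pytest.raises(ValidationError, match="primary"):
            apply_tier_weights(self._screen(), {"ec50": 1.0})
        with pytest.raises(ValidationError, match="negative"):
            apply_tier_weights(self._screen(), {"ec50": 1.0, "primary": -0.5})


class TestCompareModels:
    def test_identical_scores_paired_t_degenerate(self):
        rep = compare_models({"a": [1, 2, 3], "b": [1, 2, 3]}, test="paired_t")
        assert rep.pairwise[("a", "b")] == 1.0
        assert rep.flags

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(5) * 0.01
        scores = {"a": list(base + 10), "b": list(base)}
        rep = compare_models(scores, test="paired_t")
        assert rep.pairwise[("a", "b")] < 0.05
        # independent check with scipy directly
        assert rep.pairwise[("a", "b")] == pytest.approx(
            scipy.stats.ttest_rel(scores["a"], scores["b"]).pvalue
        )

    def test_friedman_worst_model_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(1)
        a = list(rng.normal(1.0, 0.01, 8))
        b = list(rng.normal(1.05, 0.01, 8))
        c = list(rng.normal(0.2, 0.01, 8))  # always ranks last
        rep = compare_models({"a": a, "b": b, "c": c}, test="friedman_bh")
        p_with_c = min(rep.pairwise[("a", "c")], rep.pairwise[("b", "c")])
        assert p_with_c <= rep.pairwise[("a", "b")]
        assert rep.global_p == pytest.approx(
            scipy.stats.friedmanchisquare(a, b, c).pvalue
        )

    def test_anova_tukey_bonferroni_pvalues_bounded(self):
        rng = np.random.default_rng(2)
        scores = {m: list(rng.normal(mu, 0.1, 6)) for m, mu in
                  [("a", 0.0), ("b", 0.0), ("c", 2.0)]}
        rep = compare_models(scores, test="anova_tukey_bonferroni")
        assert rep.global_p < 0.05
        assert all(0 <= p <= 1 for p in rep.pairwise.values())
        assert ("a", "c") in rep.significant and ("b", "c") in rep.significant
        assert ("a", "b") not in rep.significant

    def test_misaligned_fold_counts_error(self):
        with pytest.raises(ValidationError, match="unequal"):
            compare_models({"a": [1, 2], "b": [1, 2, 3]})
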