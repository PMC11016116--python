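"""Binarization, wrapper fitness, and the binary optimizer contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smafbi.binary import (
    CVPlan,
    FeatureMask,
    FitnessWeights,
    LabeledDataset,
    binarize,
    knn_error_cv,
    literal_threshold_binarize,
    run_bfbi,
    run_bsma_fbi,
    subset_fitness,
    transfer_v,
)
from smafbi.core import ConfigurationError, OptimizerConfig


class TestTransferV:
    def test_zero(self):
        assert transfer_v(0.0) == 0.0

    def test_symmetry_closed_form(self):
        t = math.tanh(1.0)
        assert transfer_v(1.0) == pytest.approx(t, abs=1e-12)
        assert transfer_v(-1.0) == pytest.approx(t, abs=1e-12)

    def test_saturation(self):
        v = transfer_v(10.0)
        assert v == pytest.approx(math.tanh(10.0), abs=1e-15)
        assert v < 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-50, 50), st.floats(0.01, 10))
    def test_monotone_in_magnitude(self, x, delta):
        bigger = abs(x) + delta
        assert transfer_v(bigger) >= transfer_v(x)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            transfer_v(float("nan"))


class TestBinarize:
    def test_empty_mask_repaired(self, rng):
        mask = binarize(np.zeros(30), rng)
        assert mask.l == 1  # transfer of 0 is 0 everywhere; repair sets one bit

    def test_saturated_positions_select_almost_everything(self, rng):
        mask = binarize(np.full(500, 10.0), rng)
        assert mask.l >= 495

    def test_bernoulli_law(self):
        # selection frequency at transfer value tanh(1) over 10,000 bits
        rng = np.random.default_rng(0)
        p = math.tanh(1.0)
        n = 10_000
        mask = binarize(np.ones(n), rng)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(mask.l / n - p) <= 3 * se

    def test_literal_rule_ignores_position(self):
        # printed threshold rule: same draws give the same mask regardless of x
        m1 = literal_threshold_binarize(np.zeros(50), np.random.default_rng(4))
        m2 = literal_threshold_binarize(np.full(50, 9.0), np.random.default_rng(4))
        assert np.array_equal(m1.bits, m2.bits)


class TestSubsetFitness:
    def test_perfect_and_empty(self):
        assert subset_fitness(0.0, 0, 100) == 0.0

    def test_worst_case_normalizes_to_one(self):
        assert subset_fitness(1.0, 100, 100) == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        assert subset_fitness(0.2, 10, 100) == pytest.approx(0.195, abs=1e-12)

    def test_size_monotonicity(self):
        f_small = subset_fitness(0.3, 5, 50)
        f_big = subset_fitness(0.3, 6, 50)
        assert f_small < f_big

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.integers(0, 200))
    def test_range(self, error, l):
        assert 0.0 <= subset_fitness(error, l, 200) <= 1.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            subset_fitness(1.2, 1, 10)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            FitnessWeights(alpha=0.9, beta=0.2)


def two_clouds(n_per=30, d=5, gap=10.0, seed=0):
    """Two classes separated along feature 0 only."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, d))
    y = np.repeat([0, 1], n_per)
    X[:, 0] += gap * y
    return LabeledDataset(X=X, y=y)


class TestKnnErrorCv:
    def test_separable_case(self):
        data = two_clouds()
        bits = np.zeros(5, dtype=int)
        bits[0] = 1
        err = knn_error_cv(data, FeatureMask(bits), CVPlan(split_seed=1), k=1)
        assert err == 0.0

    def test_chance_level_with_permuted_labels(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 4))
        y = np.array([0, 1] * 150)
        data = LabeledDataset(X=X, y=y)
        err = knn_error_cv(data, FeatureMask(np.ones(4, dtype=int)), CVPlan(split_seed=2))
        assert abs(err - 0.5) < 0.1

    def test_deterministic_given_split_seed(self):
        data = two_clouds(gap=1.0)
        mask = FeatureMask(np.ones(5, dtype=int))
        e1 = knn_error_cv(data, mask, CVPlan(split_seed=7))
        e2 = knn_error_cv(data, mask, CVPlan(split_seed=7))
        assert e1 == e2

    def test_infeasible_folds_named(self):
        data = two_clouds(n_per=4)
        with pytest.raises(ConfigurationError, match="class"):
            knn_error_cv(data, FeatureMask(np.ones(5, dtype=int)), CVPlan(folds=10))

    def test_empty_mask_rejected(self):
        data = two_clouds()
        with pytest.raises(ValueError):
            knn_error_cv(data, FeatureMask(np.zeros(5, dtype=int)), CVPlan())


class TestDatasetValidation:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            LabeledDataset(X=np.zeros((4, 2)), y=np.zeros(4))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LabeledDataset(X=np.zeros((4, 2)), y=np.array([0, 1]))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            LabeledDataset(X=np.zeros((5, 2)), y=np.array([0, 0, 0, 0, 1]))


def one_good_feature_dataset(d=20, n_per=20, seed=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, d))
    y = np.repeat([0, 1], n_per)
    X[:, 0] += 20.0 * y  # feature 0 perfectly separates the classes
    return LabeledDataset(X=X, y=y)


class TestRunBsmaFbi:
    plan = CVPlan(folds=5, repeat_runs=1)
    cfg = OptimizerConfig(NP=8, GEN=400, seed=0)

    def test_toy_recovery_vs_brute_force_oracle(self):
        data = one_good_feature_dataset()
        d = data.n_features
        plan = CVPlan(folds=5, repeat_runs=1, split_seed=0)
        # brute-force oracle over all singleton masks
        singles = []
        for j in range(d):
            bits = np.zeros(d, dtype=int)
            bits[j] = 1
            err = knn_error_cv(data, FeatureMask(bits), plan, k=1)
            singles.append(subset_fitness(err, 1, d))
        assert min(singles) == pytest.approx(0.05 / d, abs=1e-12)
        assert int(np.argmin(singles)) == 0

        all_bits = FeatureMask(np.ones(d, dtype=int))
        all_err = knn_error_cv(data, all_bits, plan, k=1)
        all_fitness = subset_fitness(all_err, d, d)

        res = run_bsma_fbi(data, plan, config=self.cfg, k=1, mode="cv", seed=0)
        best = res.runs[0]
        assert best.best_fitness <= all_fitness
        assert best.cv_error == 0.0  # some separating subset was found

    def test_bit_exact_reproducibility(self):
        data = one_good_feature_dataset()
        plan = CVPlan(folds=5, repeat_runs=2)
        r1 = run_bsma_fbi(data, plan, config=self.cfg, mode="cv", seed=5)
        r2 = run_bsma_fbi(data, plan, config=self.cfg, mode="cv", seed=5)
        for a, b in zip(r1.runs, r2.runs):
            assert a.best_fitness == b.best_fitness
            assert np.array_equal(a.best_mask.bits, b.best_mask.bits)
            assert a.trace == b.trace

    def test_bookkeeping_consistency(self):
        data = one_good_feature_dataset()
        res = run_bsma_fbi(data, self.plan, config=self.cfg, mode="cv", seed=1)
        run = res.runs[0]
        assert run.n_selected == run.best_mask.l
        recomputed = subset_fitness(run.cv_error, run.n_selected, data.n_features)
        assert run.best_fitness == pytest.approx(recomputed, abs=1e-12)
        summary = res.summary()
        assert summary["mean_features"] == pytest.approx(
            np.mean([r.n_selected for r in res.runs])
        )

    def test_holdout_mode_reports_test_error(self):
        data = one_good_feature_dataset(n_per=30)
        res = run_bsma_fbi(data, CVPlan(folds=5, repeat_runs=1),
                           config=self.cfg, k=1, mode="holdout", seed=2)
        assert 0.0 <= res.runs[0].reported_error <= 1.0

    def test_bfbi_is_hybrid_without_inspector(self):
        data = one_good_feature_dataset()
        plan = CVPlan(folds=5, repeat_runs=1)
        a = run_bfbi(data, plan, config=self.cfg, mode="cv", seed=3)
        b = run_bsma_fbi(data, plan, config=self.cfg, mode="cv", seed=3, inspector=False)
        assert a.runs[0].best_fitness == b.runs[0].best_fitness
        assert np.array_equal(a.runs[0].best_mask.bits, b.runs[0].best_mask.bits)
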