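"""Distribution-matrix maintenance and alignment transformation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codalign import (
    ClassDistributionMatrix,
    EMAConfig,
    ProbabilityMap,
    align_prediction,
    compute_temperature,
    init_distributions,
    update_labeled_distribution,
    update_unlabeled_distribution,
)
from conftest import random_distribution_matrix, random_simplex


class TestInit:
    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_uniform_rows(self, k):
        M = init_distributions(k)
        assert M.entries.shape == (k, k)
        assert np.all(M.entries == 1.0 / k)

    def test_degenerate_class_count_rejected(self):
        with pytest.raises(ValueError):
            init_distributions(1)


class TestLabeledUpdate:
    def test_alpha_one_is_identity(self, rng):
        M = random_distribution_matrix(rng, 3, "labeled")
        probs = ProbabilityMap(random_simplex(rng, (10,), 3))
        labels = rng.integers(0, 3, 10)
        out = update_labeled_distribution(M, probs, labels, EMAConfig(alpha=1.0))
        np.testing.assert_array_equal(out.entries, M.entries)

    def test_alpha_zero_jumps_to_batch_mean(self, rng):
        M = init_distributions(3)
        vals = random_simplex(rng, (12,), 3)
        labels = np.repeat([0, 1, 2], 4)
        out = update_labeled_distribution(
            M, ProbabilityMap(vals), labels, EMAConfig(alpha=0.0)
        )
        for i in range(3):
            np.testing.assert_allclose(out.entries[i], vals[labels == i].mean(axis=0))

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.99, 1.0])
    def test_constant_batch_closed_form(self, alpha, rng):
        # oracle: iterate the scalar recursion r <- a*r + (1-a)*p
        k = 3
        p = random_simplex(rng, (), k)
        M = random_distribution_matrix(rng, k, "labeled")
        r0 = M.entries[1].copy()
        probs = ProbabilityMap(np.tile(p, (6, 1)))
        labels = np.ones(6, dtype=np.int64)
        expected = r0.copy()
        cfg = EMAConfig(alpha=alpha)
        for n in range(1, 51):
            expected = alpha * expected + (1 - alpha) * p
            M = update_labeled_distribution(M, probs, labels, cfg)
            np.testing.assert_allclose(M.entries[1], p + alpha**n * (r0 - p), atol=1e-9)
            np.testing.assert_allclose(M.entries[1], expected, atol=1e-12)

    def test_absent_class_row_unchanged(self, rng):
        M = random_distribution_matrix(rng, 4, "labeled")
        probs = ProbabilityMap(random_simplex(rng, (5,), 4))
        labels = np.zeros(5, dtype=np.int64)
        out = update_labeled_distribution(M, probs, labels, EMAConfig(alpha=0.5))
        np.testing.assert_array_equal(out.entries[1:], M.entries[1:])
        assert not np.array_equal(out.entries[0], M.entries[0])

    def test_input_not_mutated_and_convexity(self, rng):
        M = random_distribution_matrix(rng, 3, "labeled")
        before = M.entries.copy()
        vals = random_simplex(rng, (8,), 3)
        labels = rng.integers(0, 3, 8)
        out = update_labeled_distribution(M, ProbabilityMap(vals), labels, EMAConfig(alpha=0.7))
        np.testing.assert_array_equal(M.entries, before)
        # updated row lies on the segment between old row and batch mean
        for i in np.unique(labels):
            mean_i = vals[labels == i].mean(axis=0)
            np.testing.assert_allclose(
                out.entries[i], 0.7 * before[i] + 0.3 * mean_i, atol=1e-12
            )

    @pytest.mark.parametrize(
        "bad",
        [
            {"labels": np.zeros(3, dtype=np.int64)},  # shape mismatch
            {"labels": np.array([0, 1, 5, 0, 1])},  # label out of range
        ],
    )
    def test_invalid_arguments(self, bad, rng):
        M = init_distributions(3)
        probs = ProbabilityMap(random_simplex(rng, (5,), 3))
        with pytest.raises(ValueError):
            update_labeled_distribution(M, probs, bad["labels"], EMAConfig())

    def test_role_enforced(self, rng):
        Mu = init_distributions(3, role="unlabeled")
        probs = ProbabilityMap(random_simplex(rng, (5,), 3))
        with pytest.raises(ValueError):
            update_labeled_distribution(Mu, probs, np.zeros(5, dtype=np.int64), EMAConfig())


class TestUnlabeledUpdate:
    def test_all_present_alpha_one_identity(self, rng):
        Mu = random_distribution_matrix(rng, 2, "unlabeled")
        Ml = random_distribution_matrix(rng, 2, "labeled")
        vals = np.array([[0.9, 0.1], [0.2, 0.8]])
        out = update_unlabeled_distribution(Mu, Ml, ProbabilityMap(vals), EMAConfig(alpha=1.0))
        np.testing.assert_array_equal(out.entries, Mu.entries)

    def test_absent_class_branch_worked_example(self):
        # oracle: direct scalar evaluation of the mean-ratio branch
        Ml = ClassDistributionMatrix(np.array([[0.7, 0.3], [0.2, 0.8]]), "labeled")
        Mu = ClassDistributionMatrix(np.array([[0.8, 0.2], [0.25, 0.75]]), "unlabeled")
        # batch of pixels all pseudo-labeled class 0, so class 1 is absent
        vals = np.array([[0.9, 0.1], [0.6, 0.4]])
        out = update_unlabeled_distribution(Mu, Ml, ProbabilityMap(vals), EMAConfig(alpha=1.0))
        ratio = np.mean([[0.8 / 0.7, 0.2 / 0.3], [0.25 / 0.2, 0.75 / 0.8]], axis=0)
        row1 = np.array([0.2, 0.8]) * ratio
        row1 /= row1.sum()
        np.testing.assert_allclose(out.entries[1], row1, atol=1e-6)
        np.testing.assert_allclose(row1, [0.272, 0.728], atol=5e-4)

    def test_present_and_absent_branches_together(self):
        # oracle: hand evaluation of both branches on a 4-pixel batch
        Ml = ClassDistributionMatrix(np.array([[0.6, 0.4], [0.3, 0.7]]), "labeled")
        Mu = ClassDistributionMatrix(np.array([[0.55, 0.45], [0.35, 0.65]]), "unlabeled")
        vals = np.array([[0.8, 0.2], [0.7, 0.3], [0.9, 0.1], [0.6, 0.4]])
        out = update_unlabeled_distribution(Mu, Ml, ProbabilityMap(vals), EMAConfig(alpha=0.0))
        np.testing.assert_allclose(out.entries[0], vals.mean(axis=0), atol=1e-12)
        ratio = np.mean([[0.55 / 0.6, 0.45 / 0.4], [0.35 / 0.3, 0.65 / 0.7]], axis=0)
        row1 = np.array([0.3, 0.7]) * ratio
        np.testing.assert_allclose(out.entries[1], row1 / row1.sum(), atol=1e-6)

    def test_k_mismatch_rejected(self, rng):
        Mu = init_distributions(3, role="unlabeled")
        Ml = init_distributions(4)
        with pytest.raises(ValueError):
            update_unlabeled_distribution(
                Mu, Ml, ProbabilityMap(random_simplex(rng, (4,), 3)), EMAConfig()
            )


class TestTemperature:
    def test_direct_and_clamped_values(self):
        entries = np.array([[0.6, 0.4], [0.0, 1.0]])
        Ml = ClassDistributionMatrix(entries, "labeled")
        cfg = EMAConfig(tau_min=0.05)
        assert compute_temperature(Ml, 0, cfg) == pytest.approx(0.4)
        assert compute_temperature(Ml, 1, cfg) == pytest.approx(0.05)  # 1-1.0 clamped up
        Ml0 = ClassDistributionMatrix(np.array([[0.0, 1.0], [0.5, 0.5]]), "labeled")
        assert compute_temperature(Ml0, 0, cfg) == pytest.approx(1.0)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            compute_temperature(init_distributions(2), 2, EMAConfig())


class TestAlignment:
    def test_uniform_matrices_identity(self, rng):
        k = 4
        Ml = init_distributions(k)
        Mu = init_distributions(k, role="unlabeled")
        vals = random_simplex(rng, (6, 5), k)
        out = align_prediction(ProbabilityMap(vals), Ml, Mu, EMAConfig())
        np.testing.assert_allclose(out.values, vals, atol=1e-9)
        assert out.aligned

    def test_worked_scalar_example(self):
        # oracle: scalar evaluation of the coefficient transformation
        Ml = ClassDistributionMatrix(np.array([[0.6, 0.4], [0.5, 0.5]]), "labeled")
        Mu = ClassDistributionMatrix(np.array([[0.8, 0.2], [0.5, 0.5]]), "unlabeled")
        cfg = EMAConfig(tau_min=0.05, epsilon=1e-8)
        out = align_prediction(ProbabilityMap(np.array([[0.7, 0.3]])), Ml, Mu, cfg)
        tau = 0.4
        w = np.array([0.6**tau / (0.8 + 1e-8), 0.4**tau / (0.2 + 1e-8)])
        expected = np.array([0.7, 0.3]) * w
        expected /= expected.sum()
        np.testing.assert_allclose(out.values[0], expected, atol=1e-9)
        np.testing.assert_allclose(out.values[0], [0.407, 0.593], atol=5e-4)

    def test_output_on_simplex(self, rng):
        k = 5
        Ml = random_distribution_matrix(rng, k, "labeled")
        Mu = random_distribution_matrix(rng, k, "unlabeled")
        out = align_prediction(
            ProbabilityMap(random_simplex(rng, (7, 3), k)), Ml, Mu, EMAConfig()
        )
        np.testing.assert_allclose(out.values.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(out.values >= 0)

    def test_monotone_in_labeled_row_entry(self, rng):
        # raising Ml[i][j] (pre-normalisation) weakly raises aligned prob of j
        k = 3
        Mu = random_distribution_matrix(rng, k, "unlabeled")
        vals = random_simplex(rng, (1,), k)
        i = int(np.argmax(vals[0]))
        base_row = np.array([0.5, 0.3, 0.2])
        lows = []
        for bump in (0.0, 0.2):
            row = base_row.copy()
            row[1] += bump
            entries = np.tile(row / row.sum(), (k, 1))
            Ml = ClassDistributionMatrix(entries, "labeled")
            out = align_prediction(ProbabilityMap(vals), Ml, Mu, EMAConfig())
            lows.append(out.values[0, 1])
        assert lows[1] >= lows[0] - 1e-12

    def test_determinism(self, rng):
        k = 3
        Ml = random_distribution_matrix(rng, k, "labeled")
        Mu = random_distribution_matrix(rng, k, "unlabeled")
        vals = random_simplex(rng, (4, 4), k)
        a = align_prediction(ProbabilityMap(vals), Ml, Mu, EMAConfig())
        b = align_prediction(ProbabilityMap(vals), Ml, Mu, EMAConfig())
        assert np.array_equal(a.values, b.values)

    def test_already_aligned_rejected(self, rng):
        pm = ProbabilityMap(random_simplex(rng, (2,), 2), aligned=True)
        with pytest.raises(ValueError):
            align_prediction(pm, init_distributions(2), init_distributions(2, "unlabeled"), EMAConfig())


class TestInvariants:
    @given(st.integers(2, 8), st.integers(0, 1000))
    def test_simplex_preserved_under_random_updates(self, k, seed):
        rng = np.random.default_rng(seed)
        cfg = EMAConfig(alpha=float(rng.uniform(0, 1)))
        Ml = init_distributions(k)
        Mu = init_distributions(k, role="unlabeled")
        for _ in range(5):
            n = int(rng.integers(1, 20))
            probs = ProbabilityMap(random_simplex(rng, (n,), k))
            labels = rng.integers(0, k, n)  # some classes absent by chance
            Ml = update_labeled_distribution(Ml, probs, labels, cfg)
            Mu = update_unlabeled_distribution(Mu, Ml, probs, cfg)
        for M in (Ml, Mu):
            assert np.all(M.entries >= 0)
            np.testing.assert_allclose(M.entries.sum(axis=1), 1.0, atol=1e-6)


class TestSerialization:
    def test_json_round_trip_lossless(self, rng):
        M = random_distribution_matrix(rng, 5, "unlabeled")
        back = ClassDistributionMatrix.from_json(M.to_json())
        np.testing.assert_allclose(back.entries, M.entries, atol=1e-12)
        assert back.role == M.role and back.num_classes == 5

    def test_shape_disagreement_rejected(self):
        doc = init_distributions(3).to_json().replace('"num_classes": 3', '"num_classes": 4')
        with pytest.raises(ValueError):
            ClassDistributionMatrix.from_json(doc)
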