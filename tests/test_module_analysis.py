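"""Similarity, matching, activation summaries, curve subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synergypipe.nmf_core import ModuleSet
from synergypipe import module_analysis as ma


def make_set(w, p=None, samples_per_cycle=20):
    w = np.asarray(w, dtype=float)
    k = w.shape[1]
    if p is None:
        rng = np.random.default_rng(0)
        p = rng.random((k, samples_per_cycle * 3))
    return ModuleSet(w, np.asarray(p, dtype=float), vaf=0.95, k=k)


class TestSimilarity:
    def test_identical_vectors(self):
        u = np.array([1.0, 2.0, 3.0])
        assert ma.similarity(u, u) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        assert ma.similarity([1, 0, 0], [0, 2, 5]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert ma.similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ma.similarity([0, 0], [1, 1])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 100), min_size=2, max_size=8),
        st.floats(0.001, 1000),
    )
    def test_scale_invariance(self, v, c):
        u = np.linspace(1, 2, len(v))
        assert ma.similarity(u, np.asarray(v)) == pytest.approx(
            ma.similarity(u, c * np.asarray(v)), abs=1e-9
        )


class TestMatchModules:
    def test_permuted_copy_inverts_permutation(self):
        rng = np.random.default_rng(1)
        w = rng.random((8, 4)) + 0.1
        p = rng.random((4, 60))
        perm = np.array([2, 0, 3, 1])
        a = make_set(w, p)
        b = make_set(w[:, perm], p[perm])
        match = ma.match_modules(a, b)
        np.testing.assert_array_equal(match.pairing, np.argsort(perm))
        np.testing.assert_allclose(match.weighting_similarity, 1.0)
        np.testing.assert_allclose(match.activation_similarity, 1.0)

    def test_stable_under_small_noise(self):
        rng = np.random.default_rng(2)
        w = np.eye(4) + 0.05 * rng.random((4, 4))
        p = rng.random((4, 60))
        a = make_set(w, p)
        b = make_set(w + 0.01 * rng.random((4, 4)), p)
        clean = ma.match_modules(a, make_set(w, p)).pairing
        noisy = ma.match_modules(a, b).pairing
        np.testing.assert_array_equal(clean, noisy)

    def test_matching_is_symmetric(self):
        rng = np.random.default_rng(3)
        a = make_set(rng.random((6, 3)) + 0.05)
        b = make_set(rng.random((6, 3)) + 0.05)
        ab = ma.match_modules(a, b).pairing
        ba = ma.match_modules(b, a).pairing
        np.testing.assert_array_equal(ba[ab], np.arange(3))

    def test_orthogonal_sets_flagged_not_similar(self):
        a = make_set(np.vstack([np.eye(3), np.zeros((3, 3))]))
        b = make_set(np.vstack([np.zeros((3, 3)), np.eye(3)]))
        match = ma.match_modules(a, b)
        assert not match.all_similar
        assert np.all(match.weighting_similarity < ma.SIMILARITY_THRESHOLD)

    def test_unequal_k_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            ma.match_modules(
                make_set(rng.random((5, 2)) + 0.1),
                make_set(rng.random((5, 3)) + 0.1),
            )


class TestMeanActivation:
    def test_identical_cycles_mean_equals_single_cycle(self):
        cycle = np.abs(np.sin(np.linspace(0, np.pi, 200)))
        p = np.tile(cycle, 5)[None, :]
        (summary,) = ma.mean_activation(p, 5, 200)
        np.testing.assert_allclose(summary.mean_curve, cycle)

    def test_peak_time_of_constructed_bump(self):
        curve = np.exp(-0.5 * ((np.arange(200) - 60) / 8.0) ** 2)
        p = np.tile(curve, 4)[None, :]
        (summary,) = ma.mean_activation(p, 4, 200)
        assert summary.peak_time_pct == pytest.approx(30.0)
        assert summary.peak_value == pytest.approx(1.0)

    def test_peak_time_tracks_generator_centers(self, default_matrix):
        _, _, truth = default_matrix
        cfg = truth.config
        summaries = ma.mean_activation(
            truth.activations_true, cfg.n_cycles, cfg.samples_per_cycle
        )
        for summary, burst in zip(summaries, cfg.bursts):
            d = abs(summary.peak_time_pct - 100 * burst.center)
            assert min(d, 100 - d) <= 2.0

    def test_shifted_curve_shifts_peak_time(self):
        curve = np.exp(-0.5 * ((np.arange(200) - 60) / 8.0) ** 2)
        shifted = np.roll(curve, 30)
        s0 = ma.mean_activation(np.tile(curve, 2)[None, :], 2, 200)[0]
        s1 = ma.mean_activation(np.tile(shifted, 2)[None, :], 2, 200)[0]
        assert s1.peak_time_pct - s0.peak_time_pct == pytest.approx(15.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ma.mean_activation(np.ones((2, 100)), 3, 200)


class TestCurveSubtraction:
    def test_equal_curves_give_zeros(self):
        c = np.random.default_rng(0).random(200)
        np.testing.assert_allclose(ma.curve_subtraction(c, c), 0.0)

    def test_zero_reference_returns_curve(self):
        c = np.random.default_rng(1).random(200)
        np.testing.assert_allclose(ma.curve_subtraction(c, np.zeros(200)), c)

    def test_offset_bumps_give_symmetric_two_lobes(self):
        t = np.arange(200)
        a = np.exp(-0.5 * ((t - 80) / 5.0) ** 2)
        b = np.exp(-0.5 * ((t - 110) / 5.0) ** 2)
        diff = ma.curve_subtraction(a, b)
        assert diff.max() == pytest.approx(a.max(), rel=0.05)
        # symmetric two-lobed shape about the midpoint between the centers
        mid = 95
        np.testing.assert_allclose(
            diff[mid - 40 : mid], diff[mid + 1 : mid + 41][::-1], atol=1e-9
        )
        assert diff[mid] < 0.05 * diff.max()


class TestInterSubjectSimilarity:
    def test_identical_sets_have_mean_one_sd_zero(self):
        rng = np.random.default_rng(5)
        w = rng.random((8, 3)) + 0.1
        sets = [make_set(w) for _ in range(4)]
        mean, sd, _ = ma.inter_subject_similarity(sets)
        np.testing.assert_allclose(mean, 1.0)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_three_sets_give_three_pairs(self):
        rng = np.random.default_rng(6)
        sets = [make_set(rng.random((8, 3)) + 0.1) for _ in range(3)]
        _, _, raw = ma.inter_subject_similarity(sets)
        assert raw.shape == (3, 3)

    def test_similarity_decreases_with_noise(self):
        rng = np.random.default_rng(7)
        base = rng.random((8, 3)) + 0.2
        means = []
        for noise in (0.05, 0.5, 2.0):
            sets = [
                make_set(base + noise * rng.random((8, 3))) for _ in range(4)
            ]
            means.append(ma.inter_subject_similarity(sets)[0].mean())
        assert means[0] > means[1] > means[2]

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            ma.inter_subject_similarity([make_set(np.ones((4, 2)))])
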