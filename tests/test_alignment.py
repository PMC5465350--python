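import numpy as np
import pytest

from shapealign.alignment import (
    AlignmentConfig,
    align_class,
    best_shift,
    find_centroid,
    pair_similarity,
    site_vector,
)
from shapealign.shapes import ShapeWindow

from conftest import random_window
from naive_oracles import naive_best_shift


def window_from(features, site_id="w"):
    features = np.asarray(features, dtype=float)
    return ShapeWindow(site_id=site_id, features=features,
                       center_index=features.shape[1] // 2)


def displaced_copy(window, delta, site_id):
    """Same underlying signal, sampled with the content moved right by delta."""
    return ShapeWindow(site_id=site_id, features=np.roll(window.features, delta, axis=1),
                       center_index=window.center_index)


class TestConfig:
    def test_defaults_are_the_standard_parameters(self):
        config = AlignmentConfig()
        assert (config.max_shift, config.align_window, config.center_exclusion) == (25, 90, 5)
        assert config.vector_length == 4 * (90 - 5) == 340

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            AlignmentConfig().validate_window(120)

    def test_even_center_exclusion_rejected(self):
        with pytest.raises(ValueError):
            AlignmentConfig(center_exclusion=4)

    def test_tie_break_scan_order(self):
        assert AlignmentConfig(max_shift=2).shift_order() == [0, -1, 1, -2, 2]


class TestSiteVector:
    def test_length_at_defaults(self):
        rng = np.random.default_rng(0)
        vec = site_vector(random_window(rng, width=201), AlignmentConfig())
        assert vec.shape == (340,)

    def test_constant_window_standardizes_to_zero(self):
        window = window_from(np.full((4, 201), 7.0))
        assert not site_vector(window, AlignmentConfig()).any()

    def test_mirror_windows_give_mirror_vectors(self):
        """A palindromic window yields mirror-image vectors at opposite shifts."""
        rng = np.random.default_rng(1)
        half = rng.normal(size=(4, 100))
        sym = np.concatenate([half, rng.normal(size=(4, 1)), half[:, ::-1]], axis=1)
        window = window_from(sym)
        # odd interval + 1-bp mask so mirroring maps shift +s exactly to -s
        config = AlignmentConfig(align_window=91, center_exclusion=1)
        plus = site_vector(window, config, 7)
        minus = site_vector(window, config, -7)
        assert np.allclose(plus.reshape(4, -1), minus.reshape(4, -1)[:, ::-1])

    def test_shift_beyond_limit_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="max_shift"):
            site_vector(random_window(rng, width=201), AlignmentConfig(), 26)


class TestBestShift:
    def test_identical_windows(self):
        rng = np.random.default_rng(3)
        a = random_window(rng, width=201)
        b = ShapeWindow("b", a.features.copy(), a.center_index)
        shift, sim = best_shift(a, b)
        assert shift == 0
        assert sim == pytest.approx(1.0)

    @pytest.mark.parametrize("delta", [-13, -7, 7, 25])
    def test_planted_displacement_recovered(self, delta):
        rng = np.random.default_rng(4)
        a = random_window(rng, width=201)
        b = displaced_copy(a, delta, "b")
        shift, sim = best_shift(a, b)
        assert shift == delta
        assert sim > 0.99

    def test_unrecoverable_displacement_stays_bounded(self):
        rng = np.random.default_rng(5)
        a = random_window(rng, width=201)
        b = displaced_copy(a, 30, "b")
        shift, sim = best_shift(a, b)
        assert -25 <= shift <= 25
        assert sim < 0.9

    def test_zero_variance_similarity_is_zero(self):
        rng = np.random.default_rng(6)
        flat = window_from(np.full((4, 201), 3.0), "flat")
        shift, sim = best_shift(random_window(rng, width=201), flat)
        assert (shift, sim) == (0, 0.0)

    def test_swap_symmetry_is_approximate(self):
        """Swapping the pair negates the shift; similarity agrees closely."""
        rng = np.random.default_rng(7)
        a = random_window(rng, width=201)
        b = displaced_copy(a, 9, "b")
        s_ab, sim_ab = best_shift(a, b)
        s_ba, sim_ba = best_shift(b, a)
        assert s_ba == -s_ab
        assert sim_ba == pytest.approx(sim_ab, abs=0.05)

    def test_agrees_exactly_with_naive_enumeration(self):
        """Vectorized search equals an independent pure-Python double loop."""
        rng = np.random.default_rng(8)
        config = AlignmentConfig()
        for _ in range(25):
            a, b = random_window(rng), random_window(rng)
            expected = naive_best_shift(a.features.tolist(), a.center_index,
                                        b.features.tolist(), b.center_index,
                                        config.max_shift, config.align_window,
                                        config.center_exclusion)
            shift, sim = best_shift(a, b, config)
            assert shift == expected[0]
            assert sim == pytest.approx(expected[1], abs=1e-9)

    def test_pair_similarity_matches_best_shift_at_argmax(self):
        rng = np.random.default_rng(9)
        a, b = random_window(rng), random_window(rng)
        shift, sim = best_shift(a, b)
        assert pair_similarity(a, b, shift) == pytest.approx(sim)


class TestCentroid:
    def test_single_window(self):
        rng = np.random.default_rng(10)
        w = random_window(rng, width=201)
        assert find_centroid([w]) == w.site_id

    def test_identical_pair_beats_noise_with_lexicographic_tie(self):
        rng = np.random.default_rng(11)
        template = random_window(rng, width=201)
        twin_b = ShapeWindow("site_b", template.features.copy(), template.center_index)
        twin_a = ShapeWindow("site_a", template.features.copy(), template.center_index)
        noise = ShapeWindow("site_z", rng.normal(size=(4, 201)), 100)
        assert find_centroid([noise, twin_b, twin_a]) == "site_a"

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        windows = [random_window(rng, width=201) for _ in range(6)]
        assert find_centroid(windows) == find_centroid(list(reversed(windows)))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            find_centroid([])

    def test_literal_similarity_objective_differs(self):
        """The literal minimum-similarity reading picks an outlier, not the centre."""
        rng = np.random.default_rng(13)
        template = random_window(rng, width=201)
        twins = [ShapeWindow(f"t{i}", template.features + rng.normal(0, 0.05, (4, 201)),
                             template.center_index) for i in range(3)]
        outlier = ShapeWindow("outlier", rng.normal(size=(4, 201)), 100)
        windows = twins + [outlier]
        assert find_centroid(windows) != "outlier"
        literal = AlignmentConfig(centroid_objective="similarity")
        assert find_centroid(windows, literal) == "outlier"


class TestAlignClass:
    def test_planted_shifts_cancelled_exactly(self):
        """Displaced copies of one template realign to a common frame."""
        rng = np.random.default_rng(14)
        template = random_window(rng, width=201)
        deltas = [-10, -6, -2, 0, 2, 6, 10]
        windows = [displaced_copy(template, d, f"site_{i}") for i, d in enumerate(deltas)]
        result = align_class(windows)
        recovered = np.array([result.shifts[f"site_{i}"] for i in range(len(deltas))])
        assert np.array_equal(recovered, np.array(deltas))
        # the aligned average reproduces the template over the interval
        lo = template.center_index - result.config.half
        expected = template.features[:, lo:lo + result.config.align_window]
        assert np.allclose(result.class_average, expected, atol=1e-12)
        assert np.allclose(result.class_sem, 0.0, atol=1e-12)

    def test_single_site_class(self):
        rng = np.random.default_rng(15)
        w = random_window(rng, width=201)
        result = align_class([w])
        lo = w.center_index - result.config.half
        assert np.allclose(result.class_average,
                           w.features[:, lo:lo + result.config.align_window])
        assert np.allclose(result.class_sem, 0.0)

    def test_average_equals_column_mean_and_sem_nonnegative(self, default_alignments):
        _, results = default_alignments
        for result in results.values():
            assert np.allclose(result.class_average, result.aligned_matrix.mean(axis=0))
            assert (result.class_sem >= 0).all()

    def test_pure_noise_class_shifts_spread_and_average_shrinks(self):
        """Noise classes pick near-uniform shifts; averaging cancels amplitude."""
        rng = np.random.default_rng(16)
        windows = [random_window(rng, width=201) for _ in range(60)]
        result = align_class(windows)
        shifts = np.abs(np.fromiter(result.shifts.values(), dtype=float))
        # E|s| for uniform on [-25, 25] is 12.75; noise argmax is near-uniform
        assert 8.0 < shifts.mean() < 18.0
        single_sd = np.std(windows[0].features)
        assert result.class_average.std() < 2.5 * single_sd / np.sqrt(60)

    def test_shifts_table_round_trip(self, default_alignments):
        _, results = default_alignments
        table = results["fast"].shifts_table()
        assert set(table.columns) == {"site_id", "shift", "similarity"}
        assert len(table) == len(results["fast"].site_ids)
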