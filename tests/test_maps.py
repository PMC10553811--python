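"""Map containers, the minimal-trial formula, alignment and metrics."""

import itertools

import numpy as np
import pytest

from pairseg import (
    GridSpec,
    ProbabilisticMaps,
    SegmentationMap,
    align_labels,
    count_nonempty_segments,
    entropy_map,
    mean_absolute_error,
    minimal_trials,
    read_probmaps,
    read_segmentation,
    to_segmentation,
    write_probmaps,
    write_segmentation,
)


class TestMinimalTrials:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(5, 16, 1024), (2, 11, 121), (2, 3, 9), (3, 19, 722)],
    )
    def test_formula(self, k, n, expected):
        assert minimal_trials(k, n) == expected

    @pytest.mark.parametrize("k, n", [(1, 10), (0, 10), (2, 2), (2, 1)])
    def test_domain_errors(self, k, n):
        with pytest.raises(ValueError):
            minimal_trials(k, n)


class TestContainers:
    def test_grid_requires_n_at_least_3(self):
        with pytest.raises(ValueError):
            GridSpec(2)

    def test_rows_must_sum_to_one(self):
        bad = np.full((3, 3, 2), 0.4)
        with pytest.raises(ValueError):
            ProbabilisticMaps.from_values(bad)

    def test_values_must_be_probabilities(self):
        bad = np.zeros((3, 3, 2))
        bad[..., 0] = 1.5
        bad[..., 1] = -0.5
        with pytest.raises(ValueError):
            ProbabilisticMaps.from_values(bad)

    def test_normalize_constructor(self, rng):
        raw = rng.random((4, 4, 3))
        maps = ProbabilisticMaps.from_values(raw, normalize=True)
        assert np.allclose(maps.values.sum(axis=-1), 1.0, atol=1e-9)

    def test_one_hot_roundtrip(self, rng):
        labels = rng.integers(1, 4, size=(5, 5))
        maps = ProbabilisticMaps.one_hot(labels, 3)
        assert np.array_equal(to_segmentation(maps).labels, labels)

    def test_labels_are_one_based(self):
        with pytest.raises(ValueError):
            SegmentationMap(GridSpec(3), np.zeros((3, 3), dtype=int))


class TestToSegmentation:
    def test_unique_argmax(self):
        values = np.tile([0.1, 0.7, 0.2], (3, 3, 1))
        maps = ProbabilisticMaps.from_values(values)
        assert np.all(to_segmentation(maps).labels == 2)

    def test_tie_breaks_to_smallest_label(self):
        values = np.tile([0.5, 0.5], (3, 3, 1))
        maps = ProbabilisticMaps.from_values(values)
        assert np.all(to_segmentation(maps).labels == 1)


class TestAlignment:
    def test_identity(self, random_maps):
        assert align_labels(random_maps, random_maps) == (0, 1, 2)

    def test_swap_recovered(self, random_maps):
        swapped = ProbabilisticMaps.from_values(random_maps.values[..., [1, 0, 2]])
        assert align_labels(random_maps, swapped) == (1, 0, 2)

    def test_rotation_matches_brute_force(self, random_maps):
        rotated = ProbabilisticMaps.from_values(random_maps.values[..., [2, 0, 1]])
        perm = align_labels(random_maps, rotated)
        # independent exhaustive search over all K! permutations
        best, best_cost = None, np.inf
        for cand in itertools.permutations(range(3)):
            cost = np.abs(
                random_maps.values - rotated.values[..., list(cand)]
            ).sum()
            if cost < best_cost - 1e-12:
                best, best_cost = cand, cost
        assert perm == best
        assert mean_absolute_error(random_maps, rotated, align=True) < 1e-12

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_aligned_mae_is_permutation_invariant(self, rng, k):
        values = rng.dirichlet(np.ones(k), size=16).reshape(4, 4, k)
        ref = ProbabilisticMaps.from_values(values)
        est = ProbabilisticMaps.from_values(
            rng.dirichlet(np.ones(k), size=16).reshape(4, 4, k)
        )
        base = mean_absolute_error(est, ref, align=True)
        for perm in itertools.permutations(range(k)):
            shuffled = ProbabilisticMaps.from_values(est.values[..., list(perm)])
            assert mean_absolute_error(shuffled, ref, align=True) == pytest.approx(
                base, abs=1e-12
            )


class TestMeanAbsoluteError:
    def test_zero_on_identical(self, random_maps):
        assert mean_absolute_error(random_maps, random_maps) == 0.0

    def test_alignment_fixes_channel_swap(self):
        a = ProbabilisticMaps.from_values(np.tile([1.0, 0.0], (3, 3, 1)))
        b = ProbabilisticMaps.from_values(np.tile([0.0, 1.0], (3, 3, 1)))
        assert mean_absolute_error(a, b, align=True) == 0.0
        assert mean_absolute_error(a, b, align=False) == 2.0

    def test_half_vs_onehot(self):
        a = ProbabilisticMaps.from_values(np.tile([1.0, 0.0], (3, 3, 1)))
        b = ProbabilisticMaps.from_values(np.tile([0.5, 0.5], (3, 3, 1)))
        for align in (True, False):
            assert mean_absolute_error(a, b, align=align) == pytest.approx(1.0)

    def test_pseudometric_on_random_triples(self, rng):
        def rand():
            return ProbabilisticMaps.from_values(
                rng.dirichlet(np.ones(3), size=25).reshape(5, 5, 3)
            )

        for _ in range(10):
            a, b, c = rand(), rand(), rand()
            dab = mean_absolute_error(a, b)
            assert dab >= 0
            assert dab == pytest.approx(mean_absolute_error(b, a), abs=1e-12)
            assert mean_absolute_error(a, c) <= dab + mean_absolute_error(b, c) + 1e-9

    def test_mismatched_maps_rejected(self, random_maps):
        other = ProbabilisticMaps.from_values(
            np.full((6, 6, 2), 0.5)
        )
        with pytest.raises(ValueError):
            mean_absolute_error(random_maps, other)


class TestEntropy:
    def test_one_hot_is_zero(self):
        maps = ProbabilisticMaps.one_hot(np.ones((4, 4), dtype=int), 3)
        field, summary = entropy_map(maps)
        assert np.all(field.values == 0)
        assert summary["mean"] == 0.0

    @pytest.mark.parametrize("k", [2, 4])
    def test_uniform_reaches_log_k(self, k):
        maps = ProbabilisticMaps.from_values(np.full((3, 3, k), 1.0 / k))
        field, summary = entropy_map(maps)
        assert np.allclose(field.values, np.log(k), atol=1e-12)
        assert summary["sem"] == pytest.approx(0.0, abs=1e-12)

    def test_bounds_on_random_maps(self, rng):
        for k in (2, 3, 5):
            maps = ProbabilisticMaps.from_values(
                rng.dirichlet(np.ones(k), size=49).reshape(7, 7, k)
            )
            field, _ = entropy_map(maps)
            assert np.all(field.values >= 0)
            assert np.all(field.values <= np.log(k) + 1e-12)


class TestCountNonempty:
    def test_padded_one_hot(self):
        labels = np.array([[1, 2, 3]] * 3)
        values = np.zeros((3, 3, 5))
        values[..., :3] = np.eye(3)[labels - 1]
        maps = ProbabilisticMaps.from_values(values)
        assert count_nonempty_segments(maps) == 3

    def test_uniform_counts_all(self):
        maps = ProbabilisticMaps.from_values(np.full((3, 3, 4), 0.25))
        assert count_nonempty_segments(maps, mass_threshold=0.2) == 4

    def test_threshold_cuts_weak_channels(self):
        values = np.zeros((3, 3, 3))
        values[..., 0] = 0.7
        values[..., 2] = 0.3
        values[0, 0] = [1.0, 0.0, 0.0]
        values[0, 1] = [0.0, 1.0, 0.0]
        maps = ProbabilisticMaps.from_values(values)
        assert count_nonempty_segments(maps, mass_threshold=0.99) == 2

    def test_threshold_domain(self, random_maps):
        with pytest.raises(ValueError):
            count_nonempty_segments(random_maps, mass_threshold=1.5)


class TestSerialization:
    def test_probmaps_roundtrip(self, tmp_path, random_maps):
        write_probmaps(random_maps, tmp_path, stem="m")
        back = read_probmaps(tmp_path, stem="m")
        assert np.allclose(back.values, random_maps.values, atol=1e-9)

    def test_segmentation_roundtrip(self, tmp_path, random_maps):
        seg = to_segmentation(random_maps)
        write_segmentation(seg, tmp_path / "seg.csv")
        back = read_segmentation(tmp_path / "seg.csv")
        assert np.array_equal(back.labels, seg.labels)
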