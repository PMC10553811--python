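"""Synthetic ground truths, simulated observers, textures and boundaries."""

import numpy as np
import pytest

from pairseg import (
    GridSpec,
    PairSet,
    RegularizerConfig,
    SolverConfig,
    TextureSpec,
    UncertaintyProfile,
    entropy_map,
    fit_nonparametric,
    sample_boundary,
    sample_probmaps,
    schedule_pairs,
    simulate_responses,
    soften_labels,
    synthesize_composite_texture,
)
from pairseg.features import orientation_energy_features


class TestSampleProbmaps:
    def test_level_zero_is_deterministic(self):
        maps = sample_probmaps(GridSpec(8), 3, UncertaintyProfile(level=0.0), seed=0)
        field, summary = entropy_map(maps)
        assert summary["mean"] == 0.0
        assert set(np.unique(maps.values)) <= {0.0, 1.0}

    def test_maximal_level_with_huge_scale_is_uniform(self):
        maps = sample_probmaps(
            GridSpec(8), 4, UncertaintyProfile(level=1.0, spatial_scale=100.0), seed=0
        )
        assert np.allclose(maps.values, 0.25, atol=0.05)
        _, summary = entropy_map(maps)
        assert summary["mean"] == pytest.approx(np.log(4), abs=0.02)

    def test_entropy_monotone_in_level(self):
        means = []
        for level in (0.0, 0.25, 0.5, 0.75, 1.0):
            maps = sample_probmaps(
                GridSpec(10), 3, UncertaintyProfile(level, 1.5), seed=7
            )
            means.append(entropy_map(maps)[1]["mean"])
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_all_segments_present(self):
        for seed in range(5):
            maps = sample_probmaps(GridSpec(10), 5, UncertaintyProfile(0.0), seed=seed)
            labels = np.argmax(maps.values, axis=-1)
            assert len(np.unique(labels)) == 5

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError):
            sample_probmaps(GridSpec(3), 10, UncertaintyProfile(0.0), seed=0)

    def test_invalid_profile(self):
        with pytest.raises(ValueError):
            UncertaintyProfile(level=1.5)
        with pytest.raises(ValueError):
            UncertaintyProfile(spatial_scale=0.0)


class TestSimulateResponses:
    def test_one_hot_pairs_are_deterministic(self):
        grid = GridSpec(4)
        labels = np.ones((4, 4), dtype=int)
        labels[2:] = 2
        maps = soften_labels(labels, 2, level=0.0, spatial_scale=1.0)
        same = PairSet(grid, np.array([[0, 1]]))       # both segment 1
        diff = PairSet(grid, np.array([[0, 15]]))      # across segments
        ds_same = simulate_responses(maps, same, n_blocks=20, seed=0)
        ds_diff = simulate_responses(maps, diff, n_blocks=20, seed=0)
        assert np.all(ds_same.response == 1)
        assert np.all(ds_diff.response == 0)

    def test_binomial_convergence_at_half(self):
        grid = GridSpec(3)
        values = np.full((3, 3, 2), 0.5)
        values[0, 0] = [1.0, 0.0]
        values[0, 1] = [0.5, 0.5]  # q(0,1) with (1,0): 0.5
        from pairseg import ProbabilisticMaps

        maps = ProbabilisticMaps.from_values(values)
        ps = PairSet(grid, np.array([[0, 1]]))
        ds = simulate_responses(maps, ps, n_blocks=10000, seed=42)
        assert abs(ds.response.mean() - 0.5) < 0.02

    def test_reproducible_given_seed(self, moderate_truth):
        ps = schedule_pairs(moderate_truth.grid, 3, seed=1)
        a = simulate_responses(moderate_truth, ps, n_blocks=3, seed=9)
        b = simulate_responses(moderate_truth, ps, n_blocks=3, seed=9)
        assert np.array_equal(a.response, b.response)


class TestSampleBoundary:
    def test_area_fraction_constraint(self):
        for seed in range(100):
            mask = sample_boundary(64, smoothness=2.0, seed=seed)
            assert 0.25 <= mask.mean() <= 0.75

    def test_high_smoothness_is_nearly_straight(self):
        mask = sample_boundary(64, smoothness=1000.0, seed=1)
        # boundary row per column varies by at most a couple of pixels
        boundary_rows = mask.sum(axis=0)
        assert boundary_rows.max() - boundary_rows.min() <= 3

    def test_seeds_differ(self):
        a = sample_boundary(64, smoothness=2.0, seed=0)
        b = sample_boundary(64, smoothness=2.0, seed=1)
        assert np.any(a != b)


class TestCompositeTexture:
    def test_output_range_and_mask(self):
        image, mask = synthesize_composite_texture(TextureSpec(size=64), seed=0)
        assert image.shape == (64, 64)
        assert image.min() >= 0.0 and image.max() <= 1.0
        assert mask.dtype == bool

    def test_identical_specs_give_matching_statistics(self):
        spec = TextureSpec(
            size=128,
            center_orientations=(90.0, 90.0),
            orientation_bandwidths=(10.0, 10.0),
        )
        image, mask = synthesize_composite_texture(spec, seed=3)
        fm = orientation_energy_features(image, GridSpec(8), 36, 3)
        cell_mask = mask[8::16, 8::16]
        p1 = fm.values[cell_mask].mean(axis=0)
        p2 = fm.values[~cell_mask].mean(axis=0)
        # same spectral content on both sides: normalized profiles agree
        p1, p2 = p1 / p1.sum(), p2 / p2.sum()
        assert np.abs(p1 - p2).sum() < 0.25

    def test_energy_peaks_near_spec_orientations(self):
        spec = TextureSpec(
            size=128,
            center_orientations=(80.0, 100.0),
            orientation_bandwidths=(6.0, 6.0),
        )
        image, mask = synthesize_composite_texture(spec, seed=0)
        fm = orientation_energy_features(image, GridSpec(8), 36, 3)
        cell_mask = mask[8::16, 8::16]
        peak1 = np.argmax(fm.values[cell_mask].mean(axis=0)) * 5
        peak2 = np.argmax(fm.values[~cell_mask].mean(axis=0)) * 5
        assert abs(peak1 - 80.0) <= 5.0
        assert abs(peak2 - 100.0) <= 5.0

    def test_bandwidth_controls_profile_overlap(self):
        def overlap(bw):
            spec = TextureSpec(
                size=128,
                center_orientations=(80.0, 100.0),
                orientation_bandwidths=(bw, bw),
            )
            image, mask = synthesize_composite_texture(spec, seed=5)
            fm = orientation_energy_features(image, GridSpec(8), 36, 3)
            cell_mask = mask[8::16, 8::16]
            p1 = fm.values[cell_mask].mean(axis=0)
            p2 = fm.values[~cell_mask].mean(axis=0)
            p1, p2 = p1 / p1.sum(), p2 / p2.sum()
            return float(np.sqrt(p1 * p2).sum())  # Bhattacharyya coefficient

        assert overlap(25.0) > overlap(6.0)

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            TextureSpec(orientation_bandwidths=(0.0, 8.0))


class TestEndToEnd:
    def test_boundary_uncertainty_concentrates_entropy(self):
        # simulated observer on a mask-derived truth: fitted entropy is
        # larger in the boundary band than in the segment interiors
        n = 8
        mask = sample_boundary(64, smoothness=5.0, seed=2)
        cell_labels = np.where(mask[4::8, 4::8], 1, 2)
        # blur of ~1 cell at the boundary, mild uniform mixing elsewhere
        truth = soften_labels(cell_labels, 2, level=0.3, spatial_scale=3.0)
        grid = truth.grid
        pairset = schedule_pairs(grid, 2, seed=3)
        ds = simulate_responses(truth, pairset, n_blocks=20, seed=4)
        fit = fit_nonparametric(
            ds, 2, reg=RegularizerConfig(lam=0.0), solver=SolverConfig(max_iter=2000)
        )
        ent = entropy_map(fit.maps)[0].values
        # boundary band: cells adjacent to a label change in the truth
        lab = cell_labels
        edge = np.zeros_like(lab, dtype=bool)
        edge[:-1] |= lab[:-1] != lab[1:]
        edge[1:] |= lab[:-1] != lab[1:]
        edge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
        edge[:, 1:] |= lab[:, :-1] != lab[:, 1:]
        assert ent[edge].mean() > ent[~edge].mean()
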