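"""Exponentiated-gradient solver: recovery, invariants, bootstrap."""

import itertools

import numpy as np
import pytest

from pairseg import (
    ExponentiatedGradientSegmenter,
    GridSpec,
    PairSet,
    RegularizerConfig,
    ResponseDataset,
    SolverConfig,
    UncertaintyProfile,
    align_labels,
    bootstrap_fit,
    empirical_proportions,
    fit_nonparametric,
    mean_absolute_error,
    sample_probmaps,
    schedule_pairs,
    simulate_responses,
    to_segmentation,
)


def _labels_match(fit_maps, truth):
    perm = np.array(align_labels(fit_maps, truth))
    fitted = to_segmentation(fit_maps).labels
    return np.array_equal(perm[fitted - 1] + 1, to_segmentation(truth).labels)


class TestDeterministicRecovery:
    def test_noiseless_truth_recovered_exactly(self):
        grid = GridSpec(8)
        truth = sample_probmaps(grid, 3, UncertaintyProfile(level=0.0), seed=2)
        pairset = schedule_pairs(grid, 3, seed=3)
        ds = simulate_responses(truth, pairset, n_blocks=1, seed=4)
        result = fit_nonparametric(ds, 3, reg=RegularizerConfig(lam=1.0))
        assert _labels_match(result.maps, truth)

    def test_k1_degenerate_case(self, small_dataset):
        _, ds = small_dataset
        result = fit_nonparametric(ds, 1)
        assert np.all(result.maps.values == 1.0)
        assert result.converged


class TestSolverInvariants:
    def test_iterates_stay_on_simplex(self, small_dataset):
        # stopping the solver at any iteration count yields valid maps,
        # so every iterate satisfies the simplex constraints
        _, ds = small_dataset
        for max_iter in (1, 2, 5, 20):
            result = fit_nonparametric(
                ds, 3, solver=SolverConfig(max_iter=max_iter, stop_eps=1e-16)
            )
            sums = result.maps.values.sum(axis=-1)
            assert np.allclose(sums, 1.0, atol=1e-9)
            assert result.maps.values.min() >= 0

    def test_adaptive_trace_is_monotone(self, small_dataset):
        _, ds = small_dataset
        result = fit_nonparametric(ds, 3, reg=RegularizerConfig(lam=10.0))
        diffs = np.diff(result.loss_trace)
        assert np.all(diffs <= 1e-9)

    def test_fixed_rate_monotone_for_small_step(self, small_dataset):
        _, ds = small_dataset
        result = fit_nonparametric(
            ds,
            3,
            reg=RegularizerConfig(lam=10.0),
            solver=SolverConfig(learning_rate=0.01, adaptive=False, max_iter=300),
        )
        assert np.all(np.diff(result.loss_trace) <= 1e-9)

    def test_convergence_flag_matches_trace(self, small_dataset):
        _, ds = small_dataset
        result = fit_nonparametric(ds, 3, reg=RegularizerConfig(lam=10.0))
        if result.converged:
            assert abs(result.loss_trace[-1] - result.loss_trace[-2]) <= 1e-8

    def test_uncovered_elements_warned(self):
        grid = GridSpec(3)
        ds = ResponseDataset(
            grid=grid,
            block=np.zeros(2, dtype=int),
            i_idx=np.array([0, 2]),
            j_idx=np.array([1, 3]),
            response=np.array([1, 0]),
        )
        with pytest.warns(UserWarning, match="not covered"):
            result = fit_nonparametric(ds, 2, solver=SolverConfig(max_iter=50))
        assert len(result.uncovered) == 5

    def test_mae_can_rise_while_loss_falls_unregularized(self, moderate_truth):
        # with limited data and no regularization, optimizing the data
        # loss further degrades the maps
        grid = moderate_truth.grid
        pairset = schedule_pairs(grid, 3, seed=11)
        ds = simulate_responses(moderate_truth, pairset, n_blocks=10, seed=12)
        early = fit_nonparametric(
            ds, 3, reg=RegularizerConfig(lam=0.0), solver=SolverConfig(max_iter=50)
        )
        late = fit_nonparametric(
            ds, 3, reg=RegularizerConfig(lam=0.0), solver=SolverConfig(max_iter=4000)
        )
        assert late.final_loss < early.final_loss
        assert mean_absolute_error(late.maps, moderate_truth) > mean_absolute_error(
            early.maps, moderate_truth
        )


class TestSmallInstanceFit:
    def test_exhaustive_design_fits_proportions(self):
        # all 36 pairs of a 3x3 grid, many blocks: the fitted pair
        # probabilities track the empirical proportions closely
        grid = GridSpec(3)
        truth = sample_probmaps(grid, 2, UncertaintyProfile(0.4, 1.0), seed=5)
        pairs = np.array(list(itertools.combinations(range(9), 2)))
        ds = simulate_responses(truth, PairSet(grid, pairs), n_blocks=1024, seed=6)
        result = fit_nonparametric(
            ds,
            2,
            reg=RegularizerConfig(lam=0.0),
            solver=SolverConfig(max_iter=30000, stop_eps=1e-13),
        )
        prop = empirical_proportions(ds)
        flat = result.maps.flat()
        q = np.einsum("ij,ij->i", flat[prop.i_idx], flat[prop.j_idx])
        assert np.abs(q - prop.proportion).max() <= 0.05


class TestEstimatorInterface:
    def test_sklearn_get_set_params(self):
        est = ExponentiatedGradientSegmenter(n_segments=4, reg_lambda=5.0)
        params = est.get_params()
        assert params["n_segments"] == 4
        est.set_params(reg_lambda=0.0)
        assert est.reg_lambda == 0.0

    def test_fitted_attributes(self, small_dataset):
        _, ds = small_dataset
        est = ExponentiatedGradientSegmenter(
            n_segments=3, reg_lambda=10.0, max_iter=500
        ).fit(ds)
        assert est.maps_.n_segments == 3
        assert est.labels_.shape == (6, 6)
        assert est.n_iter_ >= 1
        assert est.score(ds) <= 0.0

    def test_clone_compatible(self, small_dataset):
        from sklearn.base import clone

        est = clone(ExponentiatedGradientSegmenter(n_segments=3, max_iter=100))
        _, ds = small_dataset
        est.fit(ds)
        assert hasattr(est, "maps_")


class TestBootstrap:
    def test_identical_resample_seeds_zero_width(self):
        grid = GridSpec(6)
        truth = sample_probmaps(grid, 2, UncertaintyProfile(0.3), seed=3)
        br = bootstrap_fit(
            truth,
            n_resamples=2,
            resample_seeds=[7, 7],
            n_blocks=1,
            reg=RegularizerConfig(lam=1.0),
            solver=SolverConfig(max_iter=500),
        )
        assert br.mae_ci[0] == br.mae_ci[1]
        assert br.loss_ci[0] == br.loss_ci[1]

    def test_noiseless_truth_small_error(self):
        grid = GridSpec(8)
        truth = sample_probmaps(grid, 2, UncertaintyProfile(level=0.0), seed=3)
        br = bootstrap_fit(
            truth,
            n_resamples=4,
            seed=0,
            n_blocks=1,
            reg=RegularizerConfig(lam=1.0),
            solver=SolverConfig(max_iter=3000),
        )
        assert br.mae_mean < 0.15

    def test_interval_shrinks_with_blocks(self, moderate_truth):
        widths = []
        for nb in (1, 10):
            br = bootstrap_fit(
                moderate_truth,
                n_resamples=12,
                seed=5,
                n_blocks=nb,
                reg=RegularizerConfig(lam=10.0),
                solver=SolverConfig(max_iter=2000),
            )
            widths.append(br.mae_ci[1] - br.mae_ci[0])
        assert widths[1] < widths[0]
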