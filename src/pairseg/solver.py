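"""Non-parametric inference by exponentiated gradient descent.

The maps are treated as free simplex-constrained parameters, one K-vector
per grid element, and fitted by multiplicative (exponentiated-gradient)
updates::

    p <- p * exp(-lr * grad(loss))
    p <- p / sum_k p[k]

which preserve positivity and, after renormalization, the simplex
constraint at every iterate.  Iteration stops when the objective changes by
less than ``stop_eps`` or after ``max_iter`` steps.  The objective is the
data loss (squared error against empirical proportions by default, or the
Bernoulli negative log-likelihood) plus an optional quadratic spatial
penalty.

The estimator follows scikit-learn conventions: hyper-parameters in
``__init__``, fitted state in trailing-underscore attributes, ``fit``
returning ``self``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .design import (
    ResponseDataset,
    empirical_proportions,
    schedule_pairs,
    validate_pairset,
)
from .maps import (
    ProbabilisticMaps,
    SegmentationMap,
    mean_absolute_error,
    to_segmentation,
)
from .objectives import (
    RegularizerConfig,
    bce_value_grad,
    neighborhood_operator,
    reg_value_grad,
    se_value_grad,
)

__all__ = [
    "SolverConfig",
    "FitResult",
    "ExponentiatedGradientSegmenter",
    "fit_nonparametric",
    "bootstrap_fit",
    "BootstrapResult",
]

#: Bound on the multiplicative-update exponent, guarding overflow when a
#: gradient component is extreme (e.g. BCE near a clipped probability).
_EXP_BOUND = 50.0


@dataclass(frozen=True)
class SolverConfig:
    """Settings of the exponentiated-gradient solver.

    With ``adaptive=True`` (default) the step size starts at
    ``learning_rate`` and is halved whenever a multiplicative step would
    increase the objective (then allowed to grow back), which keeps the
    loss trace monotone for any regularization strength.  With
    ``adaptive=False`` the step size is fixed, matching the plain
    exponentiated-gradient iteration; that variant is only monotone for
    sufficiently small ``learning_rate``.
    """

    learning_rate: float = 0.5
    stop_eps: float = 1e-8
    max_iter: int = 10000
    loss: str = "se"
    seed: int = 0
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.stop_eps <= 0:
            raise ValueError("stop_eps must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.loss not in ("se", "bce"):
            raise ValueError("loss must be 'se' or 'bce'")


@dataclass
class FitResult:
    """Outcome of a map fit: maps, objective trace and convergence info."""

    maps: ProbabilisticMaps
    loss_trace: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = False
    uncovered: list = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    @property
    def segmentation(self) -> SegmentationMap:
        return to_segmentation(self.maps)


class ExponentiatedGradientSegmenter(BaseEstimator):
    """Non-parametric probabilistic-map estimator on pairwise judgments.

    Parameters
    ----------
    n_segments : int
        Number of segments K the maps are fitted with (K >= 1; K = 1 is the
        degenerate single-segment case where every map equals (1,)).
    reg_lambda : float
        Spatial regularization weight; 0 disables the penalty.
    kernel : str or ndarray
        Regularization kernel (see :mod:`pairseg.objectives`).
    loss : {"se", "bce"}
        Data objective; squared error against empirical proportions is the
        default and the one used throughout the simulation studies.
    learning_rate, stop_eps, max_iter :
        Exponentiated-gradient step size, stopping tolerance on the change
        in objective, and iteration cap.
    random_state : int
        Seed for the symmetric-Dirichlet (alpha = 1) initialization.

    Attributes
    ----------
    maps_ : ProbabilisticMaps
        Fitted probability maps.
    labels_ : ndarray of shape (n, n)
        Argmax segmentation labels (1-based).
    result_ : FitResult
        Full fit outcome, including the loss trace.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_segments: int = 3,
        reg_lambda: float = 10.0,
        kernel: str | np.ndarray = "laplacian4",
        loss: str = "se",
        learning_rate: float = 0.5,
        stop_eps: float = 1e-8,
        max_iter: int = 10000,
        adaptive: bool = True,
        random_state: int = 0,
    ):
        self.n_segments = n_segments
        self.reg_lambda = reg_lambda
        self.kernel = kernel
        self.loss = loss
        self.learning_rate = learning_rate
        self.stop_eps = stop_eps
        self.max_iter = max_iter
        self.adaptive = adaptive
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: ResponseDataset, y=None) -> "ExponentiatedGradientSegmenter":
        """Fit probability maps to a :class:`ResponseDataset`."""
        if not isinstance(X, ResponseDataset):
            raise TypeError("X must be a ResponseDataset")
        cfg = SolverConfig(
            learning_rate=self.learning_rate,
            stop_eps=self.stop_eps,
            max_iter=self.max_iter,
            loss=self.loss,
            seed=self.random_state,
            adaptive=self.adaptive,
        )
        reg = RegularizerConfig(lam=self.reg_lambda, kernel=self.kernel)
        result = _fit_eg(X, self.n_segments, reg, cfg)
        self.result_ = result
        self.maps_ = result.maps
        self.labels_ = result.segmentation.labels
        self.loss_trace_ = result.loss_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def score(self, X: ResponseDataset, y=None) -> float:
        """Negative data loss of the fitted maps on ``X`` (higher is better)."""
        from .objectives import bce_loss, se_loss

        if self.loss == "bce":
            return -bce_loss(self.maps_, X)
        return -se_loss(self.maps_, X)


def _fit_eg(
    dataset: ResponseDataset,
    n_segments: int,
    reg: RegularizerConfig,
    cfg: SolverConfig,
) -> FitResult:
    grid = dataset.grid
    m = grid.n_elements

    report = validate_pairset(dataset.pairset)
    uncovered = report.uncovered
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} grid element(s) are not covered by any tested "
            "pair; their maps stay at initialization (up to regularization)",
            stacklevel=2,
        )

    if n_segments == 1:
        maps = ProbabilisticMaps.from_values(np.ones((grid.n, grid.n, 1)))
        # the data loss is constant in the single-segment case
        return FitResult(maps, np.array([0.0]), 0, True, uncovered)
    if n_segments < 1 or n_segments > m:
        raise ValueError("n_segments must lie in 1..N^2")

    prop = empirical_proportions(dataset)
    op = (
        neighborhood_operator(grid, reg.kernel_array(), reg.edge_mode)
        if reg.lam > 0
        else None
    )
    data_vg = se_value_grad if cfg.loss == "se" else bce_value_grad
    # The SE objective carries one observation (the proportion) per pair,
    # the BCE objective carries ~N_b; scaling the penalty by the mean
    # observations-per-pair makes a given lambda exert the same
    # regularization pressure under either loss.
    lam_eff = reg.lam * (float(prop.count.mean()) if cfg.loss == "bce" else 1.0)

    rng = np.random.default_rng(cfg.seed)
    flat = rng.dirichlet(np.ones(n_segments), size=m)

    def objective_grad(p: np.ndarray) -> tuple[float, np.ndarray]:
        value, grad = data_vg(p, prop)
        if op is not None:
            rv, rg = reg_value_grad(p, op, lam_eff)
            value += rv
            grad = grad + rg
        return value, grad

    def eg_step(p: np.ndarray, grad: np.ndarray, lr: float) -> np.ndarray:
        step = np.clip(-lr * grad, -_EXP_BOUND, _EXP_BOUND)
        q = p * np.exp(step)
        sums = q.sum(axis=1, keepdims=True)
        # rows can collapse numerically if every component underflows
        dead = sums[:, 0] <= 0
        if np.any(dead):
            q[dead] = 1.0 / q.shape[1]
            sums = q.sum(axis=1, keepdims=True)
        return q / sums

    value, grad = objective_grad(flat)
    trace = [value]
    converged = False
    n_iter = 0
    lr = cfg.learning_rate
    for n_iter in range(1, cfg.max_iter + 1):
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient encountered during fit")
        if cfg.adaptive:
            # backtracking: halve the step until the objective stops rising
            while True:
                candidate = eg_step(flat, grad, lr)
                new_value, new_grad = objective_grad(candidate)
                if new_value <= value or lr <= 1e-8:
                    break
                lr *= 0.5
            lr = min(lr * 1.2, cfg.learning_rate)
        else:
            candidate = eg_step(flat, grad, lr)
            new_value, new_grad = objective_grad(candidate)
        flat, value, grad = candidate, new_value, new_grad
        trace.append(value)
        if abs(trace[-1] - trace[-2]) <= cfg.stop_eps:
            converged = True
            break

    maps = ProbabilisticMaps.from_values(
        flat.reshape(grid.n, grid.n, n_segments), grid=grid, normalize=True
    )
    return FitResult(maps, np.asarray(trace), n_iter, converged, uncovered)


def fit_nonparametric(
    dataset: ResponseDataset,
    n_segments: int,
    reg: RegularizerConfig | None = None,
    solver: SolverConfig | None = None,
) -> FitResult:
    """Functional wrapper around :class:`ExponentiatedGradientSegmenter`."""
    reg = reg if reg is not None else RegularizerConfig()
    solver = solver if solver is not None else SolverConfig()
    est = ExponentiatedGradientSegmenter(
        n_segments=n_segments,
        reg_lambda=reg.lam,
        kernel=reg.kernel,
        loss=solver.loss,
        learning_rate=solver.learning_rate,
        stop_eps=solver.stop_eps,
        max_iter=solver.max_iter,
        adaptive=solver.adaptive,
        random_state=solver.seed,
    )
    return est.fit(dataset).result_


# ---------------------------------------------------------------------------
# Bootstrap over pair resampling
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Per-resample MAE and final-loss samples with percentile summaries."""

    mae: np.ndarray
    final_loss: np.ndarray

    def _ci(self, x: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    @property
    def mae_mean(self) -> float:
        return float(self.mae.mean())

    @property
    def mae_ci(self) -> tuple[float, float]:
        return self._ci(self.mae)

    @property
    def loss_mean(self) -> float:
        return float(self.final_loss.mean())

    @property
    def loss_ci(self) -> tuple[float, float]:
        return self._ci(self.final_loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"mae": self.mae, "final_loss": self.final_loss})


def bootstrap_fit(
    truth: ProbabilisticMaps,
    n_resamples: int = 50,
    seed: int = 0,
    n_blocks: int = 10,
    n_trials: int | None = None,
    min_distance: float | None = None,
    reg: RegularizerConfig | None = None,
    solver: SolverConfig | None = None,
    resample_seeds: list[int] | None = None,
) -> BootstrapResult:
    """Sampling variability of the fit under pair-set resampling.

    Repeats schedule -> simulate -> fit ``n_resamples`` times against a
    fixed ground truth, re-drawing the tested pair set each time, and
    collects the label-aligned MAE and the final objective value.  The 2.5
    and 97.5 percentiles of the samples give 95% intervals.
    """
    from .synth import simulate_responses  # local import to avoid a cycle

    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    reg = reg if reg is not None else RegularizerConfig()
    solver = solver if solver is not None else SolverConfig()
    k = truth.n_segments
    if resample_seeds is None:
        ss = np.random.SeedSequence(seed)
        resample_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_resamples)]
    elif len(resample_seeds) != n_resamples:
        raise ValueError("resample_seeds must have length n_resamples")

    maes = np.empty(n_resamples)
    losses = np.empty(n_resamples)
    for idx, rs in enumerate(resample_seeds):
        pairset = schedule_pairs(
            truth.grid, k, n_trials=n_trials, seed=rs, min_distance=min_distance
        )
        dataset = simulate_responses(truth, pairset, n_blocks=n_blocks, seed=rs + 1)
        result = fit_nonparametric(dataset, k, reg=reg, solver=solver)
        maes[idx] = mean_absolute_error(result.maps, truth, align=True)
        losses[idx] = result.final_loss
    return BootstrapResult(mae=maes, final_loss=losses)
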