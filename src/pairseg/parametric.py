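"""Parametric map estimation: multinomial logistic models over image features.

Instead of treating each grid element's simplex vector as free, the maps
are parametrized by a multinomial logistic (softmax) model over per-cell
feature vectors ``x_i``::

    p_i[k] = exp(w_k . x_i + b_k) / sum_l exp(w_l . x_i + b_l)

with weights ``w`` (K x D) and offsets ``b`` (K).  Only the differences
``w_k - w_l`` and ``b_k - b_l`` are identifiable (softmax shift
invariance).  A constrained reparametrization sets ``b = 0`` and
``w_k = -1 / sigma_k**2`` componentwise, so that ``sigma_k**2`` can be read
as the average feature energy of segment k; for K = 2 the identifiable
quantity is the differential variance
``(sigma_1**2 - sigma_2**2) / (sigma_1**2 sigma_2**2)`` per feature band.

Fitting minimizes the squared error between model pair probabilities
``p_i . p_j`` and the empirical same-segment proportions, by L-BFGS with
analytic gradients; the model family itself acts as a regularizer, so the
spatial penalty defaults to zero here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .design import ResponseDataset, empirical_proportions
from .features import FeatureMap
from .maps import ProbabilisticMaps, to_segmentation
from .objectives import RegularizerConfig, neighborhood_operator
from .solver import FitResult

__all__ = [
    "LogisticParams",
    "VarianceParams",
    "logistic_maps",
    "variance_to_logistic",
    "LogisticSegmenter",
    "fit_parametric",
]


@dataclass(frozen=True)
class LogisticParams:
    """Weights (K x D) and offsets (K) of the multinomial logistic model."""

    omega: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if omega.ndim != 2 or beta.ndim != 1 or omega.shape[0] != beta.shape[0]:
            raise ValueError("omega must be (K, D) and beta (K,)")
        if not (np.all(np.isfinite(omega)) and np.all(np.isfinite(beta))):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "beta", beta)

    @property
    def n_segments(self) -> int:
        return self.omega.shape[0]

    @property
    def n_features(self) -> int:
        return self.omega.shape[1]


@dataclass(frozen=True)
class VarianceParams:
    """Per-segment feature variances sigma^2 (K x D), all strictly positive."""

    sigma_sq: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        sigma_sq = np.asarray(self.sigma_sq, dtype=float)
        if sigma_sq.ndim != 2:
            raise ValueError("sigma_sq must be (K, D)")
        if not np.all(sigma_sq > 0):
            raise ValueError("sigma_sq entries must be strictly positive")
        object.__setattr__(self, "sigma_sq", sigma_sq)


def variance_to_logistic(vp: VarianceParams) -> LogisticParams:
    """Map the variance parametrization to logistic weights.

    ``beta = 0`` and ``omega_k[d] = -1 / sigma_k^2[d]`` (componentwise
    inverse); as sigma^2 grows in a band, the corresponding weight
    vanishes, i.e. the band stops influencing the assignment.
    """
    omega = -1.0 / vp.sigma_sq
    return LogisticParams(omega=omega, beta=np.zeros(vp.sigma_sq.shape[0]))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def logistic_maps(features: FeatureMap, params: LogisticParams) -> ProbabilisticMaps:
    """Probability maps induced by the softmax model over the features."""
    if params.n_features != features.n_features:
        raise ValueError(
            f"feature dimensionality mismatch: params D={params.n_features}, "
            f"features D={features.n_features}"
        )
    logits = features.flat() @ params.omega.T + params.beta
    probs = _softmax(logits)
    n = features.grid.n
    return ProbabilisticMaps.from_values(
        probs.reshape(n, n, params.n_segments), grid=features.grid, normalize=True
    )


class LogisticSegmenter(BaseEstimator):
    """Feature-based probabilistic-map estimator on pairwise judgments.

    Parameters
    ----------
    n_segments : int
        Number of segments K.
    parametrization : {"free", "variance"}
        "free" fits (omega, beta) jointly; "variance" fixes beta = 0 and
        omega = -1/sigma^2 with sigma^2 > 0 enforced through a log
        parametrization sigma^2 = exp(s).
    reg_lambda : float
        Spatial penalty on the induced maps; defaults to 0 since the model
        family already regularizes.
    standardize : bool
        Z-score the features before fitting ("free" parametrization only;
        the energy interpretation of sigma^2 needs raw energies).
    n_starts : int
        Random restarts of the optimizer; the best final loss wins.
    max_iter, tol : optimizer budget and convergence tolerance (L-BFGS).
    random_state : int
        Seed for initialization.

    Attributes
    ----------
    params_ : LogisticParams
    sigma_sq_ : ndarray (K, D), only with the variance parametrization
    maps_ : ProbabilisticMaps
    labels_ : ndarray (n, n), 1-based argmax labels
    result_ : FitResult
    """

    def __init__(
        self,
        n_segments: int = 2,
        parametrization: str = "free",
        reg_lambda: float = 0.0,
        kernel: str = "laplacian4",
        standardize: bool = False,
        n_starts: int = 1,
        max_iter: int = 500,
        tol: float = 1e-10,
        random_state: int = 0,
    ):
        self.n_segments = n_segments
        self.parametrization = parametrization
        self.reg_lambda = reg_lambda
        self.kernel = kernel
        self.standardize = standardize
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: ResponseDataset, features: FeatureMap) -> "LogisticSegmenter":
        if not isinstance(X, ResponseDataset):
            raise TypeError("X must be a ResponseDataset")
        if X.grid.n != features.grid.n:
            raise ValueError("dataset and features must share the grid")
        if self.parametrization not in ("free", "variance"):
            raise ValueError("parametrization must be 'free' or 'variance'")
        if self.parametrization == "variance" and self.standardize:
            raise ValueError(
                "standardization breaks the energy interpretation of sigma^2"
            )

        k = self.n_segments
        feats = features.flat()
        d = feats.shape[1]
        if np.any(feats.std(axis=0) == 0):
            import warnings

            warnings.warn("degenerate (constant) feature column; fit proceeds", stacklevel=2)
        if self.standardize:
            mu, sd = feats.mean(axis=0), feats.std(axis=0)
            feats = (feats - mu) / np.where(sd > 0, sd, 1.0)

        prop = empirical_proportions(X)
        ia, ja = prop.i_idx, prop.j_idx
        target = prop.proportion
        op = (
            neighborhood_operator(X.grid, RegularizerConfig(
                lam=self.reg_lambda, kernel=self.kernel).kernel_array())
            if self.reg_lambda > 0
            else None
        )
        lam = self.reg_lambda
        variance = self.parametrization == "variance"

        def unpack(theta: np.ndarray):
            if variance:
                s = theta.reshape(k, d)
                omega = -np.exp(-s)  # omega = -1/sigma^2, sigma^2 = exp(s)
                beta = np.zeros(k)
            else:
                omega = theta[: k * d].reshape(k, d)
                beta = theta[k * d:]
            return omega, beta

        def objective(theta: np.ndarray):
            omega, beta = unpack(theta)
            logits = feats @ omega.T + beta
            probs = _softmax(logits)
            q = np.einsum("ij,ij->i", probs[ia], probs[ja])
            resid = q - target
            value = float((resid**2).sum())
            dp = np.zeros_like(probs)
            np.add.at(dp, ia, (2.0 * resid)[:, None] * probs[ja])
            np.add.at(dp, ja, (2.0 * resid)[:, None] * probs[ia])
            if op is not None:
                r = probs - op @ probs
                value += float(lam * np.sum(r**2))
                dp += 2.0 * lam * (r - op.T @ r)
            # pull back through the softmax: dz = p * (dp - (dp . p))
            inner = np.sum(dp * probs, axis=1, keepdims=True)
            dz = probs * (dp - inner)
            domega = dz.T @ feats
            if variance:
                s = theta.reshape(k, d)
                grad = (domega * np.exp(-s)).ravel()  # d omega / d s = exp(-s)
            else:
                grad = np.concatenate([domega.ravel(), dz.sum(axis=0)])
            return value, grad

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_starts)):
            if variance:
                # initialize sigma^2 near the mean feature magnitude
                base = np.log(np.maximum(feats.mean(axis=0) ** 2 + feats.var(axis=0), 1e-8))
                theta0 = (base + rng.normal(0, 0.5, size=(k, d))).ravel()
            else:
                theta0 = np.concatenate(
                    [rng.normal(0, 1.0 / max(1, d), size=k * d), np.zeros(k)]
                )
            res = minimize(
                objective,
                theta0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res

        omega, beta = unpack(best.x)
        self.params_ = LogisticParams(omega=omega, beta=beta)
        if variance:
            self.sigma_sq_ = np.exp(best.x.reshape(k, d))
        fm = FeatureMap(features.grid, feats.reshape(features.grid.n, features.grid.n, d))
        self.maps_ = logistic_maps(fm, self.params_)
        self.labels_ = to_segmentation(self.maps_).labels
        self.result_ = FitResult(
            maps=self.maps_,
            loss_trace=np.array([best.fun]),
            n_iter=int(best.nit),
            converged=bool(best.success),
            uncovered=[],
        )
        self.converged_ = bool(best.success)
        return self

    def differential_variance(self) -> np.ndarray:
        """sigma_1^2 - sigma_2^2 per feature band (variance fits, K = 2)."""
        if not hasattr(self, "sigma_sq_"):
            raise AttributeError("differential variance requires a variance-parametrized fit")
        if self.sigma_sq_.shape[0] != 2:
            raise ValueError("differential variance is defined for K = 2")
        return self.sigma_sq_[0] - self.sigma_sq_[1]


def fit_parametric(
    dataset: ResponseDataset,
    features: FeatureMap,
    n_segments: int,
    reg: RegularizerConfig | None = None,
    parametrization: str = "free",
    seed: int = 0,
    n_starts: int = 1,
) -> tuple[LogisticParams, ProbabilisticMaps, FitResult]:
    """Functional wrapper around :class:`LogisticSegmenter`."""
    lam = reg.lam if reg is not None else 0.0
    kernel = reg.kernel if reg is not None else "laplacian4"
    est = LogisticSegmenter(
        n_segments=n_segments,
        parametrization=parametrization,
        reg_lambda=lam,
        kernel=kernel,
        n_starts=n_starts,
        random_state=seed,
    )
    est.fit(dataset, features)
    return est.params_, est.maps_, est.result_
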