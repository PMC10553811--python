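"""Objective functions for probabilistic-map inference.

Under the conditional-independence assumption, the probability that two
grid elements i, j are judged to lie in the same segment is the dot product
of their simplex vectors, ``p_ij = p_i . p_j``.  Two data objectives are
supported:

* BCE — the Bernoulli negative log-likelihood of the per-trial responses;
* SE  — the squared error between ``p_ij`` and the empirical same-segment
  proportion ``k_ij``, which shares its minimizers with BCE whenever, for
  every tested element, the family of partner probability vectors is
  linearly independent.

A quadratic spatial penalty ``lambda * sum_i,k (p_i[k] - (G*p)_i[k])**2``
discourages maps that deviate from their local neighborhood average; ``G``
is a small kernel (by default the 4-neighbor averaging kernel, making the
residual a discrete Laplacian) and edge values are replicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .design import ProportionTable, ResponseDataset, empirical_proportions
from .maps import GridSpec, ProbabilisticMaps

__all__ = [
    "RegularizerConfig",
    "KERNELS",
    "pair_probability",
    "bce_loss",
    "se_loss",
    "regularization_penalty",
    "neighborhood_operator",
]

#: Clipping bound applied inside logs so that p_ij in {0, 1} stays finite.
BCE_CLIP = 1e-12

KERNELS: dict[str, np.ndarray] = {
    # 4-neighbor average: p - G*p is the (negated, scaled) 5-point Laplacian.
    "laplacian4": np.array(
        [[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]]
    ),
    "laplacian8": np.array(
        [[1.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 1.0]]
    )
    / 8.0,
    # 3x3 binomial (Gaussian-like) average, center included.
    "gaussian3": np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]])
    / 16.0,
}


@dataclass(frozen=True)
class RegularizerConfig:
    """Spatial regularization settings.

    Parameters
    ----------
    lam : float
        Penalty weight lambda >= 0; 0 disables regularization.
    kernel : str or ndarray
        Named kernel (``laplacian4``, ``laplacian8``, ``gaussian3``) or an
        explicit 2-D array with odd side lengths.
    edge_mode : str
        How the convolution handles the border; ``"nearest"`` replicates
        edge values.
    """

    lam: float = 10.0
    kernel: str | np.ndarray = "laplacian4"
    edge_mode: str = "nearest"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        arr = self.kernel_array()
        if arr.ndim != 2 or arr.shape[0] % 2 == 0 or arr.shape[1] % 2 == 0:
            raise ValueError("kernel must be 2-D with odd side lengths")

    def kernel_array(self) -> np.ndarray:
        if isinstance(self.kernel, str):
            try:
                return KERNELS[self.kernel]
            except KeyError:
                raise ValueError(
                    f"unknown kernel '{self.kernel}'; options: {sorted(KERNELS)}"
                ) from None
        return np.asarray(self.kernel, dtype=float)


def pair_probability(p_i: np.ndarray, p_j: np.ndarray) -> float:
    """Probability that two elements share a segment: the dot product."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if p_i.shape != p_j.shape or p_i.ndim != 1:
        raise ValueError("simplex vectors must be 1-D with matching length")
    return float(p_i @ p_j)


def _pair_probs(flat: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", flat[i_idx], flat[j_idx])


def bce_loss(maps: ProbabilisticMaps, dataset: ResponseDataset, clip: float = BCE_CLIP) -> float:
    """Bernoulli negative log-likelihood of the per-trial responses.

    Pair probabilities are clipped to ``[clip, 1 - clip]`` before taking
    logs so that deterministic maps remain finite.
    """
    flat = maps.flat()
    q = np.clip(_pair_probs(flat, dataset.i_idx, dataset.j_idx), clip, 1 - clip)
    r = dataset.response
    return float(-(r * np.log(q) + (1 - r) * np.log1p(-q)).sum())


def se_loss(maps: ProbabilisticMaps, proportions: ProportionTable | ResponseDataset) -> float:
    """Squared error between model pair probabilities and proportions k_ij."""
    if isinstance(proportions, ResponseDataset):
        proportions = empirical_proportions(proportions)
    flat = maps.flat()
    q = _pair_probs(flat, proportions.i_idx, proportions.j_idx)
    return float(((proportions.proportion - q) ** 2).sum())


def neighborhood_operator(
    grid: GridSpec, kernel: np.ndarray, edge_mode: str = "nearest"
) -> sp.csr_matrix:
    """Sparse matrix A with ``(A p)_i = (G * p)_i`` under replicate padding.

    Having the convolution as an explicit linear operator gives the exact
    adjoint needed for the penalty gradient, including the border terms
    introduced by edge replication.
    """
    if edge_mode != "nearest":
        raise ValueError("only edge replication ('nearest') is supported")
    n = grid.n
    m = grid.n_elements
    kh, kw = kernel.shape
    cy, cx = kh // 2, kw // 2
    rows_idx, cols_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    data, rows, cols = [], [], []
    for dy in range(kh):
        for dx in range(kw):
            w = kernel[dy, dx]
            if w == 0.0:
                continue
            # convolution: (G*p)[y, x] += G[dy,dx] * p[y - (dy-cy), x - (dx-cx)]
            src_y = np.clip(rows_idx - (dy - cy), 0, n - 1)
            src_x = np.clip(cols_idx - (dx - cx), 0, n - 1)
            rows.append((rows_idx * n + cols_idx).ravel())
            cols.append((src_y * n + src_x).ravel())
            data.append(np.full(m, w))
    mat = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )
    return mat.tocsr()


def regularization_penalty(maps: ProbabilisticMaps, cfg: RegularizerConfig) -> float:
    """Quadratic cost for maps deviating from their local kernel average."""
    if cfg.lam == 0.0:
        return 0.0
    op = neighborhood_operator(maps.grid, cfg.kernel_array(), cfg.edge_mode)
    flat = maps.flat()
    resid = flat - op @ flat
    return float(cfg.lam * np.sum(resid**2))


# ---------------------------------------------------------------------------
# Value-and-gradient helpers used by the solver (flat (M, K) arrays).
# ---------------------------------------------------------------------------

def _scatter_pair_grad(
    flat: np.ndarray, ia: np.ndarray, ja: np.ndarray, coeff: np.ndarray
) -> np.ndarray:
    """Accumulate ``coeff_p * p_j`` into row i and vice versa, per channel."""
    m, k = flat.shape
    grad = np.empty_like(flat)
    for c in range(k):
        grad[:, c] = np.bincount(
            ia, weights=coeff * flat[ja, c], minlength=m
        ) + np.bincount(ja, weights=coeff * flat[ia, c], minlength=m)
    return grad


def se_value_grad(
    flat: np.ndarray, prop: ProportionTable
) -> tuple[float, np.ndarray]:
    ia, ja = prop.i_idx, prop.j_idx
    q = _pair_probs(flat, ia, ja)
    resid = q - prop.proportion
    value = float((resid**2).sum())
    grad = _scatter_pair_grad(flat, ia, ja, 2.0 * resid)
    return value, grad


def bce_value_grad(
    flat: np.ndarray, prop: ProportionTable, clip: float = BCE_CLIP
) -> tuple[float, np.ndarray]:
    """BCE over trials, aggregated per pair as count * BCE(k_ij | p_ij)."""
    ia, ja = prop.i_idx, prop.j_idx
    q = np.clip(_pair_probs(flat, ia, ja), clip, 1 - clip)
    k = prop.proportion
    n = prop.count
    value = float((n * (-(k * np.log(q)) - (1 - k) * np.log1p(-q))).sum())
    dq = n * (q - k) / (q * (1 - q))
    grad = _scatter_pair_grad(flat, ia, ja, dq)
    return value, grad


def reg_value_grad(
    flat: np.ndarray, op: sp.csr_matrix, lam: float
) -> tuple[float, np.ndarray]:
    resid = flat - op @ flat
    value = float(lam * np.sum(resid**2))
    grad = 2.0 * lam * (resid - op.T @ resid)
    return value, grad
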