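"""Grid-based probability and segmentation maps, and the metrics defined on them.

The central object is a :class:`ProbabilisticMaps`: an ``N x N`` grid of
K-dimensional probability vectors, one per grid element, each lying on the
K-simplex.  A hard :class:`SegmentationMap` is obtained by taking, at every
element, the label of the segment with the highest probability.  This module
also provides the evaluation metrics used throughout the package: mean
absolute error between map collections (with optional label alignment, since
the pairwise likelihood is invariant to label permutation), per-element
Shannon entropy, and the minimal-trial design formula ``(K - 1) * N**2``.

Conventions
-----------
Grid elements are indexed ``(row, col)``, 0-based in the API; probability
channels are 0-based; segmentation labels are 1-based (``1..K``).  Files
written by :func:`write_probmaps` / :func:`write_segmentation` use 1-based
coordinates and labels.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import xlogy

__all__ = [
    "GridSpec",
    "ProbabilisticMaps",
    "SegmentationMap",
    "ScalarField",
    "minimal_trials",
    "to_segmentation",
    "mean_absolute_error",
    "align_labels",
    "entropy_map",
    "count_nonempty_segments",
    "write_probmaps",
    "read_probmaps",
    "write_segmentation",
    "read_segmentation",
]

#: Tolerance on per-element probability sums.
SIMPLEX_ATOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Square grid of cue locations covering a (square) image.

    Parameters
    ----------
    n : int
        Grid side length; the grid has ``n * n`` elements.  Must be >= 3.
    image_size : int, optional
        Side length of the underlying image, in pixels.  When set, the
        center of grid element ``(r, c)`` maps to image coordinates
        ``((r + 0.5) * image_size / n, (c + 0.5) * image_size / n)``.
    """

    n: int
    image_size: int | None = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 3:
            raise ValueError(f"grid side length must be an integer >= 3, got {self.n}")
        if self.image_size is not None and self.image_size < self.n:
            raise ValueError("image_size must be at least the grid side length")

    @property
    def n_elements(self) -> int:
        return self.n * self.n

    def ravel(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Flatten (row, col) indices into element indices ``0..n*n-1``."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        if np.any((rows < 0) | (rows >= self.n) | (cols < 0) | (cols >= self.n)):
            raise ValueError("grid coordinates out of bounds")
        return rows * self.n + cols

    def unravel(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.asarray(idx)
        return idx // self.n, idx % self.n

    def cell_centers(self) -> np.ndarray:
        """Image-pixel coordinates of the element centers, shape (n, n, 2)."""
        size = self.image_size if self.image_size is not None else self.n
        step = size / self.n
        coords = (np.arange(self.n) + 0.5) * step
        rr, cc = np.meshgrid(coords, coords, indexing="ij")
        return np.stack([rr, cc], axis=-1)


def _validate_simplex(values: np.ndarray) -> None:
    if values.ndim != 3:
        raise ValueError("probability values must have shape (n, n, K)")
    if values.shape[0] != values.shape[1]:
        raise ValueError("probability values must be defined on a square grid")
    if values.shape[2] < 1:
        raise ValueError("at least one segment channel is required")
    if not np.all(np.isfinite(values)):
        raise ValueError("probability values must be finite")
    if np.any(values < -SIMPLEX_ATOL) or np.any(values > 1 + SIMPLEX_ATOL):
        raise ValueError("probability values must lie in [0, 1]")
    sums = values.sum(axis=-1)
    if np.max(np.abs(sums - 1.0)) > SIMPLEX_ATOL:
        raise ValueError(
            "per-element probabilities must sum to 1 within "
            f"{SIMPLEX_ATOL:g}; worst deviation {np.max(np.abs(sums - 1.0)):g}"
        )


@dataclass(frozen=True)
class ProbabilisticMaps:
    """K probability maps on an N x N grid; each element is a simplex point."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _validate_simplex(values)
        if values.shape[0] != self.grid.n:
            raise ValueError(
                f"values shape {values.shape} inconsistent with grid n={self.grid.n}"
            )

    @property
    def n_segments(self) -> int:
        return self.values.shape[2]

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        grid: GridSpec | None = None,
        normalize: bool = False,
    ) -> "ProbabilisticMaps":
        """Build maps from an (n, n, K) array, optionally renormalizing rows."""
        values = np.asarray(values, dtype=float)
        if normalize:
            values = np.clip(values, 0.0, None)
            sums = values.sum(axis=-1, keepdims=True)
            if np.any(sums <= 0):
                raise ValueError("cannot normalize rows with non-positive mass")
            values = values / sums
        if grid is None:
            grid = GridSpec(values.shape[0])
        return cls(grid, values)

    @classmethod
    def one_hot(cls, labels: np.ndarray, n_segments: int, grid: GridSpec | None = None) -> "ProbabilisticMaps":
        """Deterministic maps from a 1-based label grid."""
        labels = np.asarray(labels, dtype=int)
        if labels.min() < 1 or labels.max() > n_segments:
            raise ValueError("labels must lie in 1..K")
        values = np.eye(n_segments)[labels - 1]
        return cls.from_values(values, grid=grid)

    def flat(self) -> np.ndarray:
        """View as (n*n, K)."""
        return self.values.reshape(-1, self.n_segments)


@dataclass(frozen=True)
class SegmentationMap:
    """Hard segment labels (1-based) on an N x N grid."""

    grid: GridSpec
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (self.grid.n, self.grid.n):
            raise ValueError("labels must have shape (n, n)")
        if labels.min() < 1:
            raise ValueError("labels are 1-based and must be >= 1")

    @property
    def n_segments(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ScalarField:
    """A real value per grid element (entropy maps, per-element errors)."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n, self.grid.n):
            raise ValueError("values must have shape (n, n)")
        if not np.all(np.isfinite(values)):
            raise ValueError("scalar field values must be finite")


def minimal_trials(n_segments: int, grid_size: int) -> int:
    """Minimal number of tested pairs needed to identify the maps.

    The probabilistic maps have ``(K - 1) * N**2`` free parameters (one
    simplex constraint per element), hence at least that many tested pairs
    are required.

    Parameters
    ----------
    n_segments : int
        Number of segments K (>= 2).
    grid_size : int
        Grid side length N (>= 3).
    """
    if int(n_segments) != n_segments or n_segments < 2:
        raise ValueError(f"n_segments must be an integer >= 2, got {n_segments}")
    if int(grid_size) != grid_size or grid_size < 3:
        raise ValueError(f"grid_size must be an integer >= 3, got {grid_size}")
    return (int(n_segments) - 1) * int(grid_size) ** 2


def to_segmentation(maps: ProbabilisticMaps) -> SegmentationMap:
    """Per-element argmax labels (ties broken toward the smallest label)."""
    labels = np.argmax(maps.values, axis=-1) + 1
    return SegmentationMap(maps.grid, labels)


def _channel_cost_matrix(est: ProbabilisticMaps, ref: ProbabilisticMaps) -> np.ndarray:
    """C[k, l] = sum_i |est_i[k] - ref_i[l]|; permutation cost decomposes over C."""
    e = est.flat()[:, :, None]
    r = ref.flat()[:, None, :]
    return np.abs(e - r).sum(axis=0)


def _check_compatible(a: ProbabilisticMaps, b: ProbabilisticMaps) -> None:
    if a.grid.n != b.grid.n or a.n_segments != b.n_segments:
        raise ValueError(
            f"incompatible maps: grid {a.grid.n} vs {b.grid.n}, "
            f"K {a.n_segments} vs {b.n_segments}"
        )


def align_labels(est: ProbabilisticMaps, ref: ProbabilisticMaps) -> tuple[int, ...]:
    """Channel permutation of ``ref`` that best matches ``est``.

    Returns the permutation ``pi`` (0-based, ``pi[k]`` is the ref channel
    matched to est channel ``k``) minimizing the unaligned mean absolute
    error.  Because the total cost decomposes as a sum of per-channel costs,
    the optimum is an assignment problem.  For K <= 6 all K! permutations
    are enumerated and the lexicographically smallest minimizer is returned;
    for larger K the Hungarian algorithm is used.
    """
    _check_compatible(est, ref)
    cost = _channel_cost_matrix(est, ref)
    k = cost.shape[0]
    if k <= 6:
        best_perm: tuple[int, ...] | None = None
        best = np.inf
        for perm in itertools.permutations(range(k)):
            c = cost[np.arange(k), perm].sum()
            if c < best - 1e-15:
                best = c
                best_perm = perm
        assert best_perm is not None
        return best_perm
    rows, cols = linear_sum_assignment(cost)
    return tuple(int(c) for c in cols[np.argsort(rows)])


def mean_absolute_error(
    est: ProbabilisticMaps,
    truth: ProbabilisticMaps,
    align: bool = True,
) -> float:
    """Mean over elements of the L1 distance between probability K-tuples.

    With ``align=True`` (default) the truth channels are first permuted by
    :func:`align_labels`, since the pairwise likelihood — and hence any fit —
    is invariant to label permutation.
    """
    _check_compatible(est, truth)
    if align:
        perm = align_labels(est, truth)
        truth_vals = truth.values[..., list(perm)]
    else:
        truth_vals = truth.values
    n2 = est.grid.n_elements
    return float(np.abs(est.values - truth_vals).sum() / n2)


def entropy_map(maps: ProbabilisticMaps) -> tuple[ScalarField, dict]:
    """Per-element Shannon entropy (natural log) and its summary.

    Returns the entropy field ``H_i = -sum_k p_i[k] log p_i[k]`` (with
    ``0 log 0 = 0``) and a summary dict with the mean over elements and the
    standard error across elements.
    """
    h = -xlogy(maps.values, maps.values).sum(axis=-1)
    h = np.clip(h, 0.0, None)  # guard tiny negative round-off
    field_ = ScalarField(maps.grid, h)
    n2 = maps.grid.n_elements
    summary = {
        "mean": float(h.mean()),
        "sem": float(h.std(ddof=1) / np.sqrt(n2)) if n2 > 1 else 0.0,
    }
    return field_, summary


def count_nonempty_segments(maps: ProbabilisticMaps, mass_threshold: float = 0.25) -> int:
    """Number of channels whose maximum probability exceeds ``mass_threshold``.

    When fitting with more channels than the data support, regularized fits
    drive superfluous channels toward zero everywhere; the number of
    segments actually present can then be read off as the number of
    channels that retain appreciable mass somewhere on the grid.
    """
    if not 0.0 < mass_threshold < 1.0:
        raise ValueError("mass_threshold must lie in (0, 1)")
    channel_max = maps.values.max(axis=(0, 1))
    return int(np.sum(channel_max > mass_threshold))


# ---------------------------------------------------------------------------
# Serialization: one CSV per channel (N rows x N cols), JSON metadata sidecar,
# optional 8-bit grayscale PNG per channel for visualization.
# ---------------------------------------------------------------------------

def write_probmaps(
    maps: ProbabilisticMaps,
    outdir: str | Path,
    stem: str = "probmap",
    png: bool = False,
) -> list[Path]:
    """Write maps as per-channel CSV files plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for k in range(maps.n_segments):
        path = outdir / f"{stem}_k{k + 1}.csv"
        np.savetxt(path, maps.values[..., k], delimiter=",", fmt="%.10g")
        written.append(path)
        if png:
            import imageio.v3 as iio

            img = np.round(maps.values[..., k] * 255).astype(np.uint8)
            iio.imwrite(outdir / f"{stem}_k{k + 1}.png", img)
    meta = {
        "n": maps.grid.n,
        "image_size": maps.grid.image_size,
        "n_segments": maps.n_segments,
        "stem": stem,
    }
    meta_path = outdir / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    written.append(meta_path)
    return written


def read_probmaps(outdir: str | Path, stem: str = "probmap") -> ProbabilisticMaps:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    channels = [
        np.loadtxt(outdir / f"{stem}_k{k + 1}.csv", delimiter=",")
        for k in range(meta["n_segments"])
    ]
    values = np.stack(channels, axis=-1)
    grid = GridSpec(meta["n"], meta.get("image_size"))
    return ProbabilisticMaps.from_values(values, grid=grid, normalize=True)


def write_segmentation(seg: SegmentationMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, seg.labels, delimiter=",", fmt="%d")
    return path


def read_segmentation(path: str | Path, grid: GridSpec | None = None) -> SegmentationMap:
    labels = np.loadtxt(path, delimiter=",", dtype=int)
    if grid is None:
        grid = GridSpec(labels.shape[0])
    return SegmentationMap(grid, labels)
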