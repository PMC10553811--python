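"""Synthetic ground truths, simulated observers, and composite textures.

The validation studies need three generators:

* probabilistic ground-truth maps with a controlled uncertainty level —
  a smoothed random partition of the grid whose one-hot labels are blurred
  near segment boundaries and mixed toward the uniform distribution;
* simulated same/different responses — independent Bernoulli draws with
  success probability equal to the dot product of the two simplex vectors;
* two-region composite textures — oriented bandpass Gaussian noise on each
  side of a random smooth boundary, the classic stimulus for studying
  segmentation under controlled feature overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .design import PairSet, ResponseDataset
from .maps import GridSpec, ProbabilisticMaps
from .objectives import _pair_probs

__all__ = [
    "UncertaintyProfile",
    "TextureSpec",
    "sample_probmaps",
    "soften_labels",
    "simulate_responses",
    "sample_boundary",
    "synthesize_composite_texture",
]


@dataclass(frozen=True)
class UncertaintyProfile:
    """Controls how far ground-truth maps are from deterministic.

    Parameters
    ----------
    level : float in [0, 1]
        0 gives one-hot maps; larger values blur the segment boundaries
        and mix the maps toward the uniform distribution; 1 is maximal.
    spatial_scale : float > 0
        Width (grid units) of the uncertain band around segment
        boundaries; the blur applied at uncertainty ``level`` has standard
        deviation ``level * spatial_scale``.
    """

    level: float = 0.5
    spatial_scale: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must lie in [0, 1]")
        if self.spatial_scale <= 0:
            raise ValueError("spatial_scale must be > 0")


@dataclass(frozen=True)
class TextureSpec:
    """Spectral description of a two-region composite oriented texture.

    Orientations are in degrees in [0, 180); the frequency band is given
    by its center in cycles/image and a log-domain bandwidth in octaves.
    """

    size: int = 256
    center_orientations: tuple[float, float] = (80.0, 100.0)
    orientation_bandwidths: tuple[float, float] = (8.0, 8.0)
    freq_center: float = 32.0
    freq_bandwidth_octaves: float = 1.0
    boundary_smoothness: float = 4.0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("size must be >= 16 pixels")
        if any(b <= 0 for b in self.orientation_bandwidths):
            raise ValueError("orientation bandwidths must be > 0")
        if not all(0.0 <= o < 180.0 for o in self.center_orientations):
            raise ValueError("orientations must lie in [0, 180)")
        if self.freq_center <= 0 or self.freq_bandwidth_octaves <= 0:
            raise ValueError("frequency band parameters must be > 0")
        if self.boundary_smoothness <= 0:
            raise ValueError("boundary_smoothness must be > 0")


def soften_labels(
    labels: np.ndarray,
    n_segments: int,
    level: float,
    spatial_scale: float,
) -> ProbabilisticMaps:
    """One-hot maps from a 1-based label grid, softened by blur + mixing.

    The one-hot indicators are blurred with a Gaussian of standard
    deviation ``level * spatial_scale`` (replicated edges), renormalized,
    then mixed toward uniform: ``p <- (1 - level) p + level / K``.  At
    ``level == 0`` this returns exact one-hot maps.
    """
    labels = np.asarray(labels, dtype=int)
    one_hot = np.eye(n_segments)[labels - 1].astype(float)
    sigma = level * spatial_scale
    if sigma > 0:
        blurred = np.stack(
            [gaussian_filter(one_hot[..., k], sigma, mode="nearest") for k in range(n_segments)],
            axis=-1,
        )
    else:
        blurred = one_hot
    blurred = blurred / blurred.sum(axis=-1, keepdims=True)
    values = (1.0 - level) * blurred + level / n_segments
    return ProbabilisticMaps.from_values(values, normalize=True)


def sample_probmaps(
    grid: GridSpec,
    n_segments: int,
    profile: UncertaintyProfile | None = None,
    seed: int = 0,
) -> ProbabilisticMaps:
    """Random ground-truth maps with K compact segments at a set uncertainty.

    K seed points are placed by randomized farthest-point sampling (the
    first uniformly, each next one among the grid elements in the top
    decile of distance to the existing seeds) and each element is labeled
    by its nearest seed.  This Voronoi partition yields compact, roughly
    balanced segments; the one-hot labels are then softened by
    :func:`soften_labels` according to the uncertainty profile.
    """
    profile = profile if profile is not None else UncertaintyProfile()
    n = grid.n
    m = grid.n_elements
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_segments > m:
        raise ValueError("cannot place more segments than grid elements")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    seeds = [int(rng.integers(m))]
    for _ in range(n_segments - 1):
        dmin = np.min(
            [np.sum((pts - pts[s]) ** 2, axis=1) for s in seeds], axis=0
        )
        thresh = np.quantile(dmin, 0.9)
        seeds.append(int(rng.choice(np.flatnonzero(dmin >= thresh))))
    d2 = np.stack(
        [np.sum((pts - pts[s]) ** 2, axis=1) for s in seeds], axis=1
    ).astype(float)
    # small random jitter on distances breaks ties reproducibly
    d2 = d2 + rng.uniform(0, 1e-6, size=d2.shape)
    labels = (np.argmin(d2, axis=1) + 1).reshape(n, n)
    maps = soften_labels(labels, n_segments, profile.level, profile.spatial_scale)
    return ProbabilisticMaps(grid, maps.values)


def simulate_responses(
    truth: ProbabilisticMaps,
    pairset: PairSet,
    n_blocks: int = 1,
    seed: int = 0,
) -> ResponseDataset:
    """Bernoulli same/different responses of an ideal probabilistic observer.

    For every tested pair, ``n_blocks`` independent Bernoulli variables are
    drawn with success probability ``p_i . p_j``; the same pair set is used
    in every block.
    """
    if truth.grid.n != pairset.grid.n:
        raise ValueError("truth and pairset must share the grid")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    flat = truth.flat()
    q = np.clip(_pair_probs(flat, pairset.pairs[:, 0], pairset.pairs[:, 1]), 0.0, 1.0)
    t = pairset.n_pairs
    responses = rng.random((n_blocks, t)) < q[None, :]
    block = np.repeat(np.arange(n_blocks), t)
    return ResponseDataset(
        grid=truth.grid,
        block=block,
        i_idx=np.tile(pairset.pairs[:, 0], n_blocks),
        j_idx=np.tile(pairset.pairs[:, 1], n_blocks),
        response=responses.ravel().astype(np.int64),
    )


def sample_boundary(size: int, smoothness: float = 4.0, seed: int = 0) -> np.ndarray:
    """Random smooth curve splitting a size x size image into two regions.

    The dividing curve is a low-order random Fourier series in the column
    coordinate; amplitudes shrink as ``1 / (m * smoothness)`` so large
    ``smoothness`` approaches a straight horizontal boundary.  The mask is
    resampled (bounded retries) until each region holds 25-75% of the area.
    Returns a boolean mask, True above the curve.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    rng = np.random.default_rng(seed)
    x = np.arange(size)
    for _ in range(100):
        offset = rng.uniform(-0.15, 0.15) * size
        y = np.full(size, size / 2 + offset)
        for mode in range(1, 6):
            amp = rng.normal(0, size / (6 * mode * smoothness))
            phase = rng.uniform(0, 2 * np.pi)
            y += amp * np.sin(2 * np.pi * mode * x / size + phase)
        y = np.clip(y, 0.05 * size, 0.95 * size)
        mask = np.arange(size)[:, None] < y[None, :]
        frac = mask.mean()
        if 0.25 <= frac <= 0.75:
            return mask
    raise RuntimeError("could not sample a boundary satisfying the area constraint")


def _oriented_bandpass_spectrum(
    size: int,
    theta_deg: float,
    sigma_theta_deg: float,
    freq_center_cpi: float,
    bandwidth_octaves: float,
) -> np.ndarray:
    """Real, conjugate-symmetric oriented bandpass filter in the FFT domain.

    Radial profile: log-Gaussian around the center frequency; angular
    profile: Gaussian over orientation distance (180-degree periodic, so
    the two symmetric lobes make the filtered noise real).
    """
    f = np.fft.fftfreq(size)  # cycles / pixel
    fy, fx = np.meshgrid(f, f, indexing="ij")
    rho = np.hypot(fx, fy)
    f0 = freq_center_cpi / size
    sigma_log = bandwidth_octaves * np.log(2.0) / 2.0
    with np.errstate(divide="ignore"):
        radial = np.exp(-((np.log(np.where(rho > 0, rho, 1.0) / f0)) ** 2) / (2 * sigma_log**2))
    radial[rho == 0] = 0.0
    # orientation of the wave vector, in [0, 180)
    phi = np.degrees(np.arctan2(fy, fx)) % 180.0
    d = np.abs(phi - theta_deg)
    d = np.minimum(d, 180.0 - d)
    angular = np.exp(-(d**2) / (2 * sigma_theta_deg**2))
    return radial * angular


def synthesize_composite_texture(
    spec: TextureSpec | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two-region oriented-noise texture with its ground-truth mask.

    White Gaussian noise is filtered in the frequency domain with one
    oriented bandpass filter per region (Gaussian orientation profile
    around each region's center orientation), and the two filtered fields
    are combined according to a random smooth boundary (hard, 1-pixel
    transition).  The image is normalized to [0, 1].

    Returns
    -------
    image : ndarray (size, size) in [0, 1]
    mask : ndarray of bool, True for the first region
    """
    spec = spec if spec is not None else TextureSpec()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((spec.size, spec.size))
    spectrum = np.fft.fft2(noise)
    fields = []
    for theta, sigma in zip(spec.center_orientations, spec.orientation_bandwidths):
        filt = _oriented_bandpass_spectrum(
            spec.size, theta, sigma, spec.freq_center, spec.freq_bandwidth_octaves
        )
        fields.append(np.real(np.fft.ifft2(spectrum * filt)))
    mask = sample_boundary(spec.size, spec.boundary_smoothness, seed=seed + 1)
    image = np.where(mask, fields[0], fields[1])
    scale = np.std(image)
    if scale == 0:
        raise RuntimeError("degenerate texture: zero variance")
    image = 0.5 + image / (6.0 * scale)  # +/- 3 sigma fills [0, 1]
    return np.clip(image, 0.0, 1.0), mask
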