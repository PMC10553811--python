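"""Per-grid-cell image features for the parametric segmentation models.

Two feature extractors are provided: mean RGB triples (D = 3), and average
oriented-wavelet energy over a log-Gabor filter bank (D = 36 orientation
bands by default, energies averaged over all scales and over the pixels of
each grid cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .maps import GridSpec

__all__ = [
    "FeatureMap",
    "rgb_features",
    "orientation_energy_features",
    "log_gabor_bank",
    "write_features",
    "read_features",
]


@dataclass(frozen=True)
class FeatureMap:
    """A D-dimensional feature vector per grid element."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)  # (n, n, D)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3 or values.shape[:2] != (self.grid.n, self.grid.n):
            raise ValueError("feature values must have shape (n, n, D)")
        if values.shape[2] < 1:
            raise ValueError("feature dimensionality must be >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def flat(self) -> np.ndarray:
        return self.values.reshape(-1, self.n_features)


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        import imageio.v3 as iio

        image = iio.imread(image)
    image = np.asarray(image)
    if image.dtype == np.uint8:
        image = image.astype(float) / 255.0
    elif image.dtype == np.uint16:
        image = image.astype(float) / 65535.0
    else:
        image = image.astype(float)
    return image


def _cell_edges(n_pixels: int, n_cells: int) -> np.ndarray:
    return np.round(np.linspace(0, n_pixels, n_cells + 1)).astype(int)


def _cell_average(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Average a (H, W, D) pixel field over each grid cell."""
    h, w = values.shape[:2]
    ye = _cell_edges(h, grid.n)
    xe = _cell_edges(w, grid.n)
    out = np.empty((grid.n, grid.n, values.shape[2]))
    for r in range(grid.n):
        for c in range(grid.n):
            out[r, c] = values[ye[r]:ye[r + 1], xe[c]:xe[c + 1]].mean(axis=(0, 1))
    return out


def rgb_features(image, grid: GridSpec) -> FeatureMap:
    """Per-cell mean RGB triple (D = 3), values in [0, 1]."""
    img = _load_image(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("rgb_features requires an RGB image")
    if img.shape[0] != img.shape[1]:
        raise ValueError("only square images are supported")
    return FeatureMap(grid, _cell_average(img[..., :3], grid))


def log_gabor_bank(
    size: int,
    n_orientations: int = 36,
    n_scales: int = 4,
    highest_freq: float = 0.25,
    sigma_ratio: float = 0.65,
    angular_sigma_factor: float = 0.8,
) -> np.ndarray:
    """Frequency-domain log-Gabor filters, shape (n_orientations, n_scales, size, size).

    Radial profile is a log-Gaussian (``sigma_ratio`` is the ratio
    controlling roughly one-octave bandwidth); angular profile is a
    Gaussian around each band center with standard deviation
    ``angular_sigma_factor`` times the band spacing.  Filters occupy a
    single half-plane (analytic filters), so the complex response modulus
    is an orientation-selective envelope.
    """
    f = np.fft.fftfreq(size)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    rho = np.hypot(fx, fy)
    phi = np.degrees(np.arctan2(fy, fx))  # (-180, 180]
    spacing = 180.0 / n_orientations
    sigma_theta = angular_sigma_factor * spacing
    filters = np.empty((n_orientations, n_scales, size, size))
    log_sigma = np.log(1.0 / sigma_ratio)
    for s in range(n_scales):
        f0 = highest_freq / 2**s
        with np.errstate(divide="ignore"):
            radial = np.exp(
                -((np.log(np.where(rho > 0, rho, 1.0) / f0)) ** 2) / (2 * log_sigma**2)
            )
        radial[rho == 0] = 0.0
        for b in range(n_orientations):
            theta = b * spacing
            d = np.abs((phi - theta + 180.0) % 360.0 - 180.0)  # full-circle distance
            angular = np.exp(-(d**2) / (2 * sigma_theta**2))
            filters[b, s] = radial * angular
    return filters


def orientation_energy_features(
    image,
    grid: GridSpec,
    n_orientations: int = 36,
    n_scales: int = 4,
) -> FeatureMap:
    """Average oriented-wavelet energy per grid cell (D = n_orientations).

    The image is filtered with a log-Gabor bank; squared response moduli
    are averaged over scales and over the pixels of each grid cell,
    yielding one non-negative D-vector per cell.
    """
    img = _load_image(image)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)  # luminance
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("orientation_energy_features requires a square grayscale image")
    size = img.shape[0]
    bank = log_gabor_bank(size, n_orientations=n_orientations, n_scales=n_scales)
    spectrum = np.fft.fft2(img - img.mean())
    energy = np.zeros((size, size, n_orientations))
    for b in range(n_orientations):
        for s in range(n_scales):
            resp = np.fft.ifft2(spectrum * bank[b, s])
            energy[..., b] += np.abs(resp) ** 2
    energy /= n_scales
    return FeatureMap(grid, _cell_average(energy, grid))


def write_features(features: FeatureMap, path: str | Path) -> Path:
    """CSV with columns row,col (1-based) then the D feature values."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n, d = features.grid.n, features.n_features
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    df = pd.DataFrame(features.flat(), columns=[f"f{j}" for j in range(d)])
    df.insert(0, "col", cc.ravel() + 1)
    df.insert(0, "row", rr.ravel() + 1)
    df.to_csv(path, index=False)
    return path


def read_features(path: str | Path, grid: GridSpec | None = None) -> FeatureMap:
    import pandas as pd

    df = pd.read_csv(path)
    n = int(df["row"].max())
    if grid is None:
        grid = GridSpec(n)
    cols = [c for c in df.columns if c not in ("row", "col")]
    values = np.full((grid.n, grid.n, len(cols)), np.nan)
    values[df["row"] - 1, df["col"] - 1] = df[cols].to_numpy()
    return FeatureMap(grid, values)
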