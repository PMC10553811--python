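"""Pair scheduling and response-dataset handling.

An experiment (or simulation) presents, on each trial, a pair of distinct
grid elements and records a binary same/different judgment.  This module
owns the pair scheduler (coverage-complete, load-balanced, spatially
scattered pseudo-random designs), the on-disk response format, and the
aggregation of responses into per-pair same-segment proportions, which is
the empirical quantity the squared-error objective consumes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import GridSpec, SegmentationMap, minimal_trials

__all__ = [
    "PairSet",
    "ResponseDataset",
    "ProportionTable",
    "PairSetReport",
    "DesignError",
    "ResponseParseError",
    "schedule_pairs",
    "validate_pairset",
    "empirical_proportions",
    "partner_span_fraction",
    "read_responses",
    "write_responses",
]


class DesignError(ValueError):
    """Raised when a requested design cannot satisfy its constraints."""


class ResponseParseError(ValueError):
    """Raised on malformed response files; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class PairSet:
    """Unordered pairs of distinct grid elements (flattened indices, a < b).

    The constructor normalizes pair order but does not enforce coverage or
    distinctness — use :func:`validate_pairset` for a diagnostic report.
    """

    grid: GridSpec
    pairs: np.ndarray = field(repr=False)  # (T, 2) int64, sorted within rows

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must have shape (T, 2)")
        m = self.grid.n_elements
        if pairs.size and (pairs.min() < 0 or pairs.max() >= m):
            raise ValueError("pair indices out of grid bounds")
        pairs = np.sort(pairs, axis=1)
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @classmethod
    def from_coords(
        cls, grid: GridSpec, i_rows, i_cols, j_rows, j_cols
    ) -> "PairSet":
        a = grid.ravel(np.asarray(i_rows), np.asarray(i_cols))
        b = grid.ravel(np.asarray(j_rows), np.asarray(j_cols))
        return cls(grid, np.column_stack([a, b]))

    def degrees(self) -> np.ndarray:
        """Number of pairs each grid element appears in, shape (n*n,)."""
        return np.bincount(self.pairs.ravel(), minlength=self.grid.n_elements)

    def to_frame(self) -> pd.DataFrame:
        """1-based coordinate table with columns i_row,i_col,j_row,j_col."""
        ir, ic = self.grid.unravel(self.pairs[:, 0])
        jr, jc = self.grid.unravel(self.pairs[:, 1])
        return pd.DataFrame(
            {"i_row": ir + 1, "i_col": ic + 1, "j_row": jr + 1, "j_col": jc + 1}
        )


@dataclass(frozen=True)
class PairSetReport:
    coverage_ok: bool
    uncovered: list
    n_duplicate_pairs: int
    n_identical_pairs: int
    degree_histogram: dict


def validate_pairset(pairset: PairSet) -> PairSetReport:
    """Report coverage, duplicated pairs, identical-point pairs and degrees."""
    pairs = pairset.pairs
    identical = int(np.sum(pairs[:, 0] == pairs[:, 1]))
    keys = pairs[:, 0] * pairset.grid.n_elements + pairs[:, 1]
    _, counts = np.unique(keys, return_counts=True)
    duplicates = int(np.sum(counts - 1))
    deg = pairset.degrees()
    uncovered_idx = np.flatnonzero(deg == 0)
    rows, cols = pairset.grid.unravel(uncovered_idx)
    uncovered = list(zip(rows.tolist(), cols.tolist()))
    vals, freq = np.unique(deg, return_counts=True)
    return PairSetReport(
        coverage_ok=len(uncovered) == 0,
        uncovered=uncovered,
        n_duplicate_pairs=duplicates,
        n_identical_pairs=identical,
        degree_histogram={int(v): int(f) for v, f in zip(vals, freq)},
    )


def schedule_pairs(
    grid: GridSpec,
    n_segments: int,
    n_trials: int | None = None,
    seed: int = 0,
    min_distance: float | None = None,
) -> PairSet:
    """Pseudo-random pair design: coverage-complete, balanced, scattered.

    The identifiability argument requires at least ``(K - 1) * N**2`` tested
    pairs; by default ``K * N**2`` pairs are scheduled (one extra equation
    per element, which helps preserve linear independence of the tested
    families).  Every element appears in at least one pair and in at most
    ``ceil(2 * n_trials / N**2) + 1`` pairs.  Partners are drawn uniformly
    among elements at Chebyshev distance >= ``min_distance`` (default
    ``N / 4``) when possible, so that tested partners are scattered across
    the image rather than clustered near each element.

    Raises
    ------
    DesignError
        If ``n_trials`` is below the ``(K - 1) * N**2`` minimum or the grid
        cannot host that many distinct pairs.
    """
    n = grid.n
    m = grid.n_elements
    minimum = minimal_trials(n_segments, n)
    if n_trials is None:
        n_trials = n_segments * m
    if n_trials < minimum:
        raise DesignError(
            f"n_trials={n_trials} is below the minimal design size "
            f"(K-1)*N^2 = {minimum} for K={n_segments}, N={n}"
        )
    if n_trials > m * (m - 1) // 2:
        raise DesignError(
            f"n_trials={n_trials} exceeds the number of distinct pairs on the grid"
        )
    if min_distance is None:
        min_distance = n / 4
    if min_distance < 0:
        raise DesignError("min_distance must be >= 0")

    rng = np.random.default_rng(seed)
    cap = math.ceil(2 * n_trials / m) + 1
    rows, cols = grid.unravel(np.arange(m))
    degrees = np.zeros(m, dtype=np.int64)
    used: set[tuple[int, int]] = set()
    pair_list: list[tuple[int, int]] = []

    # Chebyshev distances between all element pairs (m <= ~2500 at N=48).
    cheb = np.maximum(
        np.abs(rows[:, None] - rows[None, :]), np.abs(cols[:, None] - cols[None, :])
    )

    def pick_partner(e: int, prefer_uncovered: bool) -> int | None:
        ok = (degrees < cap) & (np.arange(m) != e)
        if not np.any(ok):
            return None
        candidates = np.flatnonzero(ok)
        # drop already-used pairs with e
        candidates = np.array(
            [c for c in candidates if (min(e, c), max(e, c)) not in used],
            dtype=np.int64,
        )
        if candidates.size == 0:
            return None
        far = cheb[e, candidates] >= min_distance
        fresh = degrees[candidates] == 0
        if prefer_uncovered:
            preference = [far & fresh, far, fresh, np.ones_like(far)]
        else:
            preference = [far, np.ones_like(far)]
        for mask in preference:
            if np.any(mask):
                return int(rng.choice(candidates[mask]))
        return None

    def add_pair(a: int, b: int) -> None:
        key = (min(a, b), max(a, b))
        used.add(key)
        pair_list.append(key)
        degrees[a] += 1
        degrees[b] += 1

    # Coverage pass: every element gets at least one pair.
    for e in rng.permutation(m):
        if degrees[e] > 0 or len(pair_list) >= n_trials:
            continue
        partner = pick_partner(int(e), prefer_uncovered=True)
        if partner is None:
            raise DesignError("could not satisfy coverage under the degree cap")
        add_pair(int(e), partner)

    # Fill pass: add pairs at the least-loaded elements until n_trials.
    while len(pair_list) < n_trials:
        open_elems = np.flatnonzero(degrees < cap)
        if open_elems.size == 0:
            raise DesignError("degree cap saturated before reaching n_trials")
        min_deg = degrees[open_elems].min()
        pool = open_elems[degrees[open_elems] == min_deg]
        e = int(rng.choice(pool))
        partner = pick_partner(e, prefer_uncovered=False)
        if partner is None:
            degrees[e] = cap  # exhausted partners for e; exclude and continue
            continue
        add_pair(e, partner)

    pairs = np.array(pair_list, dtype=np.int64)
    pairset = PairSet(grid, pairs)
    report = validate_pairset(pairset)
    if not report.coverage_ok:
        raise DesignError("scheduler failed to cover the grid")
    return pairset


@dataclass(frozen=True)
class ResponseDataset:
    """Per-trial binary same/different responses.

    Stored long-form: parallel arrays of block index (0-based), flattened
    element indices of the two cues, and the binary response (1 = "same
    segment").  The same pair may appear in several blocks (the default
    simulation protocol repeats one pair set across blocks), and per-block
    pair sets may differ.
    """

    grid: GridSpec
    block: np.ndarray = field(repr=False)
    i_idx: np.ndarray = field(repr=False)
    j_idx: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        block = np.asarray(self.block, dtype=np.int64)
        a = np.asarray(self.i_idx, dtype=np.int64)
        b = np.asarray(self.j_idx, dtype=np.int64)
        r = np.asarray(self.response, dtype=np.int64)
        if not (block.shape == a.shape == b.shape == r.shape) or block.ndim != 1:
            raise ValueError("block, i_idx, j_idx, response must be 1-D and equal length")
        m = self.grid.n_elements
        if a.size:
            if a.min() < 0 or a.max() >= m or b.min() < 0 or b.max() >= m:
                raise ValueError("element indices out of grid bounds")
            if np.any(a == b):
                raise ValueError("pairs of identical points are not allowed")
            if block.min() < 0:
                raise ValueError("block indices must be >= 0")
        if not np.isin(r, [0, 1]).all():
            raise ValueError("responses must be binary (0/1)")
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        object.__setattr__(self, "block", block)
        object.__setattr__(self, "i_idx", lo)
        object.__setattr__(self, "j_idx", hi)
        object.__setattr__(self, "response", r)

    @property
    def n_trials(self) -> int:
        return self.block.shape[0]

    @property
    def n_blocks(self) -> int:
        return int(np.unique(self.block).size)

    @property
    def pairset(self) -> PairSet:
        """Unique unordered pairs tested anywhere in the dataset."""
        keys = np.unique(self.i_idx * self.grid.n_elements + self.j_idx)
        pairs = np.column_stack([keys // self.grid.n_elements, keys % self.grid.n_elements])
        return PairSet(self.grid, pairs)

    def to_frame(self) -> pd.DataFrame:
        ir, ic = self.grid.unravel(self.i_idx)
        jr, jc = self.grid.unravel(self.j_idx)
        return pd.DataFrame(
            {
                "block": self.block + 1,
                "i_row": ir + 1,
                "i_col": ic + 1,
                "j_row": jr + 1,
                "j_col": jc + 1,
                "response": self.response,
            }
        )


@dataclass(frozen=True)
class ProportionTable:
    """Per-pair empirical same-segment proportions and observation counts."""

    grid: GridSpec
    i_idx: np.ndarray = field(repr=False)
    j_idx: np.ndarray = field(repr=False)
    proportion: np.ndarray = field(repr=False)
    count: np.ndarray = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return self.i_idx.shape[0]


def empirical_proportions(dataset: ResponseDataset) -> ProportionTable:
    """Aggregate responses into per-pair proportions ``k_ij`` across blocks."""
    m = dataset.grid.n_elements
    keys = dataset.i_idx * m + dataset.j_idx
    uniq, inv = np.unique(keys, return_inverse=True)
    count = np.bincount(inv)
    sums = np.bincount(inv, weights=dataset.response.astype(float))
    return ProportionTable(
        grid=dataset.grid,
        i_idx=uniq // m,
        j_idx=uniq % m,
        proportion=sums / count,
        count=count,
    )


def partner_span_fraction(pairset: PairSet, truth: SegmentationMap) -> float:
    """Fraction of elements whose tested partners span all K segments.

    For a deterministic ground truth the ideal design pairs each element
    with one same-segment partner and one partner in every other segment;
    this diagnostic measures how close a design comes to that ideal.
    """
    if pairset.grid.n != truth.grid.n:
        raise ValueError("pairset and segmentation map must share the grid")
    labels = truth.labels.ravel()
    k = truth.n_segments
    m = pairset.grid.n_elements
    spans = np.zeros((m, k + 1), dtype=bool)
    a, b = pairset.pairs[:, 0], pairset.pairs[:, 1]
    spans[a, labels[b]] = True
    spans[b, labels[a]] = True
    full = spans[:, 1:].all(axis=1)
    return float(full.mean())


# ---------------------------------------------------------------------------
# On-disk format: CSV with header block,i_row,i_col,j_row,j_col,response
# (1-based block and coordinates) plus a JSON metadata sidecar.
# ---------------------------------------------------------------------------

_COLUMNS = ["block", "i_row", "i_col", "j_row", "j_col", "response"]


def write_responses(dataset: ResponseDataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.to_frame().to_csv(path, index=False)
    meta = {
        "n": dataset.grid.n,
        "image_size": dataset.grid.image_size,
        "n_blocks": int(dataset.block.max()) + 1 if dataset.n_trials else 0,
        "n_trials": dataset.n_trials,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_responses(path: str | Path, grid: GridSpec | None = None) -> ResponseDataset:
    """Read a response CSV; coordinates and blocks are 1-based on disk.

    The grid is taken from the ``<path>.meta.json`` sidecar when present,
    otherwise it must be supplied.  Malformed rows raise
    :class:`ResponseParseError` with the offending 1-based line number
    (header is line 1).
    """
    path = Path(path)
    if grid is None:
        meta_path = Path(str(path) + ".meta.json")
        if not meta_path.exists():
            raise ValueError("grid must be given when no metadata sidecar exists")
        meta = json.loads(meta_path.read_text())
        grid = GridSpec(meta["n"], meta.get("image_size"))
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise ResponseParseError(f"could not parse CSV: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ResponseParseError(f"missing columns: {missing}", line=1)
    for col in _COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ResponseParseError(
                f"non-numeric value in column '{col}'", line=int(bad.idxmax()) + 2
            )
    df = df.astype(np.int64)
    bad = ~df["response"].isin([0, 1])
    if bad.any():
        raise ResponseParseError(
            f"response must be 0 or 1, got {df['response'][bad].iloc[0]}",
            line=int(bad.idxmax()) + 2,
        )
    n = grid.n
    for col in ["i_row", "i_col", "j_row", "j_col"]:
        bad = (df[col] < 1) | (df[col] > n)
        if bad.any():
            raise ResponseParseError(
                f"coordinate {col}={df[col][bad].iloc[0]} outside 1..{n}",
                line=int(bad.idxmax()) + 2,
            )
    bad = df["block"] < 1
    if bad.any():
        raise ResponseParseError("block numbers are 1-based", line=int(bad.idxmax()) + 2)
    same = (df["i_row"] == df["j_row"]) & (df["i_col"] == df["j_col"])
    if same.any():
        raise ResponseParseError(
            "pair of identical points", line=int(same.idxmax()) + 2
        )
    a = grid.ravel(df["i_row"].to_numpy() - 1, df["i_col"].to_numpy() - 1)
    b = grid.ravel(df["j_row"].to_numpy() - 1, df["j_col"].to_numpy() - 1)
    return ResponseDataset(
        grid=grid,
        block=df["block"].to_numpy() - 1,
        i_idx=a,
        j_idx=b,
        response=df["response"].to_numpy(),
    )


def coverage_warning(dataset: ResponseDataset) -> list:
    """Warn (and return) grid elements never tested in the dataset."""
    report = validate_pairset(dataset.pairset)
    if not report.coverage_ok:
        warnings.warn(
            f"{len(report.uncovered)} grid element(s) never tested: "
            f"{report.uncovered[:10]}{'...' if len(report.uncovered) > 10 else ''}",
            stacklevel=2,
        )
    return report.uncovered
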