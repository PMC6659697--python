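"""Covariate engineering: truncated distance-to-feature and buffer density.

Two covariate families are computed at arbitrary planar points:

``dist_<class>``
    Euclidean distance (m) from the query point to the nearest cell *centre*
    of the class, capped at ``distance_truncation_m`` (default 1000 m). A
    point inside a cell of the class has distance 0. A class with no cells on
    the landscape returns the cap.

``dens_<class>``
    Number of class cells whose centres fall within ``buffer_radius_m``
    (default 106 m — the mean step length) of the point, divided by the
    buffer area clipped to the raster extent. The clipped area is measured
    discretely as (cell centres inside buffer ∩ extent) × res², so a buffer
    saturated by the class has density exactly 1/res² pixels/m² and edge
    clipping introduces no bias.

Before regression, distance/density columns (current and lagged) are
standardised per individual; the raw iSSA movement-kernel terms
(``ln_step_length``, ``cos_turn_angle``) are deliberately left unscaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DomainError
from .landscape import LandscapeStack

__all__ = [
    "CovariateConfig",
    "CovariateVector",
    "distance_to",
    "density_in_buffer",
    "scale_covariates",
    "SCALED_PREFIXES",
]

SCALED_PREFIXES = ("dist_", "dens_", "lag_dist_", "lag_dens_")


@dataclass(frozen=True)
class CovariateConfig:
    buffer_radius_m: float = 106.0
    distance_truncation_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.buffer_radius_m <= 0 or self.distance_truncation_m <= 0:
            raise ValueError("buffer radius and distance truncation must be positive")


@dataclass
class CovariateVector:
    """dist/dens per class at one point (a convenience view for utilities)."""

    dist: dict[str, float]
    dens: dict[str, float]


class _ClassIndex:
    """Per-class spatial index: KD-tree of feature centres + row cumsums."""

    def __init__(self, stack: LandscapeStack, name: str):
        mask = stack.class_mask(name)
        self.n_cells = int(mask.sum())
        rows_idx, cols_idx = np.nonzero(mask)
        if self.n_cells:
            cx, cy = stack.cell_centers(rows_idx, cols_idx)
            self.tree = cKDTree(np.column_stack([cx, cy]))
        else:
            self.tree = None
        # cumsum[r, c] = number of class cells in row r with column < c
        self.rowcum = np.concatenate(
            [np.zeros((mask.shape[0], 1), dtype=np.int64), np.cumsum(mask, axis=1)],
            axis=1,
        )


def _indices(stack: LandscapeStack) -> dict[str, _ClassIndex]:
    cache = getattr(stack, "_class_index_cache", None)
    if cache is None:
        cache = {}
        stack._class_index_cache = cache
    return cache


def _class_index(stack: LandscapeStack, name: str) -> _ClassIndex:
    cache = _indices(stack)
    if name not in cache:
        cache[name] = _ClassIndex(stack, name)
    return cache[name]


def _check_points(stack: LandscapeStack, x: np.ndarray, y: np.ndarray) -> None:
    inside = stack.contains(x, y)
    if not np.all(inside):
        i = int(np.argmin(inside))
        raise DomainError(f"point ({x[i]:.1f}, {y[i]:.1f}) outside raster extent")


def distance_to(
    stack: LandscapeStack,
    class_name: str,
    points,
    config: CovariateConfig | None = None,
) -> np.ndarray:
    """Truncated distance (m) from each point to the nearest cell centre of the class."""
    config = config or CovariateConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    _check_points(stack, x, y)
    cap = config.distance_truncation_m
    idx = _class_index(stack, class_name)  # raises SchemaError on unknown class
    if idx.tree is None:
        return np.full(len(pts), cap)
    # a point inside a class cell is on-feature regardless of centre offsets
    r, c = stack.cell_of(x, y)
    on_feature = stack.class_mask(class_name)[r, c]
    d, _ = idx.tree.query(pts, k=1)
    d = np.minimum(np.asarray(d, dtype=float), cap)
    d[on_feature] = 0.0
    return d


def _buffer_counts(
    stack: LandscapeStack, index: _ClassIndex | None, x, y, radius_m: float
) -> np.ndarray:
    """Cells-in-buffer counts via per-row cumulative sums (exact, vectorised).

    With index=None counts all grid cells (the clipped-area denominator).
    """
    rows, cols = stack.shape
    res = stack.resolution_m
    x0, y0 = stack.origin
    fx = (np.asarray(x, dtype=float) - x0) / res  # col units
    fy_row = rows - (np.asarray(y, dtype=float) - y0) / res  # row units, row 0 top
    rho = radius_m / res
    counts = np.zeros(len(fx), dtype=np.int64)
    r_lo = np.ceil(fy_row - 0.5 - rho).astype(int)
    r_hi = np.floor(fy_row - 0.5 + rho).astype(int)
    max_span = int(np.floor(2 * rho)) + 1
    for off in range(max_span + 1):
        r = r_lo + off
        active = (r <= r_hi) & (r >= 0) & (r < rows)
        if not active.any():
            continue
        dy = (r + 0.5) - fy_row
        w2 = rho**2 - dy**2
        active &= w2 >= 0
        w = np.sqrt(np.where(w2 > 0, w2, 0.0))
        c_lo = np.clip(np.ceil(fx - 0.5 - w).astype(int), 0, cols)
        c_hi = np.clip(np.floor(fx - 0.5 + w).astype(int) + 1, 0, cols)
        span = np.maximum(c_hi - c_lo, 0)
        ai = np.nonzero(active & (span > 0))[0]
        if index is None:
            counts[ai] += span[ai]
        else:
            rc = np.clip(r[ai], 0, rows - 1)
            counts[ai] += index.rowcum[rc, c_hi[ai]] - index.rowcum[rc, c_lo[ai]]
    return counts


def density_in_buffer(
    stack: LandscapeStack,
    class_name: str,
    points,
    config: CovariateConfig | None = None,
) -> np.ndarray:
    """Class density (pixels/m²) in the buffer around each point."""
    config = config or CovariateConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    _check_points(stack, x, y)
    idx = _class_index(stack, class_name)
    feat = _buffer_counts(stack, idx, x, y, config.buffer_radius_m)
    total = _buffer_counts(stack, None, x, y, config.buffer_radius_m)
    area = total * stack.resolution_m**2
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(area > 0, feat / area, 0.0)
    return dens


def covariate_vector(
    stack: LandscapeStack, point, config: CovariateConfig | None = None
) -> CovariateVector:
    """dist/dens for every schema class at one point."""
    config = config or CovariateConfig()
    pt = [point]
    dist = {}
    dens = {}
    for name in stack.schema.names:
        dist[name] = float(distance_to(stack, name, pt, config)[0])
        dens[name] = float(density_in_buffer(stack, name, pt, config)[0])
    return CovariateVector(dist=dist, dens=dens)


def scale_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Standardise dist/dens columns (current + lagged) per individual.

    Each column becomes (x − mean)/sd over all used+available rows of that
    individual, with the sample (n−1) standard deviation. Zero-variance
    columns are set to 0 and recorded in ``table.attrs['zero_variance']`` as
    (individual_id, column) pairs.
    """
    out = table.copy()
    cols = [c for c in table.columns if c.startswith(SCALED_PREFIXES)]
    flags: list[tuple[str, str]] = []
    for ind, idx in out.groupby("individual_id").groups.items():
        block = out.loc[idx, cols]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        degenerate = ~(sd > 0)
        scaled = (block - mu) / sd.where(~degenerate, 1.0)
        scaled.loc[:, degenerate] = 0.0
        out.loc[idx, cols] = scaled
        flags.extend((str(ind), c) for c in sd.index[degenerate])
    out.attrs = dict(table.attrs)
    out.attrs["zero_variance"] = flags
    return out
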