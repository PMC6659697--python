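"""Seeded synthetic landscape generator and raster I/O.

A :class:`LandscapeStack` bundles a categorical cover raster (the polygonal
classes tile the grid), a protected-area boolean overlay and one boolean
overlay per linear class, all on a shared planar-metre grid.

Generation strategy
-------------------
* Polygonal cover: one smoothed Gaussian random field per class; cells are
  assigned greedily, class by class, to the unassigned cells where that
  class's field is highest, until its target cell count is met. Smoothing
  produces contiguous patches (forest blocks, wetlands) so that
  corridor-style structure exists to be selected for.
* Linear features (streams, roads, rail): correlated random-walk polylines
  entering from a random edge, rasterised one cell wide, added until the
  target length density is reached.
* Protected areas: discs / axis-aligned rectangles with log-normal areas
  around ``pa_mean_area_m2``, placed to avoid overlap where possible; they
  overlay any cover class (PAs contain development, crops, roads...).

Coordinate convention (used everywhere in the package): planar metres, origin
at the lower-left corner; cell (row, col) has its centre at
``(x0 + (col + 0.5) * res, y0 + (rows - row - 0.5) * res)`` — row 0 is the
top row, as in the ESRI ASCII grid format.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigurationError, FormatError, SchemaError
from .schema import FeatureSchema, default_schema

__all__ = [
    "LandscapeConfig",
    "LandscapeStack",
    "generate_landscape",
    "write_ascii_grid",
    "read_ascii_grid",
]


def _default_cover_fractions() -> dict[str, float]:
    # Aspen-parkland working landscape: deciduous-dominant natural cover
    # interspersed with agriculture; fractions sum to 1.
    return {
        "bare": 0.02,
        "deciduous": 0.20,
        "coniferous": 0.08,
        "mixed": 0.12,
        "wetlands": 0.10,
        "grasslands": 0.10,
        "lakes": 0.04,
        "shrubs": 0.06,
        "development": 0.05,
        "crops": 0.12,
        "forage": 0.11,
    }


def _default_linear_density() -> dict[str, float]:
    # km of feature per km^2 of landscape.
    return {"streams": 0.5, "roads": 1.2, "rail_lines": 0.1}


@dataclass
class LandscapeConfig:
    """Parameters for one synthetic landscape realisation.

    extent_m
        (width, height) in metres; must be integer multiples of
        ``resolution_m``.
    cover_fractions
        Target areal fraction per polygonal non-PA class; must sum to 1.
    linear_density
        Target total feature length per unit area, km/km², per linear class.
    pa_count, pa_mean_area_m2
        Number and mean (log-normal) area of protected-area patches.
    patch_sigma_cells
        Gaussian smoothing radius (in cells) of the cover random fields;
        controls patch grain.
    """

    extent_m: tuple[float, float] = (15_000.0, 9_000.0)
    resolution_m: float = 30.0
    seed: int = 0
    cover_fractions: dict[str, float] = field(default_factory=_default_cover_fractions)
    linear_density: dict[str, float] = field(default_factory=_default_linear_density)
    pa_count: int = 12
    pa_mean_area_m2: float = 2.0e6
    patch_sigma_cells: float = 4.0

    def validate(self, schema: FeatureSchema) -> None:
        w, h = self.extent_m
        res = self.resolution_m
        if res <= 0 or w <= 0 or h <= 0:
            raise ConfigurationError("extent and resolution must be positive")
        for dim in (w, h):
            if abs(dim / res - round(dim / res)) > 1e-9:
                raise ConfigurationError(
                    f"resolution {res} m does not divide extent {dim} m"
                )
        missing = set(self.cover_fractions) - set(schema.polygonal_cover)
        if missing:
            raise SchemaError(f"cover_fractions reference unknown classes: {missing}")
        total = sum(self.cover_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"polygonal cover fractions must sum to 1 (got {total!r})"
            )
        if any(f < 0 or f > 1 for f in self.cover_fractions.values()):
            raise ConfigurationError("cover fractions must lie in [0, 1]")
        unknown = set(self.linear_density) - set(schema.linear)
        if unknown:
            raise SchemaError(f"linear_density references unknown classes: {unknown}")
        if self.pa_count < 0 or self.pa_mean_area_m2 <= 0:
            raise ConfigurationError("pa_count >= 0 and pa_mean_area_m2 > 0 required")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.extent_m[1] / self.resolution_m)),
            int(round(self.extent_m[0] / self.resolution_m)),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        d = dict(d)
        if "extent_m" in d:
            d["extent_m"] = tuple(d["extent_m"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("landscape", doc))


@dataclass
class LandscapeStack:
    """Cover raster + overlays on a shared grid; source of all covariates."""

    cover: np.ndarray  # int codes, index into class_names
    pa_mask: np.ndarray  # bool
    linear_masks: dict[str, np.ndarray]  # class -> bool
    origin: tuple[float, float]  # (x0, y0) of lower-left corner, metres
    resolution_m: float
    class_names: list[str]  # polygonal cover classes, code order
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        shp = self.cover.shape
        if self.pa_mask.shape != shp or any(
            m.shape != shp for m in self.linear_masks.values()
        ):
            raise ConfigurationError("all raster bands must share one shape")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.cover.shape

    @property
    def extent_m(self) -> tuple[float, float]:
        rows, cols = self.cover.shape
        return cols * self.resolution_m, rows * self.resolution_m

    def contains(self, x, y) -> np.ndarray:
        x0, y0 = self.origin
        w, h = self.extent_m
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= x0) & (x <= x0 + w) & (y >= y0) & (y <= y0 + h)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point (boundary snapped in)."""
        x0, y0 = self.origin
        rows, cols = self.cover.shape
        res = self.resolution_m
        col = np.clip(np.floor((np.asarray(x) - x0) / res).astype(int), 0, cols - 1)
        # y increases upward; row 0 is the top row
        row = np.clip(
            rows - 1 - np.floor((np.asarray(y) - y0) / res).astype(int), 0, rows - 1
        )
        return row, col

    def cell_centers(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        nrows = self.cover.shape[0]
        res = self.resolution_m
        return (
            x0 + (np.asarray(cols) + 0.5) * res,
            y0 + (nrows - np.asarray(rows) - 0.5) * res,
        )

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean grid of the named class (cover, linear overlay, or PA)."""
        entry = self.schema.entry(name)
        if name in self.linear_masks:
            return self.linear_masks[name]
        if entry.category == "protected_area":
            return self.pa_mask
        if name in self.class_names:
            return self.cover == self.class_names.index(name)
        raise SchemaError(f"class {name!r} has no raster band in this stack")

    def in_pa(self, x, y) -> np.ndarray:
        r, c = self.cell_of(x, y)
        return self.pa_mask[r, c]

    # -- I/O (ESRI ASCII grids + JSON legend) ------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(directory / "cover.asc", self.cover, self.origin, self.resolution_m)
        write_ascii_grid(
            directory / "pa_mask.asc", self.pa_mask.astype(int), self.origin, self.resolution_m
        )
        for name, mask in self.linear_masks.items():
            write_ascii_grid(
                directory / f"linear_{name}.asc",
                mask.astype(int),
                self.origin,
                self.resolution_m,
            )
        legend = {
            "class_names": self.class_names,
            "linear_classes": sorted(self.linear_masks),
            "schema": [
                {"name": e.name, "category": e.category, "geometry": e.geometry}
                for e in self.schema.entries
            ],
        }
        (directory / "legend.json").write_text(json.dumps(legend, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "LandscapeStack":
        directory = Path(directory)
        legend = json.loads((directory / "legend.json").read_text())
        from .schema import FeatureEntry

        schema = FeatureSchema(
            [FeatureEntry(e["name"], e["category"], e["geometry"]) for e in legend["schema"]]
        )
        cover, origin, res = read_ascii_grid(directory / "cover.asc")
        pa, _, _ = read_ascii_grid(directory / "pa_mask.asc")
        linear = {}
        for name in legend["linear_classes"]:
            grid, _, _ = read_ascii_grid(directory / f"linear_{name}.asc")
            linear[name] = grid.astype(bool)
        return cls(
            cover=cover.astype(int),
            pa_mask=pa.astype(bool),
            linear_masks=linear,
            origin=origin,
            resolution_m=res,
            class_names=legend["class_names"],
            schema=schema,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_landscape(
    config: LandscapeConfig, schema: FeatureSchema | None = None
) -> LandscapeStack:
    """Generate a seeded synthetic landscape; bit-identical for equal inputs."""
    schema = schema or default_schema()
    config.validate(schema)
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    n_cells = rows * cols

    # --- polygonal cover by greedy field thresholding ---
    classes = [c for c in schema.polygonal_cover if config.cover_fractions.get(c, 0) > 0]
    targets = np.array([config.cover_fractions[c] for c in classes])
    counts = np.floor(targets * n_cells).astype(int)
    counts[-1] += n_cells - counts.sum()  # last class absorbs rounding remainder

    fields = {}
    for c in classes:
        noise = rng.standard_normal((rows, cols))
        fields[c] = ndimage.gaussian_filter(noise, config.patch_sigma_cells, mode="wrap")

    cover = np.full((rows, cols), -1, dtype=int)
    class_names = list(schema.polygonal_cover)
    unassigned = np.ones(n_cells, dtype=bool)
    order = np.argsort(counts)  # scarce classes first: best shot at their peaks
    for idx in order[:-1]:
        c = classes[idx]
        flat = fields[c].ravel().copy()
        flat[~unassigned] = -np.inf
        take = np.argpartition(-flat, counts[idx])[: counts[idx]]
        cover.ravel()[take] = class_names.index(c)
        unassigned[take] = False
    last = classes[order[-1]]
    cover.ravel()[unassigned] = class_names.index(last)

    # --- linear features: correlated random-walk polylines ---
    width_m, height_m = config.extent_m
    area_km2 = width_m * height_m / 1e6
    linear_masks = {}
    for name in schema.linear:
        mask = np.zeros((rows, cols), dtype=bool)
        target_m = config.linear_density.get(name, 0.0) * area_km2 * 1000.0
        drawn = 0.0
        while drawn < target_m:
            drawn += _draw_polyline(mask, rng, config.resolution_m)
        linear_masks[name] = mask

    # --- protected-area patches ---
    pa_mask = np.zeros((rows, cols), dtype=bool)
    placed = 0
    tries = 0
    sdlog = 0.35
    while placed < config.pa_count and tries < 60 * max(config.pa_count, 1):
        tries += 1
        area = rng.lognormal(math.log(config.pa_mean_area_m2) - sdlog**2 / 2, sdlog)
        patch = _pa_patch(rng, area, rows, cols, config.resolution_m)
        if patch is None:
            continue
        if (pa_mask & patch).any() and tries < 40 * max(config.pa_count, 1):
            continue  # keep patches disjoint while the budget allows
        pa_mask |= patch
        placed += 1

    return LandscapeStack(
        cover=cover,
        pa_mask=pa_mask,
        linear_masks=linear_masks,
        origin=(0.0, 0.0),
        resolution_m=config.resolution_m,
        class_names=class_names,
        schema=schema,
    )


def _draw_polyline(mask: np.ndarray, rng: np.random.Generator, res: float) -> float:
    """Rasterise one edge-to-exit correlated walk into mask; return its length (m)."""
    rows, cols = mask.shape
    edge = rng.integers(4)
    if edge == 0:  # west
        r, c, heading = rng.uniform(0, rows), 0.0, rng.normal(0.0, 0.4)
    elif edge == 1:  # east
        r, c, heading = rng.uniform(0, rows), cols - 1.0, math.pi + rng.normal(0.0, 0.4)
    elif edge == 2:  # north (row 0)
        r, c, heading = 0.0, rng.uniform(0, cols), -math.pi / 2 + rng.normal(0.0, 0.4)
    else:  # south
        r, c, heading = rows - 1.0, rng.uniform(0, cols), math.pi / 2 + rng.normal(0.0, 0.4)
    # heading in (col, -row) axes so that +pi/2 moves toward smaller row
    length_cells = 0.0
    step = 0.5  # sub-cell sampling keeps the rasterised path connected
    max_iter = int(6 * (rows + cols))
    for _ in range(max_iter):
        c += step * math.cos(heading)
        r -= step * math.sin(heading)
        if not (0 <= r < rows and 0 <= c < cols):
            break
        mask[int(r), int(c)] = True
        heading += rng.normal(0.0, 0.15)
        length_cells += step
    return length_cells * res


def _pa_patch(
    rng: np.random.Generator, area_m2: float, rows: int, cols: int, res: float
) -> np.ndarray | None:
    """One disc or rectangle of ~area_m2, fully inside the grid, as a bool mask."""
    if rng.random() < 0.5:  # disc
        radius_c = math.sqrt(area_m2 / math.pi) / res
        if 2 * radius_c + 2 >= min(rows, cols):
            return None
        cr = rng.uniform(radius_c, rows - radius_c)
        cc = rng.uniform(radius_c, cols - radius_c)
        rr, cc_idx = np.ogrid[:rows, :cols]
        return (rr + 0.5 - cr) ** 2 + (cc_idx + 0.5 - cc) ** 2 <= radius_c**2
    aspect = rng.uniform(0.5, 2.0)
    h_c = math.sqrt(area_m2 * aspect) / res
    w_c = math.sqrt(area_m2 / aspect) / res
    if h_c + 2 >= rows or w_c + 2 >= cols:
        return None
    top = rng.uniform(0, rows - h_c)
    left = rng.uniform(0, cols - w_c)
    patch = np.zeros((rows, cols), dtype=bool)
    patch[int(round(top)) : int(round(top + h_c)), int(round(left)) : int(round(left + w_c))] = True
    return patch


def pa_component_count(stack: LandscapeStack) -> int:
    """Number of connected protected-area patches (8-connectivity)."""
    _, n = ndimage.label(stack.pa_mask, structure=np.ones((3, 3)))
    return n


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    origin: tuple[float, float],
    resolution_m: float,
) -> None:
    rows, cols = grid.shape
    is_int = np.issubdtype(grid.dtype, np.integer) or grid.dtype == bool
    header = (
        f"ncols {cols}\nnrows {rows}\n"
        f"xllcorner {origin[0]:.6f}\nyllcorner {origin[1]:.6f}\n"
        f"cellsize {resolution_m:.6f}\nNODATA_value -9999\n"
    )
    fmt = "%d" if is_int else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    origin = (hdr["xllcorner"], hdr["yllcorner"])
    if grid.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise FormatError(f"grid shape mismatch in {path}")
    if np.allclose(grid, np.round(grid)):
        grid = grid.astype(int)
    return grid, origin, hdr["cellsize"]
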