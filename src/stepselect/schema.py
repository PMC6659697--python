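"""Landscape feature schema: the class list every covariate is computed over.

The default schema carries the 15 feature classes of a boreal-parkland working
landscape — nine natural (eight polygonal plus streams), five anthropogenic
(three polygonal plus rail lines and roads) and one protected-area overlay.
Covariate columns are named after these classes (``dist_deciduous``,
``dens_protected_areas``, ...), so class names are snake_case identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError

NATURAL = "natural"
ANTHROPOGENIC = "anthropogenic"
PROTECTED_AREA = "protected_area"

POLYGONAL = "polygonal"
LINEAR = "linear"


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    category: str  # natural | anthropogenic | protected_area
    geometry: str  # polygonal | linear


@dataclass
class FeatureSchema:
    """Ordered list of landscape feature classes.

    Invariants: names unique; exactly one entry has category
    ``protected_area``; categories/geometries drawn from the fixed vocabulary.
    """

    entries: list[FeatureEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise SchemaError("feature class names must be unique")
        for e in self.entries:
            if e.category not in (NATURAL, ANTHROPOGENIC, PROTECTED_AREA):
                raise SchemaError(f"unknown category {e.category!r} for {e.name!r}")
            if e.geometry not in (POLYGONAL, LINEAR):
                raise SchemaError(f"unknown geometry {e.geometry!r} for {e.name!r}")
        n_pa = sum(e.category == PROTECTED_AREA for e in self.entries)
        if self.entries and n_pa != 1:
            raise SchemaError("schema must contain exactly one protected_area entry")

    # -- lookups ----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def entry(self, name: str) -> FeatureEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise SchemaError(f"unknown feature class {name!r}")

    @property
    def pa_name(self) -> str:
        return next(e.name for e in self.entries if e.category == PROTECTED_AREA)

    @property
    def polygonal_cover(self) -> list[str]:
        """Polygonal classes that tile the cover raster (excludes the PA overlay)."""
        return [
            e.name
            for e in self.entries
            if e.geometry == POLYGONAL and e.category != PROTECTED_AREA
        ]

    @property
    def linear(self) -> list[str]:
        return [e.name for e in self.entries if e.geometry == LINEAR]


def default_schema() -> FeatureSchema:
    """The 15-class feature schema used throughout the pipeline."""
    return FeatureSchema(
        [
            FeatureEntry("bare", NATURAL, POLYGONAL),
            FeatureEntry("deciduous", NATURAL, POLYGONAL),
            FeatureEntry("coniferous", NATURAL, POLYGONAL),
            FeatureEntry("mixed", NATURAL, POLYGONAL),
            FeatureEntry("wetlands", NATURAL, POLYGONAL),
            FeatureEntry("grasslands", NATURAL, POLYGONAL),
            FeatureEntry("lakes", NATURAL, POLYGONAL),
            FeatureEntry("shrubs", NATURAL, POLYGONAL),
            FeatureEntry("streams", NATURAL, LINEAR),
            FeatureEntry("development", ANTHROPOGENIC, POLYGONAL),
            FeatureEntry("crops", ANTHROPOGENIC, POLYGONAL),
            FeatureEntry("forage", ANTHROPOGENIC, POLYGONAL),
            FeatureEntry("rail_lines", ANTHROPOGENIC, LINEAR),
            FeatureEntry("roads", ANTHROPOGENIC, LINEAR),
            FeatureEntry("protected_areas", PROTECTED_AREA, POLYGONAL),
        ]
    )
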