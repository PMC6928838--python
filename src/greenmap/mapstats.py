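"""Terrain maps and the area/biomass/contamination accounting.

Per-tile classifications are assembled into a rectangular grid map. Each
cell covers ``(gsd * tile_size)^2`` square metres on the ground (6.86 m^2
at the default 0.0131 m/px, 200 px profile). From per-class tile counts:

- per-class area = count x per-tile area,
- biomass %      = 100 x (vegetated tiles, contaminated or not) / total
                   (classes H, D, UNH, HC, DC, UNHC),
- contamination %= 100 x (tiles of any contaminated class) / total
                   (classes HC, DC, UNHC, NVC).

Vegetated and non-vegetated classes partition the grid, so
biomass% + 100*(NV+NVC)/total = 100 always. Percentages and areas are
reported to 2 decimal places.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .geotile import DEFAULT_GSD, DEFAULT_TILE_SIZE, tile_footprint_area
from .taxonomy import CLASS_ORDER, DEFAULT_PALETTE, get_class

__all__ = [
    "ClassificationMap",
    "TerrainSummary",
    "BIOMASS_CLASSES",
    "CONTAMINATED_CLASSES",
    "summarize",
    "class_area",
    "render_map",
    "cell_detail",
    "region_summary",
    "map_to_csv",
    "map_to_geojson",
    "save_map_png",
]

#: Classes with a vegetation component (counted as biomass).
BIOMASS_CLASSES = ("H", "D", "UNH", "HC", "DC", "UNHC")
#: Classes indicating garbage contamination.
CONTAMINATED_CLASSES = ("HC", "DC", "UNHC", "NVC")


@dataclasses.dataclass
class ClassificationMap:
    """Grid of per-cell class codes with optional probabilities and geo.

    ``codes`` is a (rows, cols) array of class-code strings; ``probs`` an
    optional (rows, cols, 8) probability array; ``geo`` an optional
    (rows, cols, 2) array of (lat, lon) cell centers.
    """

    codes: np.ndarray
    gsd_m_per_px: float = DEFAULT_GSD
    tile_size: int = DEFAULT_TILE_SIZE
    probs: np.ndarray | None = None
    geo: np.ndarray | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=object)
        if codes.ndim != 2:
            raise ValueError("map grid must be 2-dimensional")
        bad = set(codes.ravel()) - set(CLASS_ORDER)
        if bad:
            raise ValueError(f"unknown class codes in map: {sorted(bad)}")
        if self.probs is not None and self.probs.shape[:2] != codes.shape:
            raise ValueError("probability grid shape does not match the map")
        if self.geo is not None and self.geo.shape[:2] != codes.shape:
            raise ValueError("geo grid shape does not match the map")
        self.codes = codes

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def class_counts(self) -> np.ndarray:
        flat = self.codes.ravel()
        return np.array([int((flat == c).sum()) for c in CLASS_ORDER], dtype=np.int64)


@dataclasses.dataclass
class TerrainSummary:
    """Per-class counts and areas plus terrain-level percentages."""

    counts: dict[str, int]
    areas_m2: dict[str, float]
    total_area_m2: float
    biomass_percent: float
    contamination_percent: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def class_area(
    count: int,
    gsd_m_per_px: float = DEFAULT_GSD,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> float:
    """Ground area of ``count`` tiles in m^2, to 2 decimal places.

    ``count x per-tile area`` with the per-tile area already rounded to
    2 dp (6.86 m^2 at the default profile), matching cell-level accounting
    such as 5 tiles -> 34.30 m^2.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    return round(count * tile_footprint_area(gsd_m_per_px, tile_size, 2), 2)


def summarize(
    counts: Sequence[int] | np.ndarray,
    gsd_m_per_px: float = DEFAULT_GSD,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> TerrainSummary:
    """Terrain summary from per-class tile counts (canonical class order)."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (len(CLASS_ORDER),):
        raise ValueError(f"expected {len(CLASS_ORDER)} per-class counts")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("summary undefined for an empty terrain (zero tiles)")
    by_code = dict(zip(CLASS_ORDER, (int(c) for c in counts)))
    areas = {c: class_area(by_code[c], gsd_m_per_px, tile_size) for c in CLASS_ORDER}
    biomass = 100.0 * sum(by_code[c] for c in BIOMASS_CLASSES) / total
    contamination = 100.0 * sum(by_code[c] for c in CONTAMINATED_CLASSES) / total
    return TerrainSummary(
        counts=by_code,
        areas_m2=areas,
        total_area_m2=class_area(total, gsd_m_per_px, tile_size),
        biomass_percent=round(biomass, 2),
        contamination_percent=round(contamination, 2),
    )


def render_map(
    cmap: ClassificationMap,
    palette: dict[str, tuple[int, int, int]] | None = None,
    cell_px: int = 20,
) -> np.ndarray:
    """Render the map as an RGB image of uniform colour cells.

    Output shape is (rows*cell_px, cols*cell_px, 3); deterministic.
    """
    palette = palette or DEFAULT_PALETTE
    rows, cols = cmap.shape
    out = np.zeros((rows * cell_px, cols * cell_px, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            code = cmap.codes[r, c]
            if code not in palette:
                raise ValueError(f"palette has no colour for class {code!r}")
            out[r * cell_px : (r + 1) * cell_px, c * cell_px : (c + 1) * cell_px] = palette[code]
    return out


def cell_detail(cmap: ClassificationMap, row: int, col: int) -> dict:
    """Read-only detail record for one cell: class, area, probabilities, geo."""
    rows, cols = cmap.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"cell ({row}, {col}) outside {rows}x{cols} map")
    code = cmap.codes[row, col]
    cls = get_class(code)
    detail = {
        "row": row,
        "col": col,
        "class_code": code,
        "health": cls.health,
        "contaminated": cls.contaminated,
        "area_m2": class_area(1, cmap.gsd_m_per_px, cmap.tile_size),
        "probabilities": None,
        "geo": None,
    }
    if cmap.probs is not None:
        detail["probabilities"] = {
            c: float(p) for c, p in zip(CLASS_ORDER, cmap.probs[row, col])
        }
    if cmap.geo is not None:
        detail["geo"] = tuple(float(v) for v in cmap.geo[row, col])
    return detail


def region_summary(
    cmap: ClassificationMap, row0: int, col0: int, row1: int, col1: int
) -> TerrainSummary:
    """Summary restricted to the inclusive cell rectangle [row0..row1] x [col0..col1]."""
    sub = cmap.codes[row0 : row1 + 1, col0 : col1 + 1]
    if sub.size == 0:
        raise ValueError("empty region")
    counts = np.array([int((sub == c).sum()) for c in CLASS_ORDER])
    return summarize(counts, cmap.gsd_m_per_px, cmap.tile_size)


def map_to_csv(cmap: ClassificationMap, path: str | Path) -> None:
    """Export one row per cell: row, col, class_code, lat, lon."""
    rows, cols = cmap.shape
    records = []
    for r in range(rows):
        for c in range(cols):
            lat, lon = (None, None)
            if cmap.geo is not None:
                lat, lon = (float(cmap.geo[r, c, 0]), float(cmap.geo[r, c, 1]))
            records.append(
                {"row": r, "col": c, "class_code": cmap.codes[r, c], "lat": lat, "lon": lon}
            )
    pd.DataFrame(records).to_csv(path, index=False)


def map_to_geojson(cmap: ClassificationMap, path: str | Path) -> None:
    """Export cells as a GeoJSON FeatureCollection of ground polygons.

    Requires a georeferenced map. Cell corners are offset from the cell
    center under the same local equirectangular approximation used for
    tiling (1 deg latitude = 111,320 m, longitude scaled by cos latitude).
    """
    if cmap.geo is None:
        raise ValueError("map has no georeference; cannot export GeoJSON")
    half = cmap.gsd_m_per_px * cmap.tile_size / 2.0
    features = []
    rows, cols = cmap.shape
    for r in range(rows):
        for c in range(cols):
            lat, lon = float(cmap.geo[r, c, 0]), float(cmap.geo[r, c, 1])
            dlat = half / 111_320.0
            dlon = half / (111_320.0 * np.cos(np.radians(lat)))
            ring = [
                [lon - dlon, lat - dlat],
                [lon + dlon, lat - dlat],
                [lon + dlon, lat + dlat],
                [lon - dlon, lat + dlat],
                [lon - dlon, lat - dlat],
            ]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "row": r,
                        "col": c,
                        "class_code": cmap.codes[r, c],
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def save_map_png(cmap: ClassificationMap, path: str | Path, cell_px: int = 20) -> None:
    Image.fromarray(render_map(cmap, cell_px=cell_px), mode="RGB").save(path)
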