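"""Grid tiling of aerial images, ground-footprint areas, and tile georeferencing.

A drone survey image is cut into a regular grid of fixed-size square tiles
(partial edge strips are discarded). Each tile's ground footprint follows
from the ground sampling distance (GSD); at the default profile of
0.0131 m/px and 200 px tiles one tile covers (0.0131*200)^2 = 6.86 m^2.

When the source image carries a geographic center (e.g. from EXIF GPS),
tile centers are georeferenced under a local north-up equirectangular
approximation, adequate at the hundred-metre scale of a single frame.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from PIL import Image
from PIL.ExifTags import GPSTAGS, TAGS

__all__ = [
    "SourceImage",
    "Tile",
    "DEFAULT_GSD",
    "DEFAULT_TILE_SIZE",
    "METERS_PER_DEG_LAT",
    "tile_image",
    "tile_footprint_area",
    "georeference_tile",
    "load_image",
    "write_tiles",
]

#: Ground sampling distance at ~30 m flight altitude, metres per pixel.
DEFAULT_GSD = 0.0131
#: Side length of a classification tile, pixels.
DEFAULT_TILE_SIZE = 200
#: Metres per degree of latitude in the local equirectangular approximation.
METERS_PER_DEG_LAT = 111_320.0


@dataclasses.dataclass
class SourceImage:
    """An RGB survey frame with optional georeference.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        RGB raster.
    source_id : str
        Identifier of the frame (used in tile file names).
    center_geo : (lat, lon) in degrees, optional
        Geographic coordinates of the image center.
    altitude_m : float, optional
        Flight altitude above ground.
    gsd_m_per_px : float
        Ground sampling distance, metres per pixel.
    """

    pixels: np.ndarray
    source_id: str = "image"
    center_geo: tuple[float, float] | None = None
    altitude_m: float | None = None
    gsd_m_per_px: float = DEFAULT_GSD

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an RGB raster (H, W, 3); got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1 px")
        if self.gsd_m_per_px <= 0:
            raise ValueError("gsd_m_per_px must be positive")
        if self.center_geo is not None:
            lat, lon = self.center_geo
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"invalid geographic center {self.center_geo}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class Tile:
    """A square RGB patch cut from a source image at a grid position."""

    pixels: np.ndarray
    grid_row: int
    grid_col: int
    source_id: str = "image"
    center_geo: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
            raise ValueError(f"tile must be square RGB; got shape {px.shape}")
        if self.grid_row < 0 or self.grid_col < 0:
            raise ValueError("grid indices must be non-negative")
        self.pixels = px

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def filename(self) -> str:
        return f"{self.source_id}_r{self.grid_row}_c{self.grid_col}.png"


def tile_image(image: SourceImage, tile_size: int = DEFAULT_TILE_SIZE) -> list[Tile]:
    """Cut ``image`` into a regular grid of ``tile_size`` x ``tile_size`` tiles.

    Returns floor(W/ts) * floor(H/ts) tiles in row-major order from the
    top-left; partial strips at the right/bottom edges are discarded. Each
    tile's pixel block is a copy of the corresponding source block, so the
    mosaic of all tiles reproduces the top-left crop of the source exactly.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    n_rows = image.height // tile_size
    n_cols = image.width // tile_size
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            block = image.pixels[
                r * tile_size : (r + 1) * tile_size,
                c * tile_size : (c + 1) * tile_size,
            ].copy()
            geo = None
            if image.center_geo is not None:
                geo = georeference_tile(image, r, c, tile_size)
            tiles.append(Tile(block, r, c, image.source_id, geo))
    return tiles


def tile_footprint_area(
    gsd_m_per_px: float = DEFAULT_GSD,
    tile_size: int = DEFAULT_TILE_SIZE,
    rounding: int = 2,
) -> float:
    """Ground area of one tile in m^2: ``(gsd * tile_size)^2``, rounded.

    At the default profile (0.0131 m/px, 200 px, 2 dp) this is 6.86 m^2,
    the per-tile constant used in all area accounting.
    """
    if gsd_m_per_px <= 0:
        raise ValueError("gsd_m_per_px must be positive")
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    return round((gsd_m_per_px * tile_size) ** 2, rounding)


def georeference_tile(
    image: SourceImage, grid_row: int, grid_col: int, tile_size: int = DEFAULT_TILE_SIZE
) -> tuple[float, float]:
    """Geographic coordinates of a tile center.

    Assumes north-up nadir imagery: pixel offsets from the image center are
    converted to metric east/north offsets via the GSD, then to degrees with
    1 deg latitude = 111,320 m and longitude scaled by cos(latitude).
    """
    if image.center_geo is None:
        raise ValueError("source image has no geographic center (missing GPS metadata)")
    lat0, lon0 = image.center_geo
    row_center_px = grid_row * tile_size + tile_size / 2.0
    col_center_px = grid_col * tile_size + tile_size / 2.0
    east_m = (col_center_px - image.width / 2.0) * image.gsd_m_per_px
    north_m = (image.height / 2.0 - row_center_px) * image.gsd_m_per_px
    lat = lat0 + north_m / METERS_PER_DEG_LAT
    lon = lon0 + east_m / (METERS_PER_DEG_LAT * math.cos(math.radians(lat0)))
    return (lat, lon)


def _rational_to_float(value) -> float:
    try:
        return float(value)
    except TypeError:
        num, den = value
        return num / den


def _dms_to_degrees(dms, ref: str) -> float:
    deg = _rational_to_float(dms[0]) + _rational_to_float(dms[1]) / 60.0 + _rational_to_float(dms[2]) / 3600.0
    return -deg if ref in ("S", "W") else deg


def _read_exif_gps(img: Image.Image) -> tuple[tuple[float, float] | None, float | None]:
    """Extract (lat, lon) and altitude from EXIF GPSInfo when present."""
    exif = img.getexif()
    if not exif:
        return None, None
    gps_ifd = None
    for tag_id in exif:
        if TAGS.get(tag_id) == "GPSInfo":
            try:
                gps_ifd = exif.get_ifd(tag_id)
            except Exception:
                gps_ifd = None
            break
    if not gps_ifd:
        return None, None
    gps = {GPSTAGS.get(k, k): v for k, v in gps_ifd.items()}
    geo = None
    if all(k in gps for k in ("GPSLatitude", "GPSLatitudeRef", "GPSLongitude", "GPSLongitudeRef")):
        lat = _dms_to_degrees(gps["GPSLatitude"], gps["GPSLatitudeRef"])
        lon = _dms_to_degrees(gps["GPSLongitude"], gps["GPSLongitudeRef"])
        geo = (lat, lon)
    alt = _rational_to_float(gps["GPSAltitude"]) if "GPSAltitude" in gps else None
    return geo, alt


def load_image(
    path: str | Path, gsd_m_per_px: float = DEFAULT_GSD, source_id: str | None = None
) -> SourceImage:
    """Load a JPEG/PNG survey frame, reading EXIF GPS metadata when present.

    GPS metadata is optional; without it the image simply has no
    georeference and downstream work proceeds in grid coordinates.
    """
    path = Path(path)
    with Image.open(path) as img:
        geo, alt = _read_exif_gps(img)
        pixels = np.asarray(img.convert("RGB"))
    return SourceImage(
        pixels,
        source_id=source_id or path.stem,
        center_geo=geo,
        altitude_m=alt,
        gsd_m_per_px=gsd_m_per_px,
    )


def write_tiles(tiles: list[Tile], out_dir: str | Path) -> list[Path]:
    """Write tiles as PNG files named ``<source_id>_r<row>_c<col>.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tile in tiles:
        p = out_dir / tile.filename
        Image.fromarray(tile.pixels, mode="RGB").save(p)
        paths.append(p)
    return paths
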