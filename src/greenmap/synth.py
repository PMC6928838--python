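"""Deterministic synthetic tiles and scenes with ground truth.

Generates eight-class terrain textures so the whole pipeline — tiling,
training, evaluation, mapping — is testable without real drone imagery.
Each health state gets a distinct band-limited colour texture (smoothed
uniform noise):

- healthy: green-dominant correlated noise (G mean above R and B),
- dry: yellow/brown (R ~ G > B),
- unhealthy: patchy blend of green and brown blobs (deliberately
  overlapping the healthy and dry statistics),
- no_vegetation: low-saturation gray/asphalt texture.

Contaminated variants overlay a handful of small, high-contrast convex
polygons ("litter") on the otherwise identical clean texture; only the
overlay mask differs between a clean tile and its contaminated twin at the
same seed. Every tile is a pure function of (class code, size, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw
from scipy.ndimage import uniform_filter

from .geotile import SourceImage, Tile
from .taxonomy import CLASS_ORDER, Manifest, get_class

__all__ = ["SceneSpec", "synth_tile", "synth_scene", "tile_seed", "write_scene"]


@dataclasses.dataclass
class SceneSpec:
    """Recipe for a synthetic survey scene.

    Either ``class_layout`` (a grid of class codes) or ``class_mix``
    (per-class sampling probabilities) defines the ground truth; with
    neither, classes are drawn uniformly.
    """

    grid_rows: int
    grid_cols: int
    tile_size: int = 200
    seed: int = 0
    class_layout: list[list[str]] | None = None
    class_mix: dict[str, float] | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.class_layout is not None:
            if len(self.class_layout) != self.grid_rows or any(
                len(row) != self.grid_cols for row in self.class_layout
            ):
                raise ValueError("class_layout dimensions do not match the grid")
            for row in self.class_layout:
                for code in row:
                    get_class(code)  # raises on unknown codes
        if self.class_mix is not None:
            if not np.isclose(sum(self.class_mix.values()), 1.0):
                raise ValueError("class_mix probabilities must sum to 1")
            for code in self.class_mix:
                get_class(code)
        if self.source_id is None:
            self.source_id = f"synth_s{self.seed}"

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def tile_seed(master_seed: int, row: int, col: int) -> int:
    """Per-cell seed derived from a master seed and grid position.

    Stable across runs and platforms, so a scene can be regenerated
    cell-by-cell and still match the full-scene output exactly.
    """
    ss = np.random.SeedSequence([abs(int(master_seed)), int(row), int(col)])
    return int(ss.generate_state(1)[0] % (2**31))


# Base colours per health state (mean RGB of the clean texture).
_BASE = {
    "healthy": (62.0, 128.0, 52.0),
    "dry": (168.0, 148.0, 70.0),
    "no_vegetation": (115.0, 113.0, 118.0),
}
_UNH_GREEN = (70.0, 115.0, 55.0)
_UNH_BROWN = (142.0, 112.0, 58.0)

_LITTER_COLORS = [
    (245, 245, 240),  # white plastic / paper
    (220, 45, 40),    # saturated red
    (45, 70, 220),    # saturated blue
    (250, 210, 40),   # bright packaging yellow
]


def _smooth_field(rng: np.random.Generator, size: int, scale: int) -> np.ndarray:
    """Zero-mean correlated noise field in roughly [-1, 1]."""
    field = uniform_filter(rng.uniform(-1.0, 1.0, (size, size)), size=scale, mode="wrap")
    peak = np.abs(field).max()
    return field / peak if peak > 0 else field


def _base_texture(health: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Clean (uncontaminated) texture for a health state, float RGB."""
    coarse = max(3, size // 6)
    fine = max(2, size // 25)
    shade = _smooth_field(rng, size, coarse)  # large-scale illumination
    grain = _smooth_field(rng, size, fine)    # fine texture grain

    if health == "unhealthy":
        # patchy mixture: smoothed blob mask blending green and brown
        blobs = _smooth_field(rng, size, max(3, size // 4))
        frac = rng.uniform(0.35, 0.65)  # brown fraction varies per tile
        thresh = np.quantile(blobs, 1.0 - frac)
        mix = 1.0 / (1.0 + np.exp(-(blobs - thresh) * 12.0))  # soft edges
        img = np.empty((size, size, 3))
        for ch in range(3):
            base = _UNH_GREEN[ch] * (1 - mix) + _UNH_BROWN[ch] * mix
            img[..., ch] = base + 14.0 * shade + 10.0 * grain
        return img

    base = _BASE[health]
    amp_shade = {"healthy": 20.0, "dry": 16.0, "no_vegetation": 9.0}[health]
    amp_grain = {"healthy": 14.0, "dry": 12.0, "no_vegetation": 6.0}[health]
    jitter = rng.uniform(-6.0, 6.0, 3)  # per-tile colour cast
    img = np.empty((size, size, 3))
    for ch in range(3):
        img[..., ch] = base[ch] + jitter[ch] + amp_shade * shade + amp_grain * grain
    return img


def _litter_mask_and_colors(
    size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mask (bool) and colour image of 3-10 small convex litter polygons.

    Each polygon's circumradius is at most 0.105 * size, so a single piece
    covers < 5% of the tile; a running coverage cap keeps the whole overlay
    under 25% of the pixels.
    """
    n_poly = int(rng.integers(3, 11))
    mask_img = Image.new("L", (size, size), 0)
    color_img = Image.new("RGB", (size, size), (0, 0, 0))
    mdraw = ImageDraw.Draw(mask_img)
    cdraw = ImageDraw.Draw(color_img)
    for i in range(n_poly):
        # draw all rng values up front so the stream consumption is fixed
        cx, cy = rng.uniform(0.12 * size, 0.88 * size, 2)
        radius = rng.uniform(0.055, 0.105) * size
        k = int(rng.integers(4, 9))
        angles = np.sort(rng.uniform(0, 2 * np.pi, k))
        radii = radius * rng.uniform(0.75, 1.0, k)
        color = _LITTER_COLORS[int(rng.integers(0, len(_LITTER_COLORS)))]
        if i >= 3 and (np.asarray(mask_img) > 0).mean() > 0.18:
            continue  # coverage cap: adding one more piece stays < 25%
        pts = [(cx + r * np.cos(a), cy + r * np.sin(a)) for a, r in zip(angles, radii)]
        mdraw.polygon(pts, fill=255)
        cdraw.polygon(pts, fill=color)
    mask = np.asarray(mask_img) > 0
    return mask, np.asarray(color_img).astype(np.float64)


def synth_tile(class_code: str, tile_size: int, seed: int) -> Tile:
    """Generate one synthetic tile, deterministic for (code, size, seed).

    The clean texture consumes only the base random stream, and litter only
    a separate stream, so ``synth_tile("HC", s, seed)`` equals
    ``synth_tile("H", s, seed)`` everywhere outside the litter mask.
    """
    cls = get_class(class_code)
    if tile_size < 16:
        raise ValueError("tile_size must be >= 16")
    base_rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 0]))
    img = _base_texture(cls.health, tile_size, base_rng)
    if cls.contaminated:
        litter_rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 1]))
        mask, colors = _litter_mask_and_colors(tile_size, litter_rng)
        img[mask] = colors[mask]
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Tile(pixels, 0, 0, f"synth_{class_code}_{seed}")


def _sample_layout(spec: SceneSpec) -> list[list[str]]:
    if spec.class_layout is not None:
        return spec.class_layout
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(spec.seed)), 2]))
    if spec.class_mix is not None:
        codes = list(spec.class_mix.keys())
        probs = np.array([spec.class_mix[c] for c in codes])
        probs = probs / probs.sum()
    else:
        codes, probs = list(CLASS_ORDER), np.full(8, 1 / 8)
    draw = rng.choice(len(codes), size=(spec.grid_rows, spec.grid_cols), p=probs)
    return [[codes[draw[r, c]] for c in range(spec.grid_cols)] for r in range(spec.grid_rows)]


def synth_scene(spec: SceneSpec) -> tuple[SourceImage, Manifest]:
    """Render a full scene image plus its ground-truth manifest.

    Tiling the returned image with ``tile_image`` at ``spec.tile_size``
    reproduces, bit-exactly, the per-cell ``synth_tile`` outputs at seeds
    ``tile_seed(spec.seed, row, col)``.
    """
    layout = _sample_layout(spec)
    ts = spec.tile_size
    canvas = np.zeros((spec.grid_rows * ts, spec.grid_cols * ts, 3), dtype=np.uint8)
    records = []
    for r in range(spec.grid_rows):
        for c in range(spec.grid_cols):
            code = layout[r][c]
            tile = synth_tile(code, ts, tile_seed(spec.seed, r, c))
            canvas[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = tile.pixels
            records.append(
                {
                    "tile_path": f"{spec.source_id}_r{r}_c{c}.png",
                    "source_id": spec.source_id,
                    "grid_row": r,
                    "grid_col": c,
                    "class_code": code,
                }
            )
    image = SourceImage(canvas, source_id=spec.source_id)
    return image, Manifest.from_records(records)


def write_scene(spec: SceneSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a scene PNG, its tiles, and a ground-truth manifest CSV.

    The manifest's ``tile_path`` entries point at the written tile files, so
    it can be fed directly to training and prediction.
    """
    out_dir = Path(out_dir)
    tiles_dir = out_dir / "tiles"
    tiles_dir.mkdir(parents=True, exist_ok=True)
    image, manifest = synth_scene(spec)
    scene_path = out_dir / f"{spec.source_id}.png"
    Image.fromarray(image.pixels, mode="RGB").save(scene_path)
    ts = spec.tile_size
    paths = []
    for rec in manifest.frame.itertuples():
        r, c = rec.grid_row, rec.grid_col
        p = tiles_dir / rec.tile_path
        Image.fromarray(
            image.pixels[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts], mode="RGB"
        ).save(p)
        paths.append(str(p))
    frame = manifest.frame.copy()
    frame["tile_path"] = paths
    manifest_path = out_dir / "manifest.csv"
    Manifest(frame).write_csv(manifest_path)
    return scene_path, manifest_path
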