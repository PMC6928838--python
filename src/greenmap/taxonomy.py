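"""Eight-class terrain taxonomy, label manifests, and dataset splitting.

The classification unit is a square image patch ("tile") labelled with one
of eight terrain classes: four health states — healthy vegetation (H), dry
vegetation (D), unhealthy vegetation (UNH), no vegetation (NV) — each with a
contaminated variant (suffix ``C``: HC, DC, UNHC, NVC) indicating visible
garbage on the ground.

Manifests are the dataset currency of the pipeline: CSV tables mapping tile
image files to labels, grid positions and optional geocoordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "HEALTH_STATES",
    "CLASS_ORDER",
    "TerrainClass",
    "Manifest",
    "encode_class",
    "decode_class",
    "get_class",
    "class_counts",
    "split_dataset",
    "DEFAULT_PALETTE",
]

#: Valid health components, in canonical order.
HEALTH_STATES = ("healthy", "dry", "unhealthy", "no_vegetation")

_HEALTH_ABBREV = {
    "healthy": "H",
    "dry": "D",
    "unhealthy": "UNH",
    "no_vegetation": "NV",
}

#: Canonical class-code order used everywhere (counts, model outputs, reports).
CLASS_ORDER = ("H", "D", "UNH", "NV", "HC", "DC", "UNHC", "NVC")


def _darken(rgb: tuple[int, int, int], factor: float = 0.6) -> tuple[int, int, int]:
    return tuple(int(round(c * factor)) for c in rgb)


_BASE_COLORS = {
    "H": (46, 125, 50),     # green
    "D": (249, 231, 76),    # yellow
    "UNH": (230, 126, 34),  # orange
    "NV": (127, 140, 141),  # gray
}

#: Default display palette: clean classes get their hue, contaminated
#: variants the same hue darkened 40%. Any mapping code -> RGB works as a
#: palette; this is only the default.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    **_BASE_COLORS,
    **{h + "C": _darken(rgb) for h, rgb in _BASE_COLORS.items()},
}


@dataclasses.dataclass(frozen=True)
class TerrainClass:
    """One of the eight terrain classes.

    Attributes
    ----------
    code : str
        Canonical class code (e.g. ``"UNHC"``).
    health : str
        Health component, one of :data:`HEALTH_STATES`.
    contaminated : bool
        Whether garbage contamination is present.
    color : tuple of int
        Default RGB display color.
    """

    code: str
    health: str
    contaminated: bool
    color: tuple[int, int, int]


def encode_class(health: str, contaminated: bool) -> TerrainClass:
    """Map a (health, contaminated) pair to its terrain class.

    >>> encode_class("dry", True).code
    'DC'
    """
    if health not in _HEALTH_ABBREV:
        raise ValueError(
            f"unknown health component {health!r}; expected one of {HEALTH_STATES}"
        )
    code = _HEALTH_ABBREV[health] + ("C" if contaminated else "")
    return TerrainClass(code, health, bool(contaminated), DEFAULT_PALETTE[code])


def decode_class(code: str) -> tuple[str, bool]:
    """Inverse of :func:`encode_class`: class code -> (health, contaminated)."""
    cls = get_class(code)
    return cls.health, cls.contaminated


def get_class(code: str) -> TerrainClass:
    """Look up a :class:`TerrainClass` by its code."""
    if code not in CLASS_ORDER:
        raise ValueError(f"unknown class code {code!r}; expected one of {CLASS_ORDER}")
    contaminated = code.endswith("C") and code != "NV"  # no clean code ends in C
    base = code[:-1] if contaminated else code
    health = {v: k for k, v in _HEALTH_ABBREV.items()}[base]
    return TerrainClass(code, health, contaminated, DEFAULT_PALETTE[code])


#: All eight classes in canonical order.
ALL_CLASSES = tuple(get_class(c) for c in CLASS_ORDER)

_MANIFEST_COLUMNS = ["tile_path", "source_id", "grid_row", "grid_col", "class_code", "lat", "lon"]


class Manifest:
    """A labelled tile set: tile file paths, grid positions, class codes.

    Thin wrapper over a :class:`pandas.DataFrame` with fixed columns
    ``tile_path, source_id, grid_row, grid_col, class_code, lat, lon``
    (lat/lon optional, NaN when absent).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _MANIFEST_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        bad = set(frame["class_code"]) - set(CLASS_ORDER)
        if bad:
            raise ValueError(f"manifest contains unknown class codes: {sorted(bad)}")
        if frame["tile_path"].duplicated().any():
            dupes = frame.loc[frame["tile_path"].duplicated(), "tile_path"].tolist()
            raise ValueError(f"duplicate tile_path entries: {dupes[:5]}")
        self.frame = frame.loc[:, _MANIFEST_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "Manifest":
        frame = pd.DataFrame(list(records))
        for col in ("lat", "lon"):
            if col not in frame.columns:
                frame[col] = np.nan
        if frame.empty:
            frame = pd.DataFrame(columns=_MANIFEST_COLUMNS)
        return cls(frame)

    @classmethod
    def empty(cls) -> "Manifest":
        return cls(pd.DataFrame(columns=_MANIFEST_COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "Manifest":
        frame = pd.read_csv(path, dtype={"tile_path": str, "source_id": str, "class_code": str})
        return cls(frame)

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Manifest):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["class_code"].to_numpy()

    @property
    def paths(self) -> list[str]:
        return self.frame["tile_path"].tolist()


def class_counts(manifest: Manifest) -> np.ndarray:
    """Count records per class, in canonical :data:`CLASS_ORDER`.

    Returns an 8-vector of non-negative integers summing to ``len(manifest)``.
    """
    vc = manifest.frame["class_code"].value_counts()
    return np.array([int(vc.get(code, 0)) for code in CLASS_ORDER], dtype=np.int64)


def split_dataset(
    manifest: Manifest, test_count: int, seed: int
) -> tuple[Manifest, Manifest]:
    """Split a manifest into disjoint train/test manifests.

    The split is deterministic for a given ``seed`` and stratified by class
    whenever every present class has at least 2 records and the test draw can
    represent each class; otherwise a plain random split is used. Stratification
    matters here because contaminated classes are rare and a small random test
    draw can miss them entirely.
    """
    n = len(manifest)
    if not 0 <= test_count <= n:
        raise ValueError(f"test_count {test_count} out of range [0, {n}]")
    if test_count == 0:
        return Manifest(manifest.frame.copy()), Manifest.empty()
    if test_count == n:
        return Manifest.empty(), Manifest(manifest.frame.copy())

    labels = manifest.frame["class_code"]
    counts = labels.value_counts()
    stratify = labels if (counts >= 2).all() and test_count >= len(counts) else None
    try:
        train_idx, test_idx = train_test_split(
            np.arange(n), test_size=test_count, random_state=seed, stratify=stratify
        )
    except ValueError:
        train_idx, test_idx = train_test_split(
            np.arange(n), test_size=test_count, random_state=seed
        )
    train = manifest.frame.iloc[np.sort(train_idx)].reset_index(drop=True)
    test = manifest.frame.iloc[np.sort(test_idx)].reset_index(drop=True)
    return Manifest(train), Manifest(test)
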