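"""Chalkley point-count scoring of vascular hot spots.

A 25-point graticule is overlaid on each selected field; the Chalkley count
is the number of grid points coinciding with stained-vessel pixels,
maximized over a small set of graticule rotations and translations (classic
Chalkley practice rotates the eyepiece graticule to maximize hits).  The
per-case microvessel-density (MVD) score is the arithmetic mean over 3-5
fields, dichotomized at a cutoff of six.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError
from .hotspots import FieldSpec
from .segmentation import VesselMask

GRID_SIZE = 25
MIN_POINT_SPACING = 0.15  # in units of the field radius
DEFAULT_LAYOUT_SEED = 17
DEFAULT_CUTOFF = 6.0


@dataclass(frozen=True)
class ChalkleyGrid:
    """25 graticule point offsets in the closed unit disc (unit = field radius)."""

    points: np.ndarray  # (25, 2) array of (x, y) offsets
    layout_id: str
    layout_seed: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (GRID_SIZE, 2):
            raise ConfigError(f"grid must have exactly {GRID_SIZE} points")
        if (np.linalg.norm(pts, axis=1) > 1.0 + 1e-12).any():
            raise ConfigError("all grid points must lie in the closed unit disc")
        object.__setattr__(self, "points", pts)


def make_grid(layout_id: str = "chalkley25", layout_seed: int = DEFAULT_LAYOUT_SEED) -> ChalkleyGrid:
    """Build the 25-point graticule layout for the given seed.

    Points are drawn uniformly in the unit disc by dart-throwing, rejecting
    any candidate closer than 0.15 radius units to an accepted point; the
    spacing floor prevents degenerate clumping.  The layout is a pure
    function of the seed.
    """
    if layout_id != "chalkley25":
        raise ConfigError(f"unknown layout_id {layout_id!r}")
    rng = np.random.default_rng(layout_seed)
    pts: list[np.ndarray] = []
    for _ in range(200_000):
        cand = rng.uniform(-1.0, 1.0, size=2)
        if cand @ cand > 1.0:
            continue
        if all(np.linalg.norm(cand - p) >= MIN_POINT_SPACING for p in pts):
            pts.append(cand)
            if len(pts) == GRID_SIZE:
                break
    else:  # pragma: no cover - spacing floor is far below the packing limit
        raise RuntimeError("failed to place 25 grid points with the spacing floor")
    return ChalkleyGrid(points=np.array(pts), layout_id=layout_id, layout_seed=layout_seed)


@dataclass(frozen=True)
class PlacementSearch:
    """Rotations and translations tried when placing the graticule.

    ``n_rotations`` evenly spaced rotations are combined with
    ``n_translations`` small shifts of the grid center (the identity plus a
    ring of shifts of magnitude ``max_shift_frac`` of the field radius).
    ``n_rotations=1, n_translations=1`` gives the fixed-placement mode used
    for sensitivity analysis.
    """

    n_rotations: int = 8
    n_translations: int = 9
    max_shift_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_rotations < 1 or self.n_translations < 1:
            raise ConfigError("n_rotations and n_translations must be >= 1")
        if not 0.0 <= self.max_shift_frac <= 0.1 + 1e-12:
            raise ConfigError("max_shift_frac must be in [0, 0.1]")

    def rotations(self) -> np.ndarray:
        return np.arange(self.n_rotations) * (2.0 * math.pi / self.n_rotations)

    def translations(self) -> np.ndarray:
        """Shift offsets in radius units; index 0 is always (0, 0)."""
        out = [np.zeros(2)]
        n_ring = self.n_translations - 1
        for j in range(n_ring):
            ang = 2.0 * math.pi * j / n_ring
            out.append(self.max_shift_frac * np.array([math.cos(ang), math.sin(ang)]))
        return np.array(out)


@dataclass(frozen=True)
class FieldCount:
    """Chalkley count of one field and the placement that achieved it."""

    field: FieldSpec
    count: int
    placement: tuple[int, int]  # (rotation index, translation index)

    def __post_init__(self) -> None:
        if not 0 <= self.count <= GRID_SIZE:
            raise ConfigError(f"count must be in [0, {GRID_SIZE}]")


@dataclass(frozen=True)
class MVDResult:
    """Per-case result: field counts, their mean, and the cutoff group."""

    field_counts: tuple[FieldCount, ...]
    mean_count: float
    cutoff: float
    group: str


def count_field(
    mask: VesselMask,
    field: FieldSpec,
    grid: ChalkleyGrid,
    search: PlacementSearch = PlacementSearch(),
) -> FieldCount:
    """Maximum number of grid points landing on vessel pixels over placements.

    Each grid offset is rotated, shifted, scaled by the field radius and
    mapped to its nearest pixel; a point scores when that pixel is a vessel
    pixel.  The maximum over all rotation x translation placements is
    returned, with the first placement attaining it (rotation-major order).
    """
    h, w = mask.shape
    cx, cy = field.center_xy
    r = field.radius_px
    ry = math.floor(r)
    if not (ry <= cx <= w - 1 - ry and ry <= cy <= h - 1 - ry):
        raise DomainError(f"field at {field.center_xy} exits the {h}x{w} image")

    best_count = -1
    best_place = (0, 0)
    translations = search.translations()
    for ri, theta in enumerate(search.rotations()):
        c, s = math.cos(theta), math.sin(theta)
        rot = grid.points @ np.array([[c, -s], [s, c]]).T
        for ti, shift in enumerate(translations):
            px = np.rint(cx + r * (rot[:, 0] + shift[0])).astype(int)
            py = np.rint(cy + r * (rot[:, 1] + shift[1])).astype(int)
            ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
            hits = int(mask.mask[py[ok], px[ok]].sum())
            if hits > best_count:
                best_count = hits
                best_place = (ri, ti)
    return FieldCount(field=field, count=best_count, placement=best_place)


def mean_mvd(counts: list[FieldCount] | list[int]) -> float:
    """Arithmetic mean Chalkley count over 3-5 fields."""
    if not 3 <= len(counts) <= 5:
        raise DomainError(f"mean MVD requires 3-5 field counts, got {len(counts)}")
    values = [c.count if isinstance(c, FieldCount) else int(c) for c in counts]
    return float(np.mean(values))


def classify_mvd(mean_count: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Dichotomize a mean Chalkley count: 'high' iff mean >= cutoff.

    A mean of exactly 6 is high under the default convention (the boundary
    side is not derivable from the reference protocol; the cutoff is a
    parameter).
    """
    if not 0.0 <= mean_count <= GRID_SIZE:
        raise DomainError(f"mean_count must be in [0, {GRID_SIZE}], got {mean_count}")
    return "high" if mean_count >= cutoff else "low"


def score_fields(
    mask: VesselMask,
    fields: list[FieldSpec],
    grid: ChalkleyGrid,
    search: PlacementSearch = PlacementSearch(),
    cutoff: float = DEFAULT_CUTOFF,
) -> MVDResult:
    """Count every field, average, and dichotomize — one case end to end."""
    counts = [count_field(mask, f, grid, search) for f in fields]
    mean = mean_mvd(counts)
    return MVDResult(
        field_counts=tuple(counts),
        mean_count=mean,
        cutoff=cutoff,
        group=classify_mvd(mean, cutoff),
    )
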