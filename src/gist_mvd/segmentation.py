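"""Vessel segmentation of brightfield immunostained images.

An RGB image of CD31/DAB-stained tissue is converted into a binary vessel
mask in three steps: per-pixel optical density is decomposed onto the DAB
and hematoxylin stain vectors (Beer-Lambert color deconvolution), the DAB
channel is thresholded, and connected components below a minimum physical
area are discarded.  The Chalkley scoring core is agnostic to how the mask
was produced; a user-supplied mask can bypass this module entirely via
:meth:`VesselMask.from_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .errors import ConfigError

#: Ruifrok & Johnston optical-density unit vectors for the two stains.
DAB_OD_VECTOR = (0.268, 0.570, 0.776)
HEMATOXYLIN_OD_VECTOR = (0.650, 0.704, 0.286)


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB brightfield image with a physical pixel size.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of intensities in ``[0, 255]``.
    um_per_px
        Physical side length of one pixel in micrometers.
    """

    pixels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ConfigError(f"pixels must be (H, W, 3) with H, W >= 1, got {px.shape}")
        if not self.um_per_px > 0:
            raise ConfigError(f"um_per_px must be positive, got {self.um_per_px}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class StainMaps:
    """Per-stain optical-density rasters from color deconvolution."""

    dab_od: np.ndarray
    hema_od: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        if self.dab_od.shape != self.hema_od.shape:
            raise ConfigError("dab_od and hema_od must have identical shapes")
        if (self.dab_od < 0).any() or (self.hema_od < 0).any():
            raise ConfigError("optical densities must be non-negative")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and filtering parameters for vessel segmentation.

    ``dab_od_threshold`` is in optical-density units of the DAB channel;
    ``min_object_area_um2`` removes stain specks smaller than a plausible
    vessel profile; ``morphology_radius_px`` is the radius of the closing
    footprint that bridges small gaps before component filtering.
    ``fill_lumens_below_um2`` optionally fills enclosed holes (vessel
    lumina) smaller than the given area; by the usual Chalkley convention
    any stained endothelial structure counts, so it defaults to off.
    """

    dab_od_threshold: float = 0.25
    min_object_area_um2: float = 20.0
    morphology_radius_px: int = 1
    fill_lumens_below_um2: float | None = None

    def __post_init__(self) -> None:
        if not self.dab_od_threshold > 0:
            raise ConfigError("dab_od_threshold must be > 0")
        if not self.min_object_area_um2 > 0:
            raise ConfigError("min_object_area_um2 must be > 0")
        if self.morphology_radius_px < 0:
            raise ConfigError("morphology_radius_px must be >= 0")


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel raster with labeled connected components.

    ``components`` is a table with columns ``label``, ``area_um2``,
    ``centroid_x``, ``centroid_y`` (pixel coordinates, 0-based, origin at
    the top-left corner).
    """

    mask: np.ndarray
    labels: np.ndarray
    components: pd.DataFrame
    um_per_px: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, um_per_px: float, min_object_area_um2: float = 0.0
    ) -> "VesselMask":
        """Wrap a precomputed binary mask, labeling 8-connected components."""
        mask = np.asarray(mask).astype(bool)
        if not um_per_px > 0:
            raise ConfigError(f"um_per_px must be positive, got {um_per_px}")
        px_area_um2 = um_per_px**2
        labels = measure.label(mask, connectivity=2)
        if min_object_area_um2 > 0:
            keep = np.zeros(labels.max() + 1, dtype=bool)
            for rp in measure.regionprops(labels):
                keep[rp.label] = rp.area * px_area_um2 >= min_object_area_um2
            mask = keep[labels]
            labels = measure.label(mask, connectivity=2)
        rows = []
        for rp in measure.regionprops(labels):
            cy, cx = rp.centroid
            rows.append((rp.label, rp.area * px_area_um2, cx, cy))
        comp = pd.DataFrame(rows, columns=["label", "area_um2", "centroid_x", "centroid_y"])
        return cls(mask=mask, labels=labels, components=comp, um_per_px=um_per_px)


def separate_stains(
    image: RGBImage,
    stain_vectors: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        DAB_OD_VECTOR,
        HEMATOXYLIN_OD_VECTOR,
    ),
) -> StainMaps:
    """Decompose per-pixel optical density onto two stain vectors.

    Optical density per channel is ``OD_c = -log10((I_c + 1) / 256)``, so a
    pure-white pixel has zero density in every channel.  The two stain
    loadings are the least-squares solution of ``loadings @ S = OD`` for the
    2x3 stain matrix ``S``; negative loadings are clipped to zero.
    """
    dab_vec = np.asarray(stain_vectors[0], dtype=float)
    hema_vec = np.asarray(stain_vectors[1], dtype=float)
    dab_vec = dab_vec / np.linalg.norm(dab_vec)
    hema_vec = hema_vec / np.linalg.norm(hema_vec)
    if np.linalg.norm(np.cross(dab_vec, hema_vec)) < 1e-8:
        raise ConfigError("stain vectors are collinear; deconvolution is underdetermined")

    od = -np.log10((image.pixels.astype(float) + 1.0) / 256.0)  # (H, W, 3), >= 0
    stain_mat = np.stack([dab_vec, hema_vec])  # (2, 3)
    gram = stain_mat @ stain_mat.T  # (2, 2)
    proj = od @ stain_mat.T  # (H, W, 2)
    loadings = proj @ np.linalg.inv(gram).T
    loadings = np.clip(loadings, 0.0, None)
    return StainMaps(
        dab_od=loadings[..., 0], hema_od=loadings[..., 1], um_per_px=image.um_per_px
    )


def segment_vessels(stains: StainMaps, params: SegmentationParams) -> VesselMask:
    """Threshold the DAB channel and filter components by physical area.

    The raw mask ``dab_od >= threshold`` is morphologically closed with a
    disc footprint, then 8-connected components smaller than
    ``min_object_area_um2`` are removed and the component table rebuilt.
    """
    mask = stains.dab_od >= params.dab_od_threshold
    if params.morphology_radius_px > 0:
        mask = morphology.closing(
            mask, footprint=morphology.disk(params.morphology_radius_px)
        ).astype(bool)
    if params.fill_lumens_below_um2 is not None:
        max_hole_px = int(params.fill_lumens_below_um2 / stains.um_per_px**2)
        mask = morphology.remove_small_holes(mask, area_threshold=max_hole_px)
    return VesselMask.from_mask(
        mask, stains.um_per_px, min_object_area_um2=params.min_object_area_um2
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A & B| / (|A| + |B|)``; 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
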