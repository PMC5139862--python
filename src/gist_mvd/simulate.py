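"""Synthetic immunostained images and patient cohorts with known ground truth.

Every downstream stage (stain separation, hot-spot scanning, Chalkley
counting, survival comparison) is tested against fixtures produced here:
elliptical DAB-brown vessel profiles on a pale hematoxylin background, with
an optional spatial "hot spot" structure, and a cohort whose latent
microvessel-density (MVD) group drives an exponential survival model with
independent exponential censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .segmentation import RGBImage

#: Default chromogen / counterstain colors (8-bit RGB).
DAB_BROWN = (130, 80, 40)
HEMATOXYLIN_PALE = (225, 225, 240)

SITES = ("stomach", "small intestine", "colon/rectum", "omentum/mesenterium")
HISTOLOGIES = ("spindle", "epithelioid", "mixed")
RISK_CATEGORIES = ("very low", "low", "intermediate", "high")


def _default_site_probs() -> tuple[float, ...]:
    # Reported site shares (stomach 45.6, small intestine 38.0,
    # omentum/mesenterium 26.4, in %) overlap and sum above 100;
    # normalized here, so the defaults are approximate by construction.
    raw = np.array([45.6, 38.0, 0.0, 26.4])
    return tuple(raw / raw.sum())


@dataclass(frozen=True)
class EllipseShape:
    """One vessel profile: center (x, y) px, semi-axes px, rotation rad."""

    center_xy: tuple[float, float]
    axes_px: tuple[float, float]
    angle_rad: float


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of one synthetic immunostained image.

    ``hotspot_fraction`` of the ``n_vessels`` profiles are centered inside
    discs of radius ``hotspot_radius_um`` around ``hotspot_centers``; the
    rest are placed uniformly over the image.  Vessel semi-major axes are
    drawn uniformly from ``vessel_radius_um`` with eccentricity at most 3:1.
    """

    width_px: int = 256
    height_px: int = 256
    um_per_px: float = 4.0
    n_vessels: int = 40
    vessel_radius_um: tuple[float, float] = (6.0, 16.0)
    hotspot_centers: tuple[tuple[float, float], ...] = ()
    hotspot_fraction: float = 0.0
    hotspot_radius_um: float = 140.0
    dab_color: tuple[int, int, int] = DAB_BROWN
    background_color: tuple[int, int, int] = HEMATOXYLIN_PALE
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ConfigError("image dimensions must be positive")
        if not self.um_per_px > 0:
            raise ConfigError("um_per_px must be positive")
        if self.n_vessels < 0:
            raise ConfigError("n_vessels must be >= 0")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ConfigError("hotspot_fraction must be in [0, 1]")
        if self.hotspot_fraction > 0 and not self.hotspot_centers:
            raise ConfigError("hotspot_fraction > 0 requires hotspot_centers")
        lo, hi = self.vessel_radius_um
        if not (0 < lo <= hi):
            raise ConfigError("vessel_radius_um must be a positive (min, max) range")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Known vessel geometry for a synthetic image."""

    vessel_shapes: tuple[EllipseShape, ...]
    truth_mask: np.ndarray
    hotspot_centers: tuple[tuple[float, float], ...]


def _rasterize_ellipse(mask: np.ndarray, shape: EllipseShape) -> None:
    """Mark pixels whose centers fall inside the ellipse (no anti-aliasing)."""
    h, w = mask.shape
    cx, cy = shape.center_xy
    a, b = shape.axes_px
    r = max(a, b)
    x0, x1 = max(0, int(math.floor(cx - r))), min(w - 1, int(math.ceil(cx + r)))
    y0, y1 = max(0, int(math.floor(cy - r))), min(h - 1, int(math.ceil(cy + r)))
    if x0 > x1 or y0 > y1:
        return
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xs - cx
    dy = ys - cy
    c, s = math.cos(shape.angle_rad), math.sin(shape.angle_rad)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[y0 : y1 + 1, x0 : x1 + 1] |= inside


def generate_vessel_image(config: ImageSimConfig) -> tuple[RGBImage, GroundTruth]:
    """Draw a synthetic CD31/DAB-stained image and its exact truth mask.

    Exactly ``round(hotspot_fraction * n_vessels)`` vessel centers are
    placed inside the hot-spot discs (clipped to the image); the remainder
    are uniform over the image.  The truth mask marks the union of ellipse
    interiors; pixel noise is added to the rendered image only.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    truth = np.zeros((h, w), dtype=bool)
    shapes: list[EllipseShape] = []

    n_hot = int(round(config.hotspot_fraction * config.n_vessels))
    hot_r_px = config.hotspot_radius_um / config.um_per_px
    lo_px = config.vessel_radius_um[0] / config.um_per_px
    hi_px = config.vessel_radius_um[1] / config.um_per_px

    for i in range(config.n_vessels):
        if i < n_hot:
            hx, hy = config.hotspot_centers[rng.integers(len(config.hotspot_centers))]
            for _ in range(1000):
                ang = rng.uniform(0, 2 * math.pi)
                rad = hot_r_px * math.sqrt(rng.uniform())
                cx, cy = hx + rad * math.cos(ang), hy + rad * math.sin(ang)
                if 0 <= cx < w and 0 <= cy < h:
                    break
            else:  # pragma: no cover - hot spot entirely outside the image
                raise ConfigError("hotspot disc does not intersect the image")
        else:
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        a = rng.uniform(lo_px, hi_px)
        b = a / rng.uniform(1.0, 3.0)  # eccentricity capped at 3:1
        angle = rng.uniform(0, math.pi)
        shape = EllipseShape((cx, cy), (a, b), angle)
        shapes.append(shape)
        _rasterize_ellipse(truth, shape)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = config.background_color
    img[truth] = config.dab_color
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return (
        RGBImage(pixels=pixels, um_per_px=config.um_per_px),
        GroundTruth(
            vessel_shapes=tuple(shapes),
            truth_mask=truth,
            hotspot_centers=tuple(config.hotspot_centers),
        ),
    )


def assign_risk_category(size_cm: float, mitoses_per_50hpf: int) -> str:
    """NIH consensus aggressive-behavior risk category from size and mitoses.

    The lookup partitions the (size, mitotic count) plane with no gaps:
    mitotic bands are <=5, 6-10 and >10 per 50 HPF; size bands are <2,
    2-5, 5-10 and >10 cm.  Any tumor over 10 cm or over 10 mitoses is
    high risk regardless of the other variable.
    """
    if not size_cm > 0:
        raise DomainError(f"size_cm must be positive, got {size_cm}")
    if mitoses_per_50hpf < 0:
        raise DomainError(f"mitoses_per_50hpf must be >= 0, got {mitoses_per_50hpf}")
    m, s = mitoses_per_50hpf, size_cm
    if m > 10 or s > 10:
        return "high"
    if s > 5:
        return "high" if m > 5 else "intermediate"
    if m > 5:
        return "intermediate"
    return "very low" if s < 2 else "low"


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of a synthetic GIST cohort.

    Defaults emulate the reference study conditions this package models: 79
    cases, 12/79 in the high-MVD group, mean age 58.9 y (SD 13), tumor size
    0.5-25 cm, mean follow-up about 2.5 y.  Event times are exponential
    with hazard ``baseline_hazard`` (times ``hazard_ratio_high`` in the
    high-MVD group); censoring is independent exponential with mean
    ``censor_time_mean``, optionally truncated at ``max_followup_years``.
    With the defaults the expected observed death proportions are 4.5 %
    (low) and 25 % (high).
    """

    n_patients: int = 79
    p_high_mvd: float = 12 / 79
    baseline_hazard: float = 0.019
    hazard_ratio_high: float = 7.0
    censor_time_mean: float = 2.5
    max_followup_years: float | None = 17.0
    age_mean: float = 58.9
    age_sd: float = 13.0
    sex_p_male: float = 42 / 79
    site_probs: tuple[float, ...] = field(default_factory=_default_site_probs)
    size_range_cm: tuple[float, float] = (0.5, 25.0)
    mitoses_mean: float = 3.0
    histology_probs: tuple[float, float, float] = (0.722, 0.200, 0.078)
    p_metastasis: float = 9 / 79
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 <= self.p_high_mvd <= 1.0:
            raise ConfigError("p_high_mvd must be in [0, 1]")
        if not (self.baseline_hazard > 0 and self.hazard_ratio_high > 0):
            raise ConfigError("hazards must be positive")
        if not self.censor_time_mean > 0:
            raise ConfigError("censor_time_mean must be positive")
        if abs(sum(self.site_probs) - 1.0) > 1e-9:
            raise ConfigError("site_probs must sum to 1 within 1e-9")
        if len(self.site_probs) != len(SITES):
            raise ConfigError(f"site_probs must have {len(SITES)} entries")
        lo, hi = self.size_range_cm
        if not (0 < lo <= hi):
            raise ConfigError("size_range_cm must be a positive (min, max) range")


COHORT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "site",
    "size_cm",
    "mitoses_per_50hpf",
    "histology",
    "risk_category",
    "followup_years",
    "death_event",
    "metastasis",
    "latent_mvd_group",
]


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Draw a cohort table with the configured marginals and survival model.

    Tumor size is log-uniform on ``size_range_cm`` and mitotic counts are
    Poisson, so all four NIH risk categories occur with non-trivial
    probability.  ``latent_mvd_group`` is the ground-truth group the image
    pipeline is expected to recover.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    high = rng.random(n) < config.p_high_mvd
    hazard = config.baseline_hazard * np.where(high, config.hazard_ratio_high, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(config.censor_time_mean, size=n)
    if config.max_followup_years is not None:
        censor_time = np.minimum(censor_time, config.max_followup_years)
    followup = np.minimum(event_time, censor_time)
    death = event_time <= censor_time  # ties resolved as deaths

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = np.where(rng.random(n) < config.sex_p_male, "M", "F")
    site = rng.choice(SITES, size=n, p=np.asarray(config.site_probs))
    lo, hi = config.size_range_cm
    size_cm = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    mitoses = rng.poisson(config.mitoses_mean, size=n)
    histology = rng.choice(
        HISTOLOGIES, size=n, p=np.asarray(config.histology_probs) / sum(config.histology_probs)
    )
    metastasis = rng.random(n) < config.p_metastasis
    risk = [assign_risk_category(s, int(m)) for s, m in zip(size_cm, mitoses)]

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "age_years": age,
            "sex": sex,
            "site": site,
            "size_cm": size_cm,
            "mitoses_per_50hpf": mitoses.astype(int),
            "histology": histology,
            "risk_category": risk,
            "followup_years": followup,
            "death_event": death,
            "metastasis": metastasis,
            "latent_mvd_group": np.where(high, "high", "low"),
        },
        columns=COHORT_COLUMNS,
    )


def reference_partition_cohort() -> pd.DataFrame:
    """Cohort table reproducing the reference study's printed partition.

    79 cases: 67 in the low-MVD group with 3 deaths, 12 in the high-MVD
    group with 3 deaths, and 9 metastatic cases overall.  Follow-up times
    are nominal (they carry the group/outcome structure, not the study's
    unpublished patient-level times).
    """
    rows = []
    meta_left = 9
    for i in range(79):
        group = "high" if i < 12 else "low"
        death = (i < 3) or (12 <= i < 15)
        metastasis = meta_left > 0
        if metastasis:
            meta_left -= 1
        rows.append(
            {
                "patient_id": f"R{i:03d}",
                "age_years": 58.9,
                "sex": "M" if i < 42 else "F",
                "site": "stomach",
                "size_cm": 4.8,
                "mitoses_per_50hpf": 3,
                "histology": "spindle",
                "risk_category": assign_risk_category(4.8, 3),
                "followup_years": 1.0 + 0.01 * i,
                "death_event": death,
                "metastasis": metastasis,
                "latent_mvd_group": group,
            }
        )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df["mvd_group"] = df["latent_mvd_group"]
    return df
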