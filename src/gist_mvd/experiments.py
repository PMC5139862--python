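"""Seeded simulation experiments that characterize the pipeline.

Each function runs a self-contained study on synthetic data: segmentation
accuracy against ground truth, the dose-response of the Chalkley count to
configured vessel density, and the operating characteristics (type-I error,
power) of the log-rank stage at the study's group sizes.
"""

from __future__ import annotations

import numpy as np

from .chalkley import make_grid, score_fields
from .hotspots import FieldGeometry, select_hotspots
from .segmentation import SegmentationParams, dice_coefficient, segment_vessels, separate_stains
from .simulate import ImageSimConfig, generate_vessel_image
from .survival import logrank_test

#: Study-sized arms: 67 low-MVD vs 12 high-MVD cases.
STUDY_GROUP_SIZES = (67, 12)
#: Event/censoring scales matched to the modeled cohort (see CohortSimConfig).
BASELINE_HAZARD = 0.019
CENSOR_TIME_MEAN = 2.5


def dice_experiment(n_images: int = 20, seed: int = 0) -> list[float]:
    """Dice of default segmentation vs generator truth on seeded images."""
    out = []
    seeds = np.random.SeedSequence(seed).generate_state(n_images)
    for s in seeds:
        image, truth = generate_vessel_image(ImageSimConfig(seed=int(s)))
        vm = segment_vessels(separate_stains(image), SegmentationParams())
        out.append(dice_coefficient(vm.mask, truth.truth_mask))
    return out


DENSITY_LEVELS = (20, 50, 90, 140, 200)  # configured n_vessels per level


def density_level_experiment(
    levels: tuple[int, ...] = DENSITY_LEVELS,
    n_replicates: int = 20,
    seed: int = 0,
) -> dict[int, float]:
    """Mean Chalkley count per configured vessel-density level.

    For each level, ``n_replicates`` seeded images are rendered (vessels
    uniform over the image), segmented, hot-spotted (3 fields) and scored;
    the per-level mean of the per-image mean counts is returned.  A usable
    scoring core must be monotone in the underlying vascularity, so these
    level means should increase strictly with the level.
    """
    grid = make_grid()
    geometry = FieldGeometry(field_diameter_um=280.0, scan_stride_px=4)
    seeds = np.random.SeedSequence(seed).generate_state(len(levels) * n_replicates)
    means: dict[int, float] = {}
    i = 0
    for level in levels:
        vals = []
        for _ in range(n_replicates):
            cfg = ImageSimConfig(n_vessels=level, seed=int(seeds[i]))
            i += 1
            image, _ = generate_vessel_image(cfg)
            vm = segment_vessels(separate_stains(image), SegmentationParams())
            fields = select_hotspots(vm, 3, geometry)
            vals.append(score_fields(vm, fields, grid).mean_count)
        means[level] = float(np.mean(vals))
    return means


def _simulate_two_arm_pvalues(
    n_reps: int,
    hazard_ratio: float,
    seed: int,
    group_sizes: tuple[int, int] = STUDY_GROUP_SIZES,
) -> np.ndarray:
    """Log-rank p-values from repeated two-arm exponential trials."""
    n_lo, n_hi = group_sizes
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        t_lo = rng.exponential(1.0 / BASELINE_HAZARD, n_lo)
        t_hi = rng.exponential(1.0 / (BASELINE_HAZARD * hazard_ratio), n_hi)
        c_lo = rng.exponential(CENSOR_TIME_MEAN, n_lo)
        c_hi = rng.exponential(CENSOR_TIME_MEAN, n_hi)
        res = logrank_test(
            np.minimum(t_lo, c_lo), t_lo <= c_lo,
            np.minimum(t_hi, c_hi), t_hi <= c_hi,
        )
        pvals[r] = res.p_value
    return pvals


def logrank_null_rejection_rate(
    n_reps: int = 2000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Empirical type-I error: both arms drawn from the same exponential."""
    return float((_simulate_two_arm_pvalues(n_reps, 1.0, seed) < alpha).mean())


def logrank_power(
    n_reps: int = 500, hazard_ratio: float = 8.0, seed: int = 0, alpha: float = 0.05
) -> float:
    """Empirical power against a high-vascularity hazard-ratio alternative."""
    return float((_simulate_two_arm_pvalues(n_reps, hazard_ratio, seed) < alpha).mean())
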