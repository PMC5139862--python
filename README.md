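# gist-mvd

Chalkley microvessel-density (MVD) analysis for gastrointestinal stromal
tumors (GISTs): from CD31-immunostained brightfield images to per-case
Chalkley counts, a six-vessel cutoff dichotomization, and a Kaplan–Meier /
log-rank survival comparison between the low- and high-MVD groups.

The package is aimed at pathology image-analysis work where tumor
vascularity is scored on immunostained sections and related to outcome. No
slide archive is required: a synthetic-data module renders DAB-stained
vessel images with exact ground truth and draws cohorts with a known latent
MVD structure, so the whole pipeline is testable end to end.

## Method

1. **Stain separation.** Per-pixel optical density
   `OD_c = −log10((I_c + 1)/256)` is decomposed by least squares onto the
   DAB and hematoxylin stain vectors (Beer–Lambert color deconvolution);
   negative loadings are clipped at zero.
2. **Vessel segmentation.** The DAB channel is thresholded, morphologically
   closed, and 8-connected components smaller than a minimum physical area
   (µm²) are removed.
3. **Hot-spot selection.** Every candidate center of a circular 200×-style
   microscopic field is scanned; the 3–5 densest, pairwise non-overlapping
   fields (center distance ≥ field diameter) are kept, ranked by
   vessel-pixel fraction.
4. **Chalkley count.** A 25-point graticule is overlaid on each field; the
   count is the number of points coinciding with vessel pixels, maximized
   over a small set of rotations and translations:
   `C = max_{placement} #{p : mask(round(center + r·(R_θ p + t))) = 1}`,
   with `0 ≤ C ≤ 25`. The case score is the mean over fields, and the case
   is `high` iff `mean ≥ 6`.
5. **Survival comparison.** Kaplan–Meier product-limit curves per group,
   `S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)`, and the two-sample log-rank test
   with hypergeometric expected deaths,
   `χ² = (Σ_i (d_{1i} − e_{1i}))² / Σ_i v_i ~ χ²(1)`,
   plus a seeded permutation p-value as a robustness option. Group
   percentages are always re-derived from integer counts (half-up, one
   decimal).

## Worked example

The `analysis/` scripts run the whole study on synthetic data:

```sh
python analysis/01_simulate_study.py --seed 0   # cohort + images
python analysis/02_score_images.py  --seed 0    # segmentation + Chalkley
python analysis/03_survival_analysis.py         # KM + log-rank
```

which prints (seed 0):

```
simulated 79 cases (13 latent high-MVD), mean follow-up 2.49 y, 5 deaths
scored 79 cases; latent-group agreement 100.0%
  latent high-MVD cases: mean Chalkley count 7.90
  latent low-MVD cases: mean Chalkley count 2.59
MVD groups: 66 low (83.5%), 13 high (16.5%).
Deaths: 3/13 (23.1%) high vs 2/66 (3.0%) low.
Log-rank: chi-square = 6.822 (1 df), P = 0.009003 (permutation P = 0.01049).
```

Low-vascularity cases score a mean Chalkley count well under the cutoff of
six and high-vascularity cases well above it, the image pipeline recovers
every latent group label, and the survival difference between the groups is
detected by the log-rank test. Tables land under `results/`.

The same pipeline is available as a CLI (`gist-mvd run-all`,
`simulate-images`, `simulate-cohort`, `segment`, `hotspots`, `score`,
`analyze`) and as a library (`gist_mvd.run_pipeline`).

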