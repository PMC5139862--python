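# Methods

## Scope and model

The package quantifies tumor vascularity on CD31/DAB-immunostained
brightfield images by the modified Chalkley method and relates the
resulting microvessel-density (MVD) groups to survival. The unit of
analysis is one case (patient) with 1–5 images; the case score is the mean
Chalkley count over 3–5 vascular hot spots, dichotomized at six.

The Chalkley count is dimensionless (grid-point hits, bounded by 25) and is
never converted to vessels/mm²; the cutoff therefore lives on the same
0–25 scale.

## Stain separation and segmentation

Optical density is `OD_c = −log10((I_c + 1)/256)` per channel, so
saturated white maps to zero in every channel. The 2×3 stain matrix uses
the Ruifrok–Johnston unit vectors for DAB (0.268, 0.570, 0.776) and
hematoxylin (0.650, 0.704, 0.286); both are overridable. Loadings are the
least-squares solution of the 2×2 normal equations per pixel, clipped at
zero.

Segmentation thresholds the DAB loading (default 0.25 OD — roughly a
quarter of the loading of a fully stained vessel pixel and an order of
magnitude above the background's), closes with a 1 px disc, and removes
8-connected components under 20 µm² (below any plausible capillary
profile; the parameter deliberately exposes the "does a single stained
endothelial cell count?" choice rather than fixing it). An optional
lumen-fill step (fill holes below a given area) defaults off: by the usual
Chalkley convention any stained endothelial structure counts. How vessels
were delineated in the original protocol is not recoverable; automatic
color-deconvolution delineation is this package's choice, and the scoring
core accepts any user-supplied binary mask instead
(`VesselMask.from_mask`).

## Hot spots

Fields are discs; the default diameter of 940 µm corresponds to a 0.69 mm²
field of view at 200× with a 26.5 mm eyepiece and is configurable because
microscopes differ. Density at a candidate center is the vessel-pixel
fraction in the disc (a `component_fraction` mode — the share of vessel
components whose centroid falls in the disc — exists because
"microvascular density" is ambiguous between area and count). Disc sums
are computed exactly in integer arithmetic via per-row cumulative sums, so
the scan equals brute-force pixel counting bit for bit.

Selection is greedy top-k with ties broken by row then column, under a
pairwise center distance of at least one field diameter. Non-overlap is a
deliberate strengthening: averaging near-duplicate fields is degenerate.
Greedy (rather than jointly optimal) selection matches how a pathologist
scans a slide. Scanning happens at full resolution only; no low-power
pre-pass.

## Chalkley grid and placement

The historical graticule's exact point pattern is not standardized in the
sources this package models, so the 25 points are drawn once, seeded,
uniformly in the unit disc with a rejection rule enforcing a minimum
pairwise spacing of 0.15 radius units; the default layout (seed 17) is
frozen and swappable. Counting maximizes hits over 8 rotations × 9
translations (center plus a ring at 10 % of the field radius), matching
classic Chalkley practice of rotating the graticule to maximize
coincidences; `PlacementSearch(1, 1)` gives the fixed-placement mode for
sensitivity analysis. Coincidence is nearest-pixel lookup (no sub-pixel
interpolation): simple and exactly testable against enumeration.

A mean of exactly six classifies as `high`. The boundary side is a
convention (the protocol's own description is ambiguous) and is exposed as
a parameter.

## Survival analysis

Kaplan–Meier and the two-sample log-rank test are implemented from first
principles; lifelines serves in the test suite as an independent oracle
(agreement to ≥ 9 significant digits on shared inputs). Conventions: at tied times deaths precede censoring; with zero
total deaths the log-rank test returns statistic 0, p = 1 (uninformative,
not an error); percentages are half-up-rounded to one decimal from integer
counts at print time only. Cases without an MVD score are excluded from
the comparison and listed as rejects — no imputation.

A permutation p-value (seeded label reshuffles) is available because the
asymptotic χ²(1) reference is imperfect at a 12-case arm: simulation at
the study's 67-vs-12 sizes puts the true size of the asymptotic test near
0.056–0.061 rather than 0.050. The permutation variant is exact by
construction and is the recommended robustness check at these sample
sizes.

## Synthetic data

**Images.** Vessels are ellipses (eccentricity ≤ 3:1 — no morphometry is
being modeled, ellipses merely exercise the counting geometry) with
semi-major axes 6–16 µm by default, rendered in DAB brown (130, 80, 40) on
a pale hematoxylin background (225, 225, 240) — colors chosen to make
stain separation non-trivial but solvable — with optional Gaussian pixel
noise (default SD 5). A configured fraction of vessel centers falls inside
hot-spot discs (radius 140 µm by default). The truth mask is the exact
union of ellipse interiors at pixel centers; rasterization error against
the analytic area πab is bounded by the perimeter. The generator does not
attempt nuclei, stroma, texture, or whole-slide formats, so passing tests
demonstrate the geometry and arithmetic of the method, not robustness to
real histology variation (staining artifacts, necrosis, folds).

**Cohorts.** Defaults pin the modeled study conditions: n = 79, high-MVD
probability 12/79, age ~ N(58.9, 13²) years, 42/79 male, tumor size
log-uniform on 0.5–25 cm, mitoses Poisson(3)/50 HPF, site probabilities
proportional to (45.6, 38.0, 0, 26.4) — the printed shares overlap and sum
above 100 %, so they are normalized and approximate; histology
(spindle/epithelioid/mixed) = (72.2, 20.0, 7.8) %. Event times are
exponential with baseline hazard 0.019/year, multiplied by a hazard ratio
of 7.0 in the high-MVD group; censoring is independent exponential with
mean 2.5 years (truncated at 17 years of study span). Under
`P(death) = λ/(λ+μ)` these give expected observed death proportions of
4.5 % (low) and 25 % (high) and a mean follow-up near 2.5 years — the
modeled study's figures. Metastasis is an independent Bernoulli(9/79)
marker, not linked to the survival model.

The NIH risk lookup (size × mitotic count) is implemented as a gapless
partition: mitotic bands ≤ 5, 6–10, > 10 per 50 HPF and size bands < 2,
2–5, 5–10 (exclusive-inclusive), > 10 cm, with "> 10 cm or > 10 mitoses ⇒
high" taking precedence. The printed consensus table leaves the exact
boundaries at 5 mitoses and 5 cm ambiguous; the convention above closes
them.

**Pipeline image conditions.** The default end-to-end study renders one
256×256 image per case at 4 µm/px with a 280 µm scan field (stride 4 px) —
a deliberately small problem size that keeps a full 79-case run around two
seconds while leaving every stage non-trivial. Latent low-MVD cases get
18–30 vessels (60 % in the hot spot), high-MVD cases 160–220 vessels
(85 %); these were calibrated once so the two conditions score mean
Chalkley counts near 2.6 and 8 — clearly on either side of the cutoff,
like the low- and high-vascularity tumors the method is meant to separate
— and then frozen.

## Determinism

One master seed drives everything: cohorts are drawn from a seeded
generator; per-case seeds derive from the master via `SeedSequence`, so
any single case can be re-rendered in isolation; the grid layout seed is
independent of the data seeds. Identical configuration and seed give
byte-identical study summaries.

## Simulation experiment sizes

The packaged experiments (`gist_mvd.experiments`) use 20 images for the
segmentation-accuracy study, 5 density levels × 20 replicates for the
dose-response study, 2,000 replicates for the log-rank type-I-error study
and 500 for the power study at the 67-vs-12 arm sizes — sizes at which the
Monte-Carlo standard error is small relative to the effects examined while
a full run of every experiment stays under ten seconds.

## Known limitations

- Stain separation assumes the two-stain Beer–Lambert model; chromogen
  saturation and mixed pigments are not modeled.
- Hot-spot scanning is single-resolution; the classic low-power pre-scan
  is not emulated.
- The synthetic cohort's covariates (site, histology, risk category,
  metastasis) are marginals only — they do not influence survival, so the
  package cannot (and does not claim to) reproduce covariate–outcome
  associations.
- The asymptotic log-rank p-value is slightly anti-conservative at a
  12-case arm (see above); use the permutation option when the small arm
  matters.
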