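# Methods

This note documents the models the package implements, the choices made
where the procedure was genuinely open, what the synthetic-data generator
does and does not emulate, and the problem sizes used by the test suite
and the acceptance script.

## Mean linear intercept

The morphometry chain operates on RGB fields with a pixels-per-micron
calibration (default 2.764 px/μm, the native field being 1600×1200 px).

**Segmentation.** Pixels are clustered on their raw RGB vectors into two
classes by K-means. Initialisation is deterministic: the two centroids
start at the darkest and brightest pixel colours by Rec. 601 luminance,
and Lloyd iterations run to label convergence. The cluster with the
brighter centroid is airspace. A single-colour image is degenerate and is
resolved against a mid-grey reference (luminance 127.5): brighter means
all-airspace. Feature space and initialisation are implementation
choices; the darkest/brightest rule makes the output reproducible without
an RNG, and on two-tone phantoms it recovers the white regions exactly.

**Component filter.** Airspace components (8-connectivity) with area
strictly below `min_area_px` (default 500) are reassigned to tissue, to
avoid counting vessels and stray white pixels as airspace. "Below" is
strict: a 500-px component is kept. The filter is applied to the binary
mask after clustering, is idempotent, and never increases airspace area.

**Line grid and counting.** Horizontal lines are placed at rows 0, s, 2s,
… (s = 69 px ≈ 25 μm by default), each spanning the full width; for a
1200-row image this yields 18 lines and 28,800 px (10,420 μm) of test
line — row-0 anchoring is the rule that reproduces that total. Scanning
left to right, a transition is an airspace pixel whose right neighbour is
tissue; borders are not transitions. Counting is one-directional
(airspace→tissue) by default, which makes L_M = (N·l/ΣI)/ppm a *period*
measure — mean air chord plus one septal crossing — rather than a pure
air-chord mean; stereology-conventional both-direction counting is
available via `count_direction="both"`. On a vertical stripe phantom with
air width a and tissue width t the measured L_M is exactly (a+t)/ppm
(one air→tissue crossing per period); the period-200-px phantom at
2.764 px/μm gives 200/2.764 = 72.36 μm.

**Aggregation.** Per-mouse L_M is the unweighted mean over that mouse's
images; group summaries are mean ± SEM (sample SD/√n) over mouse-level
values. Because group SEMs are sometimes reported over images rather than
mice, an image-level aggregation is also written
(`mli_per_group_imagelevel.csv`); the mouse-level table is primary. A
field with ΣI = 0 has no defined intercept and raises an explicit error;
in the pipeline such images are skipped with a warning and a mouse with
no valid images drops out of the aggregation.

## Respiratory mechanics

The perturbation names in this field map onto three standard model
forms, which is what the fitters implement:

* **Single-compartment equation of motion** P = R·V̇ + V/C + P₀, fitted
  by closed-form OLS over all samples of a fixed-frequency oscillation
  record. A rank-deficient design (e.g. zero flow) raises a singular-fit
  error rather than returning arbitrary coefficients.
* **Constant-phase impedance** Z(f) = Rn + j·2πf·Iaw + (G − jH)/(2πf)^α,
  with α tied to (2/π)·arctan(H/G). The complex residual is minimised by
  bounded (Rn ≥ 0, G, H > 0) trust-region least squares from three fixed
  starting points spanning mouse-plausible scales; the best optimum is
  returned, so the fit is deterministic and its residual never exceeds
  that of any start. Noise-free spectra are inverted to better than 1e−6
  relative error across the tested parameter range.
* **Salazar–Knowles PV limb** V = A − B·e^(−K·P) on the deflation limb.
  Cst = B·K·e^(−K·P*) is evaluated at P* = 5 cmH2O and TLC at 30 cmH2O —
  both configurable, since reporting pressures vary between studies.
  Hysteresis is the absolute shoelace area of the closed loop (orientation
  conventions differ, so the sign is dropped). A limb better described by
  a straight line (the K→0 limit) falls back to a linear fit whose slope
  is Cst; the exponential fit is preferred only when its residual is
  strictly smaller.

## Expression

rel = E^−(Ct_gene − Ct_RPL13a) with amplification efficiency E = 2
(perfect doubling) by default and an optional per-gene efficiency. The
MMP-9:TIMP-1 ratio is computed per animal; group summaries give the
arithmetic mean ± SEM (the conventional display) alongside a log2-scale
summary, because ratios are log-normal and the arithmetic mean is
upward-biased for skewed data. Animals missing the housekeeping Ct, or
with zero/missing TIMP-1, are excluded with a logged warning.

## Statistics

Diet (CD/VDD) and smoke (NS/CSE) are crossed between-subjects factors.
The ANOVA uses sum-to-zero contrasts with Type III sums of squares, which
coincides with the textbook partition SS_total = SS_diet + SS_smoke +
SS_interaction + SS_error when cells are balanced; group sizes in the
mechanics arm of such studies are typically unbalanced (14–17), which is
why Type III is the default. Conventions: all-equal data report F = 0,
p = 1; a zero residual with a nonzero effect reports p = 0. An empty or
singleton cell raises an error naming the cell.

Planned comparisons are Welch (unequal-variance) two-sample t tests —
chosen over pooled t because group variances are not assumed equal — with
Bonferroni adjustment p_adj = min(1, m·p) and family size m defaulting to
the number of pairs. The default pair set contrasts each treated group
with the control group plus the combined-insult group with each
single-insult group (five pairs).

Pathology scores on the four-tier 0/+/++/+++ scale are binarised
(presence = score > 0) before the tie-corrected Kruskal–Wallis test,
with the raw ordinal scale available as an option. The chi-square
reference for H is asymptotic: at the study's own group size (11/group)
its true level is mildly conservative (≈0.042 at nominal 0.05), never
anticonservative; the calibration experiment in `validation` therefore
runs at 50/group, where the level is ≈0.05.

## Synthetic-data generator

**Parenchyma phantom.** Cell centres are a Poisson point process with
intensity λ = 4/(π·d²) per μm², so the mean Voronoi cell's
equivalent-circle diameter is the target d. A pixel is tissue when its
perpendicular distance to the bisector of its two nearest centres —
computed exactly as (d₂² − d₁²)/(2·|s₂ − s₁|) — is at most half the
septal thickness (default 3.5 μm), airspace otherwise. This Voronoi
septum model produces contiguous airspaces separated by thin septa, the
standard parenchyma phantom geometry. The recorded ground truth (the
pre-confounder airspace mask and its exhaustive row-wise chord scan,
border chords included, since the line scan also runs border to border)
is computed, never assumed.

Confounders are drawn into the rendered image only: macrophage blobs are
disks placed at cell centres wholly inside airspace, coloured a dusty
brown (RGB 150,105,95) that is clearly darker than the tissue pink
(214,143,168) yet close enough to it that two-class clustering assigns
blobs to the tissue class — the mechanism by which intra-airspace
macrophages depress measured L_M without changing true airspace size.
Speckles are white disks fully inside tissue with area < 500 px,
exercising the component filter. Additive Gaussian pixel noise (default
SD 6 intensity units) is clipped to [0,255]. What the phantom does *not*
emulate: staining variation, out-of-focus blur, alveolar ducts and
vessels with real lumina, anisotropic tissue — so passing tests show the
measurement chain is correct on its stated geometry, not that
segmentation is robust to arbitrary real-slide artefacts.

**Mechanics, expression, pathology.** PV loops come from the
Salazar–Knowles relation with a half-sine hysteresis lobe that vanishes
at both pressure endpoints (so the loop closes); impedance spectra from
the constant-phase model with complex Gaussian noise; Ct tables as
Ct = baseline − log2fc(gene, group) + noise with the housekeeping gene
pinned at fold-change 0; pathology scores as Bernoulli presence at
per-group prevalences with present findings mostly focal. Default group
effects program the study's qualitative structure: larger airspaces only
in the combined-insult group, many intra-airspace macrophages in the
smoke groups (so measured L_M in CD-CSE falls *below* control while true
airspace size does not — the macrophage confound), higher compliance/TLC
and lower tissue elastance in both smoke groups, and a proteolytic
expression shift (MMP9 up, TIMP1/A1AT down) in the combined-insult group.

**Seeding.** Every cohort entity draws from its own stream derived from
the master seed by a counter scheme
(`SeedSequence(master_seed, spawn_key=(…indices…))`), so any animal or
image can be regenerated in isolation and bundles are byte-identical
across runs.

## Problem sizes used by tests and the acceptance script

Full-frame geometry constants (grid length, calibration, the stripe
phantom) are computed at the native 1600×1200 px. Cohort-scale
simulations run on reduced fields so repeated end-to-end experiments are
cheap: the 440-image bookkeeping run uses 400×300 px fields with a 23-px
grid and otherwise default parameters, and the effect-detection
experiment scales the whole geometry together — 400×300 px fields with
half-scale cells (16.5 vs 18.15 μm, the same ~10% contrast) and septa
(1.75 μm) — preserving the full-frame field-to-cell ratio (~12 airspaces
across a field). Calibration (2.764 px/μm) and the 500-px filter are
unchanged throughout. Monte-Carlo experiment sizes: 2000 null replicates
for type-I calibration, 20 repetitions of the two-cohort detection
experiment (11 mice × 10 images per group), 10-point parameter sweeps
for the mechanics round trips.

## Known limitations

* The one-directional transition count makes L_M a period-like measure;
  comparisons with air-chord-based literature values need the
  `count_direction="both"` setting or the recorded ground-truth chords.
* K-means with two classes assumes bimodal colour structure; slides with
  strong gradients or three-way colour mixtures (heavy haemorrhage,
  mounting artefacts) violate the phantom's assumptions.
* The constant-phase fit ties α to G and H; independent-α variants are
  not implemented.
* The expression module assumes one consolidated Ct per animal × gene
  (technical replicates averaged upstream) and 100% amplification
  efficiency unless configured otherwise.
* Repeated images within a mouse are aggregated, not modelled (no
  mixed-effects layer), matching the study design the package targets.
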