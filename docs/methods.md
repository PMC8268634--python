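# Methods

## Scope and data model

The package analyses multi-channel cytospin slides of blood-enriched cell
suspensions and the patient cohorts built from them. Five channels are fixed
throughout, in this order: `DAPI`, `AF488_tumor` (pan-keratin or
PMEL17/Melan-A depending on entity), `AF647_CD45`, `CD74`, `CD44`. All
intensities live on an 8-bit-like mean-grey-value (mgv) scale in [0, 255],
so the expression category anchors (negative ≤ 10, strong ≥ 21) are directly
meaningful. Per-cell expression is always the arithmetic mean grey value of
a channel over the cell mask.

## Synthetic cytospin slides

`generate_cytospin(params, seed)` plants cells as disks on a raster
(default 0.5 µm/pixel; slides are imaged at low magnification, so the pixel
size is a free, configurable parameter):

- **Classes and sizes.** Leukocytes (clipped normal, 10 ± 1 µm), classical
  CTCs (13 ± 2.5 µm, clipped to 8.5–19.5 µm), large cells (30 ± 3 µm,
  > 25.5 µm), multinucleated cells (24 ± 4 µm, 2–4 nuclei), and touching
  chains of 2–6 cluster members with classical-CTC sizes.
- **Nuclei.** One central nucleus at 0.55 R for mononucleated cells; for
  multinucleated cells, n nuclei of radius 0.32 R placed at 0.42 R from the
  centre, evenly spaced. The resulting nucleus spacing (< 0.9 R) is well
  below the nucleus spacing of touching cluster members (≈ the sum of their
  radii), which is what makes the two geometries separable downstream.
- **Intensities.** Clipped lognormals per class: leukocytes are CD45-bright
  (median 160 mgv) and tumor-marker-dim (median 2, capped at 8); tumor cells
  the converse (AF488 median 120, floor 30; CD45 capped at 8); DAPI median
  150 with floor 100 so that even a binucleated cell's whole-body DAPI mean
  stays above the gate. CD74/CD44 on tumor cells come from the correlated
  bivariate lognormal described below; leukocytes draw both independently
  (leukocytes also express both receptors).
- **Placement.** Rejection sampling, largest cell first, with a clear
  separation between non-cluster entities of one cell diameter of the larger
  partner. Bounded retries; an infeasible density raises `PlacementError`
  rather than silently truncating. Cluster members are painted in order and
  later members claim only unclaimed pixels, so planted masks stay disjoint
  and the planted mean is exact on every mask.
- **Noise.** I.i.d. Gaussian noise (default sd 2 mgv) added everywhere and
  left unclipped, like background-subtracted measurements; clipping at zero
  would bias the means of near-zero channels upward and break the
  planted-mean fidelity the ground truth guarantees.
- The default slide carries 1,000 leukocytes on a 3000² raster — the
  leukocyte carryover per cytospin after enrichment is not standardised and
  is a free parameter. Tests and examples use smaller slides (typically
  1200², 40 leukocytes, 13 tumor cells) so a full
  simulate → quantify → classify round trip takes a few seconds.

## Correlated marker expression

Cohort and slide generators draw per-cell (CD74, CD44) pairs from a
bivariate lognormal (medians 45/40 mgv, log-sd 0.5 each; positivity and
right skew of fluorescence). The requested Pearson correlation ρ (breast
default 0.9686) is interpreted on the *observed* (lognormal) scale: the
normal-scale correlation is obtained by inverting

    r_obs = (exp(ρ* σ₁σ₂) − 1) / sqrt((exp(σ₁²) − 1)(exp(σ₂²) − 1)),

so the population Pearson correlation of the generated values equals ρ
exactly rather than being attenuated by the exponentiation. Unattainable
combinations (|ρ*| > 1) raise.

## Quantification

- **Nuclei** — Gaussian smoothing (0.5 µm), Otsu threshold, minimum-area
  filter, distance-transform watershed for declumping. A contrast guard
  (Otsu classes closer than 10 mgv) rejects blank/noise-only images, giving
  zero spurious detections on empty slides.
- **Cell bodies** — the cytoplasmic composite is the pixelwise maximum over
  the four non-DAPI channels (every stained cell is bright in at least one).
  The foreground is the *raw* composite above a robust background threshold
  (median + 6 MAD-sigmas); thresholding a smoothed image instead would bleed
  a halo of background pixels into each mask and dilute measured means by up
  to ~20% for large cells, and a class-variance (Otsu) split can land inside
  the wide foreground brightness range and truncate dim cells. Holes are
  filled; a watershed seeded by the nuclei (smoothed composite as landscape)
  partitions the foreground.
- **Multinucleation vs clusters** — watershed regions grown from different
  nuclei are merged into one cell when their nucleus centroids are closer
  than 0.8 × the sum of the regions' equivalent radii. For planted
  multinucleated geometry this ratio is ≤ ~0.65; for touching cluster
  members it is ≈ 0.98, so the rule has margin on both sides. Touching cells
  that remain distinct are recorded in each other's `neighbor_ids`
  (8-connectivity).
- **Measurements** — equivalent diameter of the equal-area circle, converted
  to µm; channel means are exact arithmetic means over the mask. Coordinates
  are 0-based (x = column, y = row), origin top-left. Border-touching cells
  are flagged and excluded from enumeration because their diameters are
  truncated.

## Gating, morphotypes, categories

`GateConfig` defaults: tumor marker ≥ 21, CD45 ≤ 10, DAPI ≥ 21 — the
expression-category anchors reused as gating levels, all configurable.
Morphotype precedence for gated cells: cluster membership (connected groups
of ≥ 2 touching tumor cells) > multinucleated (≥ 2 nuclei) > large
(> 25 µm) > classical. The (20, 25] µm band belongs to classical, since
"large" is defined only by exceeding 25 µm. Gated cells under 8 µm are
labelled `sub_size` and excluded from counts, keeping the morphotype column
a partition of all cells. Expression categories partition the line as
negative (≤ 10), weak (10, 21), strong (≥ 21); the published wording of the
weak band ("11 ≤ mgv > 20") is internally inconsistent and is resolved to
the open interval between the two printed anchors.

## H-score

H = Σ_{level ∈ {1,2,3}} level × %area, range 0–300, with categories
negative (< 10), weak ([10, 100)), strong (≥ 100). The band between the
published "< 10 negative" and "11 ≤ weak" is assigned to weak so the
categories partition the range. Validation rejects negative percentages and
totals above 100%.

## Unconditional exact test

- **Ordering statistic.** One-sided: the Fisher exact p (hypergeometric
  tail) of the candidate table. Two-sided: the minimum-likelihood Fisher
  two-sided p (sum of conditional probabilities no larger than the observed
  table's, with the customary 1 + 1e−7 relative tie tolerance). The
  minimum-likelihood form is invariant under simultaneous row and column
  swaps, which the symmetric covariate tables require, and it is the
  construction that reproduces the published cohort p-values; ordering by
  the smaller of the two one-sided p-values does not.
- **Models.** `binomial`: row margins fixed, one nuisance parameter;
  `multinomial`: only N fixed, nuisance pair (π_row, π_col) under
  independence. The multinomial model is the default for covariate tables.
- **Rejection region.** All tables of the sample space with statistic ≤
  observed statistic + 1e−12. Degenerate observed tables (a zero margin)
  raise with the margin named.
- **Supremum.** The region's null probability collapses onto table margins
  (a weight matrix indexed by row/column margins), so evaluation over the
  grid is a bilinear form. Grid: 1001 points per dimension, uniform on the
  open interval, plus one refinement pass of the same resolution in a
  ±1-step window around the argmax. The p-value is monotone under grid
  refinement and stable to 3 decimals from resolution 500 upward on the
  cohort tables.
- **Oracle.** The test suite carries an independent brute-force
  implementation (binomial-coefficient Fisher p, explicit enumeration, dense
  per-table grid accumulation without the margin factorisation or
  refinement) and checks agreement to 4 decimals on every non-degenerate
  table with n ≤ 8, both models, one- and two-sided. The oracle grid is 10⁴
  points for the one-parameter model and 501 points per dimension for the
  two-parameter model, where the worst-case grid error (~3 × 10⁻⁵, bounded
  by the curvature of a degree-≤ 8 Bernstein form) is below the asserted
  tolerance.

## Table reconstruction

`reconstruct_table(group_n, pct_negative, (total_neg, total_pos, N))`
rebuilds a covariate row from a published group size and percentage; the
complement row is the cohort totals minus the stated row. The product
pct × n/100 must be within 0.05 of an integer (rows whose printed
percentages cannot come from integer counts — e.g. 60% of n = 2 — are
rejected explicitly). Cohort totals must cover only the patients evaluable
for that covariate: rows with missing data use the evaluable subset's
totals, not the full cohort's.

## Other statistics

- **Mann–Whitney** — exact by full enumeration of group assignments (valid
  under ties, midranks; extremeness as distance of U from n₁n₂/2) for
  combined n ≤ 20; tie-corrected normal approximation above. Validated
  against an independent pair-counting enumeration oracle for n ≤ 10.
- **Survival** — Kaplan–Meier product-limit curves per CTC stratum and the
  two-group log-rank test, via `lifelines`. Single-stratum input and
  non-positive times raise. Cohort survival simulation is exponential per
  stratum (medians 24/14 months for CTC-negative/-positive breast cohorts)
  with uniform censoring over a 60-month follow-up — the simplest structure
  supporting log-rank testing.
- No multiple-testing correction is applied to covariate tables.

## Synthetic cohorts

Per entity: breast n = 14 (prevalence 0.5, zero-truncated negative binomial
counts, mean 6 / size 4 ≈ median 5), NSCLC n = 18 (mean 4.5 / size 1.2 ≈
median 3, long tail), melanoma n = 11 (prevalence 4/11, mean 7 / size 2.5).
Morphotype composition is classical-dominated with occasional large or
multinucleated cells and rare 2-cell clusters, never producing a patient
with large cells only. Site and receptor flags are independent Bernoulli
draws with entity-specific frequencies.

## What the synthetic data does and does not show

The simulator provides exact ground truth for segmentation, gating,
categorisation and enumeration logic, and calibrated statistical structure
(correlation, counts, censoring) for the cohort statistics. It deliberately
omits: optics (no PSF, no chromatic effects, uniform illumination), red-cell
debris and staining artefacts, megakaryocytes and other CD45-intermediate
confounders, capture/enrichment losses, and irregular cell shapes (all cells
are disks). Passing the recovery tests therefore demonstrates correctness of
the analysis rules, not robustness of segmentation on real microscopy.

## Problem sizes

Tests and the acceptance script run on one CPU in well under a minute each:
slides of 1200² pixels with ~55 cells; cohorts of 11–18 patients;
correlation calibration over 100–200 replicate 40-cell draws; exact-test
oracle sweep over all 350 non-degenerate 2×2 tables with n ≤ 8 × 4
model/sidedness settings.

## Known limitations

- The multinucleation-vs-cluster merge rule is geometric and tuned to
  disk-shaped cells; elongated real cells could defeat it.
- Watershed cell boundaries between touching cluster members are
  intensity-driven and may shift a few pixels, slightly biasing member-level
  means and diameters (cluster membership itself is unaffected).
- The exact-test grid supremum is a lower bound on the true supremum;
  resolution 1001 + refinement makes the residual error ≪ 10⁻⁶, far below
  reporting precision, but pathological regions could in principle require
  finer grids.
- Expression categories sit on hard thresholds; cells whose true mean lies
  within the measurement noise of a boundary can flip category.
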