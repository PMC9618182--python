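# Methods

## Ratiometric model

The analysis targets pooled isobaric-labelling experiments: one master
sample per experimental group, all groups quantified in a single MS run.
With one intensity per protein per pool there is no within-group variance,
so inference is ratiometric rather than test-based:

1. **Analysis-ready filter.** A protein is retained iff it was identified
   with at least `min_unique_peptides` (default 2) unique peptides and has a
   positive intensity in every pool of the design. Zero and blank cells are
   both treated as "not detected" (search-engine exports use both
   conventions). The two filters commute; the filter is idempotent and
   order-independent, and the report counts a doubly failing protein in both
   tallies while reconciling retained = input − |union of failures|.
2. **Normalization.** Raw ratio = case intensity / control intensity.
   Within each comparison all raw ratios are divided by their median
   ("1/median" correction), making the median normalized ratio exactly 1.
   The median is per-comparison, not global, because loading differs per
   pool. The correction removes any constant multiplicative factor on
   either pool, so results are invariant to pool rescaling.
3. **Classification.** UP iff normalized ratio ≥ 1.2, DOWN iff ≤ 0.8,
   inclusive at both boundaries. The pair (1.2, 0.8) is deliberately not
   reciprocal — 1/1.2 ≈ 0.833 > 0.8 — so a protein and its inverse ratio
   are not guaranteed symmetric calls; the suite asserts this documented
   asymmetry rather than hiding it. The threshold is applied **after** the
   median correction, since the corrected value is the quantity the
   ±20 % criterion is meant to bound.

Heatmap support computes row z-scores of the log2 normalized ratios using
the **sample** SD (ddof = 1); rows with zero spread return all-zero scores
and a degenerate flag instead of NaNs. Hierarchical ordering uses Euclidean
distance with complete linkage by default (the default of the common R
heatmap tooling; configurable).

## Set logic

Altered = UP ∪ DOWN per comparison. "Specific to comparison T within a
contrast group O" means altered in T and not altered in any member of O;
the contrast group is always explicit configuration, never inferred,
because different figures use different contrasts (region vs region,
stratum vs stratum). Specific and shared always partition the target's
altered set. Venn regions are computed over all 2^n − 1 membership
patterns for 2–4 sets and conserve the union size. Rankings use the
normalized ratio with deterministic lexicographic tie-break by accession.
Membership is by accession throughout: gene symbols collide and are
carried as annotation only.

## Over-representation analysis

Upper-tail hypergeometric p-value P(X ≥ k) for k hits of an n-protein
query in a K-member set over an N-protein universe, computed with
`scipy.stats.hypergeom.sf(k−1, N, K, n)`; fold enrichment (k/n)/(K/N);
Benjamini–Hochberg step-up FDR within each collection (not across
collections, mirroring per-database reporting). The universe is the
intersection of the analysis-ready proteins with the collection's
annotation space — the background a web enrichment tool uses when given a
custom list — which avoids inflating enrichment with unannotatable ids.
Only over-representation is tested. The test suite checks the p-values
against exact enumeration (rational arithmetic) for universes N ≤ 25 at
1e−12 and verifies that uniform random null queries produce ≤ 6 % rejections
at p ≤ 0.05 over 10,000 draws.

## Validation statistics

- **Orthogonal regression**: ordinary least squares of proteomics ratios on
  orthogonal-method ratios (e.g. western-blot band intensity over
  total-protein stain, case/control); R² is the squared Pearson
  correlation and the p-value is the two-sided zero-slope test. Requires
  ≥ 3 pairs and non-degenerate x.
- **Summary t-test**: two-sample two-tailed t-test from mean/SD/n alone,
  pooled-variance by default (cohort tables rarely state which variant was
  used; Welch is available by flag). Verified to reproduce a raw-data
  t-test to 1e−10 when a sample's own summary statistics are fed back.
  Two zero-variance groups with equal means return t = 0, p = 1 by
  convention.

## Array tomography

Stacks are assumed registered upstream. Per-slice thresholding at
mean + k·SD of that slice (default k = 2) tolerates section-to-section
staining variation; because the rule is affine in the slice statistics it
is invariant to global intensity rescaling. Components are 3D
26-connected across sections, filtered by voxel count (default ≥ 2,
optional maximum) and slice span (default ≥ 1; no consecutive-section
requirement is imposed). Densities are counts per µm³ of the analyzed
volume. Colocalization is centroid-distance based — a channel-B punctum
is colocalized iff its nearest channel-A centroid lies within
`max_distance_nm` (default 500 nm) in physical coordinates with the
anisotropic voxel size (default 70 × 100 × 100 nm) respected — reflecting
the *opposed*, not overlapping, arrangement of pre/postsynaptic markers.
One A punctum may partner many B puncta. Group effects are summarized as
percent change of mean densities, 100 · (mean_B − mean_A)/mean_A.

## Synthetic generators

**Cohort.** Baseline intensities are log10-normal (mean 6, SD 0.5),
mimicking reporter-intensity dynamic range; exact values are immaterial to
ratios. For each comparison an exact count round(frac_altered · n) of
proteins receives a planted ratio drawn uniformly from the UP
(default 1.3–2.5) or DOWN (default 0.4–0.77) interval, applied
multiplicatively to the case pool before noise; with zero noise the
realized raw ratio equals the planted ratio to machine precision. To keep
planted ratios well-defined, a pool may be the case of at most one
comparison and never doubles as a control — the ten-pool study layout
satisfies this. Optional per-pool loading factors (log10-normal,
`pool_loading_sd`) exercise the median correction; measurement noise is
multiplicative log-normal with the requested CV; missing values are
injected only into non-control pools (so ratio denominators always exist;
configurable); unique-peptide counts are 1 + Poisson(4) with a forced
low-count subset. All draws come from one `numpy.random.Generator` seeded
by the config, making tables byte-identical across reruns.

What the generator does **not** emulate: peptide-level quantification,
reporter-ion interference/ratio compression, correlated protein modules,
and batch structure across runs (a pooled design has a single run). Tests
passing on these cohorts therefore demonstrate the correctness of the
filtering/normalization/classification machinery and its statistical
behaviour under idealized noise — not robustness to TMT compression or
inter-individual variability, which pooling removes by construction.

**Image stacks.** Puncta are 2×2×2-voxel cubes placed with a Chebyshev
separation of ≥ 5 voxels (components can never merge under
26-connectivity) inside a 3-voxel margin. A planted fraction of channel-B
puncta is placed at a fixed physical opposition distance (default 280 nm)
from distinct channel-A puncta; the remaining B puncta are sampled
uniformly **outside** an exclusion radius (default 600 nm) around every A
punctum. The exclusion is a deliberate design choice: without it a
"random" B punctum could land within the colocalization cutoff by chance
and the planted fraction would only be a lower bound; with it the planted
fraction is exact for any cutoff between the opposition distance plus one
voxel diagonal and the exclusion radius, which is what makes the
segmentation → colocalization path testable to ±1 punctum. Optional
Gaussian PSF blur and additive Gaussian noise follow placement. Placement
is rejection sampling with bounded retries; infeasible requests raise a
placement error rather than looping.

**Validation panel.** Orthogonal-method ratios cycle through increased
(1.4–2.0), decreased (0.4–0.7) and unchanged (0.9–1.1) bands — the
composition of a deliberately spanning validation panel — and proteomics
ratios are a linear response plus Gaussian noise.

## Problem sizes and numerical choices

The default test suite runs cohorts of 100–500 proteins and stacks of
20 × 128 × 128 voxels, and `scripts/acceptance.py` uses a 6,059-protein
cohort with per-pool missingness 0.008 and low-peptide fraction 0.06 —
rates at which the two clean-up filters remove roughly one protein in
nine, the attrition typical of deep TMT brain proteomes. The whole suite
completes in seconds on one CPU.

Numerical conventions: medians use the standard interpolating definition
(scaling-equivariant, so the post-correction median is exactly 1 up to
floating rounding); z-scores use ddof = 1; the hypergeometric tail is
`sf(k−1)`; BH values are clamped to [0, 1]; thresholds are inclusive;
segmentation thresholds are strict (`>`), so a perfectly flat slice yields
no foreground. Coordinates are 0-based voxel indices; all physical
distances are computed in nanometres with per-axis voxel sizes.

## Limitations

- No per-protein significance testing: with pooled samples the fold-change
  criterion is the inference; the package deliberately provides none.
- No missing-value imputation; proteins with any missing pool are excluded,
  matching the complete-detection filter.
- Enrichment results depend on the chosen universe; term-level agreement
  with web tools is qualitative because their backgrounds differ and are
  versioned.
- The imaging module assumes aligned stacks and does not implement
  registration or deconvolution; with heavy noise and an aggressive
  threshold (low k) over-segmentation is expected — raise `threshold_k`
  and `min_voxels` for noisy data.
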