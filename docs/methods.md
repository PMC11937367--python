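# Methods

## The prioritization funnel

The funnel operates on gene symbols (uppercased, whitespace-stripped, no
alias resolution — symbol normalization is deterministic by design; an
optional synonym table can be applied upstream). A protein is *identified*
in a fraction when detected in at least one replicate, *consistent* when
detected in every replicate of that fraction. Intensity tables are
binarized as `detected := intensity > 0` by default, matching label-free
DIA output quantified without imputation; the threshold is configurable.

Stages run in a fixed order, and each stage's surviving set is a subset of
the previous one by construction:

| stage | rule |
|---|---|
| identified | ≥ 1 replicate, per fraction |
| consistent | all R replicates, per fraction |
| partition | EV-only / SF-only / shared |
| growth factor | membership in a user-supplied gene set (GMT) |
| secreted | predictor calls, `any` (default) or `all` agreement |
| receptor-matched | ≥ 1 receptor partner expressed in ≥ 1 target cell type |

Two genuinely open choices are exposed rather than hidden. The secretion
combiner defaults to *any-of-predictors* (two independent signal-peptide
predictors rarely disagree on clear secreted proteins; requiring agreement
is available via `secretion_mode="all"` and is echoed into every report).
Receptor "expressed" is a boolean input column because expression sources
and cutoffs vary; `expression_flags_from_matrix` builds the flags from a
fraction-of-cells matrix at a configurable threshold (default 10% of cells
of that type). Growth-factor/cytokine sets are always user-supplied GMT
files, never bundled, to avoid database-version drift.

Ligands missing from the ligand–receptor map are dropped with a logged
reason, not an error: an absent pair entry is an annotation gap, not a
malformed input.

`marker_enrichment` builds the 2×2 table (marker / non-marker ×
EV-consistent / SF-consistent) and reports the Fisher exact odds ratio and
two-sided hypergeometric p. A zero cell in the off-diagonal yields an
infinite odds-ratio sentinel; a zero margin switches to a Haldane
(+0.5) continuity-corrected odds ratio with the p-value from the
uncorrected table.

## Organoid assay statistics

Colony-forming efficiency is `100 · n_organoids / n_seeded` in percent,
with organoids counted only above the 50 µm threshold (strictly greater,
matching the counting convention). Diameter comparisons use the
two-sample Kolmogorov–Smirnov test with the asymptotic two-sided p-value
at the effective sample size; the KS verdict is invariant under monotone
transforms, so the log scale used for display does not change it. The
per-comparison alpha under Bonferroni correction is `family_alpha / m`
with `m` supplied explicitly by the caller (the number of comparisons is a
design fact, not something to infer from the data). The display
convention renders four decimals (half-up) and drops to three when the
fourth decimal shifts the value by at most 2·10⁻⁴, reproducing the usual
figure-legend style (0.0167, 0.0125, 0.0025, 0.025, 0.004).

The normality battery runs D'Agostino–Pearson, Anderson–Darling,
Shapiro–Wilk and Kolmogorov–Smirnov (Lilliefors variant, parameters
estimated from the sample) at α = 0.05 and declares a sample parametric
when at least three of the four fail to reject. It requires n ≥ 8 (the
D'Agostino–Pearson minimum) and instructs a nonparametric fallback below
that.

Many-to-one comparisons use Dunnett's procedure. The unpaired case
delegates to `scipy.stats.dunnett`. The paired (repeated-measures) case is
not available in scipy or statsmodels, so the adjustment is computed here:
each treatment's within-replicate differences versus control give a paired
t statistic at df = n − 1, and the family-wise adjusted p is the tail of
max |T₁..T_k| under the equicorrelated (ρ = ½) multivariate-t — evaluated
by 80-node Gauss–Hermite quadrature over the shared control variate and
adaptive quadrature over the pooled scale. For k = 1 this reduces to the
paired t-test; for the balanced unpaired design it agrees with scipy's
Dunnett distribution (both are asserted in the test suite).

The treatment effect is summarized as the mean over matched pairs of
`100·(CFE_t − CFE_c)/CFE_c`, with a seeded percentile bootstrap CI (2,000
resamples over pairs). Pairs with zero control CFE are excluded with a
warning — the ratio is undefined, and silently substituting a pseudo-count
would bias small experiments.

## Histology quantification

Stain separation converts RGB to optical density (`OD = −ln(I/255)`, with
I clipped to ≥ 1 to avoid the singularity at 0) and solves the per-pixel
least-squares projection onto two unit stain color vectors (hematoxylin
counterstain + red chromogen by default; both configurable), clamping
concentrations at zero. Positivity is decided by Otsu's threshold computed
within the tissue mask only, with a fixed-threshold override; the
threshold used is always reported. An Otsu threshold is floored at a
minimum concentration of 0.02 OD: 8-bit quantization alone produces
residual concentrations of order 1/255, and without the floor an entirely
unstained field would be split on that noise. The tissue mask is
non-background pixels (luminance < 0.95 of white), minus an optional
manual exclusion mask for airway walls, vessels and artefacts.

The positive-area percentage is `100·|positive ∩ tissue|/|tissue|`
(areas in pixels; µm² conversions use pixel_size²). Reciprocal intensity
is `255 − mean(intensity over positive pixels)` on the 8-bit scale where
0 is darkest; it is undefined (None) for an empty positive mask. Inside
the full pipeline the intensity entering this formula is the brightness
attributable to the unmixed chromogen alone, `255·exp(−c)`.

LMI lays parallel test lines every `line_spacing` µm (at least one pixel
apart); each maximal run of airspace pixels along a line is one chord,
measured directly in µm. Chords touching the field border are excluded
(their true length is unknowable), and horizontal plus vertical line
families are pooled by default. Per-animal LMI is the unweighted mean of
per-field means, with a warning when the number of fields differs from
the conventional five. Chord measurement (rather than line-length ÷
intercept counting) is used because the target quantity is the average
free-airspace distance; on a disk of diameter d the mean parallel-secant
chord is π·d/4, which the dense-line measurement reproduces within 5%.

## Synthetic fixtures

The generators define the study conditions the tests run under; their
defaults are fixed, and every expected value is recorded by direct
bookkeeping while the fixture is built, never re-derived from the output.

**Secretome fixture.** Four replicates per fraction by default. Planted
candidates are made consistent in a randomly assigned compartment
(shared/SF-only/EV-only at 45/40/15%), annotated as growth factors,
called secreted, and paired to a receptor expressed in AT1 and/or AT2
cells. Decoys fail at controlled stages: inconsistent detection (partial
replicate patterns), consistent but not a growth factor (65%), growth
factor but predicted non-secreted (40% of decoy GFs), or secreted with
either no known receptor or a receptor not expressed in the target cells.
Optional per-replicate dropout noise applies to consistent decoys only
(bookkeeping updated as each dropout lands); planted candidates are
exempt so the planted truth stays exact. Marginal consistency rates
default to 0.25 (EV) and 0.60 (SF), echoing that the soluble fraction
carries the larger consistent proteome.

**Organoid fixture.** Per replicate, each of 10,000 seeded cells receives
one uniform propensity draw shared across conditions; a cell forms an
organoid under a condition when its draw falls below that condition's CFE
probability. Marginally every condition's count is exactly
Binomial(n_seeded, p), while pairs are positively coupled — the
generative meaning of a paired design in which conditions split one cell
isolate, and the reason paired estimation gains precision. Baseline CFE
defaults to 1% (hundreds of organoids per insert at 10,000 seeded cells —
absolute magnitudes are implementer-chosen, documented here, as only the
percent-scale effects are constrained). The default treatment multiplies
CFE by 1.75; cigarette-smoke-extract conditions multiply it by 0.6 and
shift the diameter log-mean by +0.15, qualitatively matching suppressed
formation with larger organoids. Diameters are lognormal
(log-mean ln 120 µm, log-sd 0.4 — organoid sizes are right-skewed and
compared on a log scale) truncated by rejection at the 50 µm counting
threshold. Type counts are multinomial at fixed proportions
(SPC+/ACT+/double+/double− = 55/20/15/10%).

**Histology fixtures.** The stained field is forward-mixed with the same
Beer–Lambert model the unmixer inverts, using the declared stain vectors:
every pixel carries counterstain, and an exact planted fraction of pixels
additionally carries the chromogen, with 5% multiplicative concentration
noise. Airspace masks come in band mode (one vertical air band of known
width — constant horizontal chords) and disk mode (non-overlapping air
disks placed by rejection sampling with a hard attempt cap that fails
loudly rather than overlapping; analytic mean chord π·d/4).

What the fixtures do **not** emulate: real protein identities or
abundance distributions, correlated dropout structure across replicates,
organoid growth dynamics, microscope optics, uneven illumination or
staining gradients, and tissue texture. Passing tests therefore
demonstrate that the estimators recover known truth under the stated
generative models — not that the laboratory results themselves are
reproduced.

## Problem sizes and numerical choices

The test suite runs the funnel-recovery property over 100 random
configurations at 30–150 proteins, the effect-recovery grid at 50 seeds ×
4 planted ratios with 4 paired replicates of 10,000 cells, and the
exhaustive KS cross-check over all ~209² multiset pairs of sizes ≤ 6 from
a 4-letter alphabet. The acceptance script uses 8 paired replicates of
10,000 seeded cells, the generator's defaults, and a single master seed
from which all substreams (generation, bootstrap) are derived via
`SeedSequence`-based splitting, keeping every derived seed below 2³¹.

Degenerate inputs are handled explicitly rather than numerically:
all-identical groups report adjusted p = 1; empty positive masks report a
None intensity; fields whose every chord touches the border report NaN
with a warning; zero-margin 2×2 tables switch to the continuity-corrected
odds ratio.

## Known limitations

- The funnel is intentionally binary and unordered; it does not rank
  candidates or model detection uncertainty.
- The paired Dunnett adjustment assumes a balanced design and a common
  correlation of ½ between comparisons (exact for difference scores
  sharing one control); strongly unbalanced paired designs are not
  supported.
- LMI values depend on inflation/pressure conditions of the source
  tissue; within this package they are comparable only within a paired
  design, which is why the paired comparison is the only one offered at
  the per-animal level.
- Stain unmixing assumes the two-stain Beer–Lambert model; co-localized
  dense stains that saturate the 8-bit range will clip concentrations.
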