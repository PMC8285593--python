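# Methods

This package implements a complete, desk-scale multi-site harmonisation
study for white-matter-hyperintensity (WMH) quantification: a synthetic
cohort generator with known ground truth, a supervised k-NN lesion
segmenter, bias-field handling, lesion-overlap metrics, a statistical
evaluation battery, and the orchestration of two study scenarios (a scanner
upgrade within one cohort; a retrospective merge of differently-equipped
cohorts).  This note documents the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic study does and
does not establish about real data.

## The synthetic cohort model

Each subject is a 3-D phantom on a configurable grid (default 48³ for the
library, 32³ in the scenario defaults; 1 mm isotropic).  The anatomy is an
ellipsoidal brain with a cortical grey-matter shell, interior white matter
and a central ellipsoidal ventricle (CSF).  Hard tissue assignments are
softened by a small Gaussian blur and renormalised, giving partial-volume
maps that sum to one inside the brain; the exclusion mask is the cortical
shell (the structures that confound FLAIR hyperintensity detection).

**Biology.** The true lesion load follows a log-linear age model

    log WMH% = intercept + slope · (age − age_ref) + ε,   ε ~ N(0, σ²)

with defaults intercept = 0 (1 % of brain volume at the reference age
65 y), slope = 0.06 / y, σ = 0.25.  The 1 % scale and the exponential age
dependence are typical of ageing cohorts; the slope makes the load roughly
triple between 60 and 80 y.  The load is split into Poisson-many clusters
(rate 6), seeded half periventricularly (on the ventricle rim) and half in
deep white matter, and grown as jittered near-spherical blobs.  Biology is
identical across sites by construction — the generator's null of "no true
site effect" — so any between-site difference in *measured* load is, by
design, non-biological.

**Scanner effects.**  Per site: a per-modality multiplicative gain and
additive offset; a smooth multiplicative bias field (exponential of a
band-limited Gaussian random field, rescaled so max/min over the brain is
1 + amplitude, mean one over the brain); and additive Gaussian noise.  FA
is treated as a derived quantitative map: it gets a small noise floor
(sd 0.01) but no gain/offset/bias, which is why including it stabilises
cross-site feature matching.  The applied field and the clean (pre-bias,
pre-noise) images are stored as ground truth.

**Raters.**  A simulated annotator omits small lesion clusters (below a
size threshold) with some probability, then moves the lesion boundary by a
signed offset (systematic over-/under-segmentation, in voxels, applied to
the signed Euclidean distance from the mask surface) plus a smooth random
jitter field of given pointwise sd.  The default profiles differ chiefly in
their boundary bias (R1 +0.6, R2a −0.6, R2b −0.4, RU +0.3 voxels): repeat
sessions of one rater (R2a/R2b) are closer to each other than to a
different rater, reproducing the usual within- vs between-rater ordering.
No quantitative rater-noise model exists for the real data; these knobs are
calibrated only to reproduce that qualitative ordering, with between-rater
volume differences of roughly ±30 %.

**Traveling heads** are lesion-free subjects rendered twice under two site
conditions with a known integer-voxel rigid offset; they isolate
non-biological variability and exercise the half-way resampling code.

**Labelled subsets.**  Manual masks are simulated for a fixed number of
subjects per site (default 12), chosen as the highest-load subjects.  This
mirrors the practice of load-matching annotation sets across sites and
guarantees the training-point budget is drawable from every labelled scan.

## Preprocessing stand-ins

The package intentionally re-implements, in minimal form, the standard
preprocessing a real pipeline delegates to established neuroimaging tools.

**Bias-field estimation** fits a 3-D polynomial (default total degree 3,
on [−1,1]³ coordinates) to median-filtered (radius 1) log-intensities, on
an eroded brain interior (erosion ≈ 1/8 of the grid extent) with a
shrinking robust-trimming schedule (3.0, 2.0, 1.5, 1.5 robust sds of the
fit residual).  The erosion matters: a cortical shell whose log-intensity
offset (~0.14 for GM vs WM on FLAIR) is comparable to the field's own log
range cannot be separated from the field by robust statistics alone, and a
plain median-filter detrend tops out near r ≈ 0.7 against the generator's
truth; the interior fit with residual trimming (which rejects CSF and
lesions, whose offsets are large) reaches r ≥ 0.95 on zero-noise subjects
at amplitude 0.3.  The field is exponentiated and normalised to mean one
over the brain; degree 0 therefore returns an identically-unit field.  The
polynomial resolves fields whose spatial scale is no finer than about a
quarter of the grid extent.

**Correlation ratio** uses 64 equal-width bins over the masked range of the
conditioning image and reports the symmetric mean of the two directions;
cost = 1 − explained variance fraction, so 0 is self-similarity and 1 is
independence.  A constant dependent image has no explainable variance and
is reported as cost 1 with a flag.  Traveling-heads costs are computed in
the eroded intersection of the two resampled brain masks (the choice of
mask is a convention; it is recorded here because it affects the absolute
cost values, though not the before/after ordering).

**Half-way resampling** uses the principal matrix square root of the
voxel-to-voxel affine; each image is interpolated exactly once (trilinear
for images, nearest-neighbour for masks).  Affines with non-positive
determinant are rejected (a reflection has no real half).

## The k-NN segmenter

Features per candidate voxel (brain minus exclusion mask), per modality:
the voxel intensity and the mean over a centred cubic patch (default edge
3), both z-scored per subject within the brain mask; plus the three world
coordinates, z-scored over the brain and multiplied by the spatial
weighting coefficient (default 2).  The published parameterisation fixes
the patch size, spatial weight, k = 40 and the 2000/10000
lesion/non-lesion point budget, but not the exact feature operators; this
minimal set is the package's documented stand-in, and per-subject z-scoring
is what makes nearest-neighbour distances meaningful across scanners.

Training sets are drawn without replacement from the labelled subjects'
manual masks (lesion points) and from brain∖(mask ∪ exclusion) (non-lesion
points), split equally across subjects with round-robin remainders.  The
three compositions: *single-site* (one site's examples applied everywhere),
*site-specific* (each site trained on its own examples), *mixed* (one
pooled set, budget stratified equally across sites — the pooled-total
interpretation is the default; a per-site budget is a caller choice).

Classification is exact k-NN under Euclidean distance; the lesion
probability is the fraction of lesion labels among the k neighbours, so
probabilities are multiples of 1/k.  Ties at the k-th distance are broken
by training-point index order — a documented, testable convention verified
bit-for-bit against a brute-force oracle.  Squared distances are computed
in float64 via the inner-product expansion, chunked over candidate voxels.
With leave-one-out evaluation the test subject's own points are removed
before the search.  The binary mask is probability ≥ threshold; the
threshold is not stated in the source description of the method, and 0.9 is
the package default.  Full-cohort volumes are produced by the model as
trained (the designated labelled pool per option), with LOO applied only
when evaluating labelled subjects against their own rater's mask.

## Overlap metrics

Dice, voxel-level FPR (fraction of detected voxels not in the reference)
and FNR (fraction of reference voxels missed), and cluster-level FPR/FNR
(clusters = connected components, default 26-connectivity, configurable to
6/18; a detected cluster is false-positive if it shares no voxel with the
reference).  Conventions for empty masks: Dice of two empty masks is 1;
empty denominators give rate 0; all such cases carry explicit flags rather
than being dropped.

## The statistical battery

*t-tests*: paired and pooled-variance independent (Welch available);
zero-variance degeneracies raise, except identical paired samples which
return t = 0, p = 1.  *Chi-square*: no continuity correction.

*Two-way mixed ANOVA* (between: site; within: analysis option): classical
two-stratum decomposition — subjects-within-site error for the between
effect, subject × option residual for the within and interaction effects.
With unequal site sizes the within-stratum option/interaction split uses
site-size weights, which keeps the sums of squares exactly conservative
(they add to the total SS); for balanced designs this reduces to the
textbook decomposition and matches pingouin.  An all-equal table returns
flagged zeros rather than NaNs.

*One-way ANOVA* with Bonferroni-adjusted pairwise post-hocs, in
between-groups and repeated-measures forms.  Significance markers follow
the *, **, *** convention at 0.05/0.01/0.001.

*ANCOVA*: WMH% on demeaned age with reference-coded site (first site in
sorted order), fitted by normal equations.  The slope test is the joint F
on all age × site interaction terms; the intercept test the joint F on all
site main effects in the interaction model, i.e. the between-site
difference at the mean age.

*Johnson–Neyman*: for a site pair, the t-ratio of the fitted between-site
difference γ + δ·(age − ā) crosses ±t_crit where a quadratic in age is
zero; the roots are solved in closed form and the sub-intervals of the
queried age range where |t| < t_crit are returned.  Degenerate
zero-interaction cases reduce analytically to the whole range or the empty
set.  With more than two sites, per-pair regions are computed via
coefficient contrasts and their intersection is reported — the intersection
convention is this package's choice.

*Elastic-Net variance attribution*: predictors z-scored (categoricals
dummy-coded, constants dropped with a warning), mixing parameter 0.5, 50
penalty values, 10-fold cross-validation with a fixed seed.  The fraction
of outcome variance carried by feature j is β̂_j²/Var(y) (exact for
orthogonal z-scored predictors; predictor covariance terms are ignored,
which is the main caveat of this attribution).  A drop-one ΔR² attribution
and an OLS companion fit are provided because the exact attribution used
for such figures is rarely stated; the two methods are labelled in the
output.  The "site fraction" sums the fractions of all site-derived dummy
columns.

## Non-imaging harmonisation

A declarative ruleset (YAML) maps each cohort's raw covariate units to
common target units: linear rescales (cm → m, min/day → h/week via 7/60),
row-wise field combinations (day/week × min/day / 60 → h/week), and total
categorical collapses (4-class smoking → binary) with no silent "other"
bucket.  Missing operands propagate; nothing is imputed; statistics run on
complete cases and the exclusion count is reported.  Cohort comparison uses
t-tests for continuous and chi-square for categorical variables.

## The two scenarios and their default conditions

Scaled-down defaults keep a full scenario run in the low minutes on one
core: grid 32³, upgrade cohort 30 + 20 subjects (SC1/SC2), merge cohort
20 + 14 + 30 (SC1/SC2/UKB analogue), 12 labelled subjects per site, 300
lesion / 1500 non-lesion training points per pool (the segmenter's own
defaults remain 2000/10000), k = 40, threshold 0.9.  Site conditions:
bias-field amplitude 0.1 (SC1) vs 0.6 (SC2) vs 0.35 (UKB), gains
1.0/1.15/0.9, offsets 0/8/−5, noise sd 2/3/2.5; ages 60–85 for the two
upgrade sites and 46–80 for the third site (partially overlapping ranges).
Each site's designated training masks come from its own rater profile.

These conditions encode the study's causal structure rather than any
particular numeric outcome: the un-corrected bias-field difference is what
option A (no bias correction) must pay for; the per-site rater biases and
scanner idiosyncrasies are what site-specific training inherits and mixed
training averages out.  Under them the expected qualitative pattern
emerges: site-attributed Elastic-Net variance highest without bias
correction, higher for site-specific than mixed training in both
scenarios, and automated segmentations more repeatable than repeated
manual annotation.

## What the synthetic study does and does not show

Passing tests establish that every stage does what it claims on data whose
ground truth is known, that the statistical machinery agrees with
independent oracles to numerical precision, and that the pipeline's
qualitative harmonisation findings are reproduced under controlled
conditions that contain the relevant causal mechanisms.  They do not
establish segmentation accuracy on real FLAIR contrast (the phantom's
lesion contrast and noise are Gaussian caricatures; no Rician magnitude
bias, no motion, no real partial-voluming), nor the size of real scanner
effects, nor that the specific default thresholds are optimal for any real
cohort.

## Numerical conventions and degenerate inputs

Voxel indices are 0-based; world coordinates come from the affine; masks
are unsigned 8-bit.  Determinism: every public entry point takes a seed and
identical seeds give bit-identical outputs; scenario reports are written
with sorted keys and fixed float formatting so repeated runs are
byte-identical.  Degenerate inputs fail loudly with the offending quantity
named: non-positive intensities in the bias fit, empty masks, insufficient
lesion voxels for a training quota, rank-deficient ANCOVA designs,
zero-variance outcomes, incomplete repeated-measures designs, unmapped
categorical values.
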