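# Methods

## Clinical scoring

The MDS-UPDRS part III motor examination has 18 items; each item is the
sum of its rated sub-elements (0–4 each), so item scores are non-negative
integers with item-specific maxima (e.g. rigidity, item 3, has five
sub-elements). Subscores are plain sums over fixed item groups:

| subscore      | items            |
|---------------|------------------|
| tremor        | 15–18            |
| rigidity      | 3                |
| bradykinesia  | 2, 4–9, 14       |
| axial         | 1, 9–13          |

Item 9 (arising from chair) appears in both the bradykinesia and the
axial grouping. We implement the groupings exactly as defined — the item
is double-counted across the two subscores but counted once in the total
(always the sum of all 18 items). The groupings are exposed as keyword
arguments of `compute_subscores` for users who consider the overlap a
transcription slip; note that the published subscore means sum almost
exactly to the published total mean, which mildly supports that reading,
but fidelity to the stated definition wins by default.

When multiple visits exist per subject, the visit nearest the scan date
is scored; exact ties resolve to the earlier visit (deterministic and
pre-treatment-leaning). Dates must be ISO-8601; anything else is
rejected loudly because silent date misparsing shifts visit matching.
Sex is coded female = 0, male = 1; only the significance of the sex
coefficient is ever interpreted, which is invariant to this choice.

The subscore cross-correlation uses Pearson r with df = n − 2 and the
analytic critical value r\* = t\*/√(t\*² + df) at alpha 0.05 two-tailed
(r\* = 0.1028 at df = 362). Variance explained is reported as
round(100·r²) percent. Zero-variance columns produce NaN correlations,
never a silent 0.

## Voxel-wise statistics

Inputs are a 4-D stack of co-registered, modulated, smoothed GM
partial-volume maps (non-negative, finite) with a voxel→mm affine. The
analysis mask keeps voxels with across-subject mean intensity ≥ 0.05
(units of the modulated partial-volume maps, whose tissue values are
O(0.1–1)) and nonzero variance; excluding degenerate voxels up front
keeps every downstream p value well defined.

Per voxel we compute Pearson r against the chosen score, Fisher
z = atanh(r), t = r·√(df/(1−r²)) with df = n − 2, and the tail p from
Student's t. The GLM Y = a + b·UPDRS3 + c·Age + d·Sex + e is fitted by
OLS per voxel; coefficient t statistics use residual df = n − p. With
the nuisance columns removed the t for b reduces exactly to the Pearson
t, which is tested to 1e-10. Designs with condition number above 1e8
are rejected naming the near-collinear columns. |r| within 1e-12 of 1
clamps t at ±1e6 with a warning rather than returning infinity.

### Family-wise error

The FWE method is permutation maxT: relabel the score across subjects
(simple relabelling for the Pearson test; Freedman–Lane permutation of
reduced-model residuals when nuisance covariates are present), record
the tail-extreme statistic over the mask per permutation, and take the
empirical quantile — `numpy.quantile(..., method="higher")` at 1 − alpha
for positive/two-tailed tests, `method="lower"` at alpha for the
negative tail (reported as a negative threshold). Corrected p values use
the add-one convention (1 + #{permutation extreme beats observed}) /
(n_perm + 1), so no p is ever exactly zero. When n_perm reaches n!, all
distinct permutations are enumerated instead (with a warning). Defaults:
n_perm = 1000, seeded generator, negative one-tailed tests for
GM–severity associations (two-tailed by flag). Small-volume correction
is the identical procedure restricted to the intersection of the
a-priori mask with the analysis mask. A Bonferroni threshold
(t at alpha/n_voxels) is reported alongside as an assumption-free
cross-check; maxT is never more conservative under independence and
gains power under spatial correlation.

Permutation inference was chosen over random-field theory because it is
exactly implementable, assumption-light, and auditable against an
enumeration oracle; printed thresholds from other software are therefore
not comparable numbers.

## Cluster reporting

Suprathreshold voxels are decomposed into connected components
(default 18-connectivity; 6 and 26 available), sorted by descending
size. Peaks are the tail-extreme voxel, always reported signed, with
voxel indices and world-mm coordinates (peak_mm = affine · peak_ijk).
Atlas labels are the modal nonzero label over the cluster's voxels with
its coverage fraction; ties break to the lowest label id, and clusters
wholly in background are "unlabeled". Post-hoc cluster-averaged
GM/score correlations are two-tailed with the same critical-r
convention; every exported table carries a note that correlations on
clusters selected for showing an effect are optimistically biased.

## Synthetic cohorts

The generator emulates the *outputs* of a VBM preprocessing chain, not
the chain itself.

**Clinical tables.** Latent 4-vectors are drawn from a Gaussian copula
with the published subscore correlation structure (axial/bradykinesia/
rigidity/tremor block), mapped monotonically to integer subscores with
the published marginals (axial 2.08 ± 1.48, bradykinesia 9.68 ± 5.56,
rigidity 4.12 ± 2.89, tremor 5.76 ± 3.42), then distributed over items
by multinomial splits so the group sums reconstruct the subscores
exactly (item 9 is drawn small, consistent with early-disease cohorts,
and serves both overlapping groups). Age is Normal(62.12, 9.77²)
truncated to [30, 90]; sex and medication flags are Bernoulli with the
cohort frequencies (235/364, 117/364). At n = 364 the realized
bradykinesia–total correlation lands within ±0.05 of 0.8879 across
seeds.

**Images.** Per subject, GM = baseline + b·total + c·age + noise,
Gaussian-smoothed at sigma = 3 mm (reflective boundaries, mass
preserving) and clipped at 0. The default grid is 40×48×40 at 4 mm
(~77k voxels, ~29k in-mask) — desk-scale rather than full template
resolution; coarser grids (20×24×20 at 8 mm, ~3k in-mask voxels) are
used for replicate-heavy simulations. The toy atlas plants eight
mirror-symmetric spherical regions (caudate, putamen, precentral,
hippocampal complex × L/R) with anatomically plausible radii
(10–12 mm); the score effect lives in the striatal labels
(b = −0.002 GM units per UPDRS point), the age effect in the
hippocampal-complex labels (c = −0.0015 per year).

**Noise calibration.** The default noise SD is set by the closed form
ρ = b·σ_score / √(b²σ_score² + σ_sm²), where σ_sm is the smoothed-noise
SD obtained from the kernel's L2 norm. The target interior-voxel
correlation is ρ = −0.40. This was a deliberate design choice made from
an a-priori power analysis: with 3 mm smoothing, voxels near a region
boundary retain only ~0.5–0.7 of the interior slope, and detecting
≥ 80% of all planted striatal voxels under a small-volume maxT
threshold (|r| ≈ 0.19 at n = 364) requires roughly this interior
strength. Weaker calibrations matching the cluster-level correlations
reported for real cohorts (≈ −0.2) would put boundary-voxel power near
30–50% and make voxel-wise recovery a coin flip; the chosen default
keeps the planted effect weak enough that uncorrected inference would
drown in false positives (the FWE machinery still matters) while making
whole-region recovery a sharp, testable property. The generator also
provides closed-form expected *cluster-mean* correlations — stronger
than voxel correlations because region averaging suppresses
smoothed white noise — and the pipeline's recovered cluster-mean r is
validated against that closed form (within ±0.10), not against a fixed
constant.

**What the generator does not emulate.** Registration error,
segmentation failure, inter-regional anatomical covariance, global
atrophy factors, non-stationary or heavy-tailed noise, and asymmetric
hemispheric intensity. Tests passing on these cohorts demonstrate that
the statistical machinery is correct and calibrated under its stated
model; they do not show that real repository data satisfy that model.

## Numerical choices

- OLS via the normal equations with an explicit condition-number guard
  (cond > 1e8 → error); Freedman–Lane t statistics via QR of the
  nuisance block.
- Correlations are clipped to [−1, 1] before the t conversion;
  |r| ≥ 1 − 1e-12 clamps t at ±1e6 with a warning.
- Permutation thresholds use the order-statistic quantile methods noted
  above, so an enumeration oracle reproduces them exactly.
- Atlas label ties break to the lowest id; nearest-visit ties to the
  earlier date; cluster tables sort by size with a stable sort.
- Simulation problem sizes: type-I studies use 200 replicates at n = 30
  on the coarse grid with 500 permutations; recovery and laterality use
  the default grid at n = 364 with 500–1000 permutations.

## Known limitations

- Voxel-level inference only: no cluster-extent or TFCE statistics.
- The Freedman–Lane scheme assumes exchangeable errors after nuisance
  removal; heteroscedastic or family-structured cohorts would need
  restricted exchangeability blocks, which are not implemented.
- Post-hoc cluster correlations are circular by construction and are
  reported descriptively with a warning, never as confirmatory.
- The item-level simulator reproduces group sums and cross-correlations,
  not realistic per-item marginal distributions.
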