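# Methods

## Data model and conventions

A subject consists of two co-registered 3D parametric perfusion maps —
K^trans (min⁻¹) and leakage-corrected rCBV (mL/100 mL) — each paired with a
binary volume-of-interest (VOI) mask on the same grid. Axes are
(row, col, slice): the first two axes are in-plane axial, the third is the
slice direction; voxel indices are 0-based. Maps and masks must be
pre-aligned; no resampling or registration is performed. Masks stored as
floats binarize at > 0.5. Separate masks per map are supported (clinical
VOIs segmented on the two maps genuinely differ in volume).

## First-order (histogram) features

Ten features of the masked intensity distribution. Frozen estimator
conventions (`histogram.py`): sample SD (n−1); Fisher g1 skewness and excess
kurtosis, both population (biased) definitions; percentiles by linear
interpolation between order statistics. A zero-variance VOI gets
skewness = kurtosis = 0 rather than NaN, so feature tables never carry
missing values (the classifiers require completeness). These conventions are
declared, not canonical: different radiomics codebases disagree at the
third decimal, and any consistent choice preserves the downstream ranking.

## Texture features

**Requantization.** Masked intensities map to integer levels 1..G by
equal-width bins spanning [min, max] of the masked values; the masked
maximum lands in level G and a constant VOI maps wholly to level 1. Because
bin edges follow the masked extrema, any positive-affine intensity transform
leaves the quantized volume — and hence all 300 texture features — exactly
unchanged. G ∈ {8, 16, 32, 64, 256} by default.

**Co-occurrence accumulation.** Pair counts are accumulated over *all*
axial slices of the 3D VOI into a single G×G matrix per (direction, G): a
pair (v, v + d·θ) contributes only when both voxels are inside the mask.
This pooled-matrix choice (rather than per-slice matrices averaged) avoids
the sparse, frequently degenerate matrices that small per-slice VOI areas
would produce. Distance d = 1 voxel; directions (0,1), (−1,1), (−1,0),
(−1,−1) in (row, col); matrices are symmetrized by adding the transpose, so
offset signs are immaterial. A direction with no valid pair raises an
error; a pair count below G logs a sparsity warning (expected and benign at
G = 256 for small VOIs — features stay defined).

**Feature formulas.** The 20 Haralick/Soh-Tsatsoulis/Clausi features are
centralized in `texture.haralick_features` with these conventions: logs are
base 2; entropy-type sums run over nonzero probabilities (equivalent to an
ε-guard inside the log); GLCM "variance" (sum of squares) is taken about
the GLCM mean μ = Σᵢⱼ i·p(i,j); sum variance is taken about the sum
average; correlation is clamped to [−1, 1] and defined 0 for a
zero-variance marginal; IMC2 = √(1 − exp(−2(HXY2 − HXY))) clamped to
[0, 1]. The marginal cross-entropies satisfy HXY1 = HXY2 = HX + HY
identically (log(pₓp_y) = log pₓ + log p_y), which the implementation uses;
the test oracle computes the double sums explicitly. Homogeneity is
Σ p/(1+|i−j|), inverse difference moment Σ p/(1+(i−j)²), and its
normalized form Σ p/(1+((i−j)/G)²).

**Rotation-invariant summaries.** For each feature and G, the four
per-direction values are summarized by their average, range (max−min) and
angular variance (population variance, divisor 4). The direction set is
closed under 90° in-plane rotation, so all summaries are invariant to
rotating volume+mask jointly by 90° — a tested property. Inventory:
20 × 5 × 3 = 300 texture + 10 histogram = 310 per map, 620 fused, with
column names `{map}|hist|{name}` and `{map}|glcm|G{g}|{feature}|{summary}`
so the inventory is auditable by string parsing.

## Hotspot baseline

The conventional perfusion readout: four circular ROIs of area 10.55 mm²
placed on the highest-valued regions, means averaged, groups compared by a
two-sided Mann–Whitney U test. Clinically these ROIs are drawn by hand;
here placement is an automated surrogate — a greedy search that repeatedly
centers a disc at the in-mask position maximizing the disc mean, removes
its pixels, and repeats, with deterministic row-major tie-breaking and
search over all slices. Disc membership is the round(area/pixel-area)
pixels closest to the center (ties row-major): the naive
"center-within-radius" rule yields 9 px = 9 mm² at 1 mm spacing, 1.55 px
off the target area, whereas the closest-pixel rule is within half a pixel
at any spacing by construction. The Mann–Whitney p-value uses the exact
null distribution for small untied samples (n₁n₂ ≤ 400) and the normal
approximation with tie correction otherwise; no continuity correction, so
identical groups give exactly p = 1.

## MRMR feature ranking

Features are discretized to three states by the classic mean ± σ rule
(population σ; affine-equivariant, so ranking is scale-free). Mutual
information is the plug-in contingency-table estimate in bits. Ranking is
greedy MID: pick argmax over unselected f of
MI(f; label) − mean over selected s of MI(f; s), ties broken by column
order. MID (difference) rather than MIQ (quotient) was chosen because it is
the canonical default and stays numerically stable as redundancy → 0. This
self-contained estimator is a deliberate substitute for the correlation-
based surrogate in the mRMRe R package; exact reproduction of any
particular published feature list is not claimed. Featureset-size sweeps
are nested prefixes of one ranking: 310, 300, …, 20 per map (620, 610, …
for the fused table). `MRMRSelector` exposes the ranking as a scikit-learn
selector for pipelines.

## Classifiers and evaluation

**SVM**: scikit-learn SVC, linear kernel and C = 1 by default, on features
z-scored with training-fold statistics (zero-variance columns dropped with
a warning). **Tree**: a C4.5/C5.0-family implementation — binary threshold
splits on numeric features (midpoints between observed values), multiway
splits on declared-categorical features, split criterion = information gain
ratio, and bottom-up pessimistic pruning comparing subtree vs collapsed-
leaf pessimistic error counts, where the pessimistic rate is the exact
binomial upper confidence limit at CF = 0.25 (the family's historical
default; the classic software's own printed bounds differ in the third
decimal because it approximates this inversion). Subtree raising is not
implemented. Scores are leaf class frequencies.

**Cross-validation.** Protocols: leave-one-out, stratified 10-fold
(shuffled, seeded, folds re-drawn up to 10 times if a training fold would
lose a class under nested selection), and resubstitution. Out-of-fold
scores (oriented PD-positive; the cohort's sensitivity/specificity
asymmetry matches that orientation) pool into one ROC; AUC is the
tie-corrected concordant-pair statistic; the operating point is the Youden
optimum on the pooled ROC (no threshold rule is canonical here; Youden is
the declared choice); accuracy is tested one-sided against the
no-information rate with an exact binomial tail. Default pairing mirrors
common practice — SVM↔LOOCV, tree↔10-fold — but any pairing is allowed.

**Pooled vs nested selection.** POOLED mode ranks features once on the
full cohort before CV; it is the default for fidelity to how such analyses
are commonly run, and every POOLED report carries an explicit caveat
string, because selection that has seen the test subjects inflates CV
metrics. NESTED mode re-runs selection inside every training fold and is
the statistically sound estimate. The package demonstrates the inflation
mechanism directly: on pure-noise cohorts (n = 98, 200 features) pooled
selection exceeds nested by a positive median AUC margin across seeds —
consistent with near-perfect pooled CV results being achievable without
any real signal.

## Synthetic cohort generator

Each phantom subject is an ellipsoidal lesion (semi-axes 8×8×10 mm,
±15% jitter, jittered center; separate, slightly jittered masks for the two
maps, mirroring the differing clinical VOI volumes) on a 32×32×12 grid at
(1, 1, 5) mm spacing — 5 mm slices as in routine protocols, lesion volume
≈ 2–3 cm³. Within-mask intensities are a stationary Gaussian random field:
white noise smoothed by an anisotropic Gaussian kernel of width
ℓ/spacing per axis, standardized, then affinely mapped to the map's
intensity range (K^trans 0.15 ± 0.05 min⁻¹, rCBV 4.0 ± 1.5 mL/100 mL —
plausible positive ranges; absolute physiology is irrelevant because the
texture stage is affine-invariant). The single class dial is the
correlation length ℓ: 1.5 mm for PD-like (rough: high co-occurrence
entropy, low autocorrelation) vs 4.0 mm for PsP-like (smooth). Class sizes
default to 76/22. No quantitative class effect size exists to calibrate
against, so the ℓ gap is a declared free parameter: at the default gap the
classes are fully separable (CV metrics saturate at 1.0), and as the two
lengths converge the cross-validated AUC collapses to chance — both ends
are tested. Everything is bitwise-deterministic given (seed, subject seed).

What the phantoms emulate: masked 3D geometry, anisotropic voxels,
class-specific spatial texture, per-map mask jitter. What they do not:
necrosis/vessel substructure, pharmacokinetics, scanner noise spectra,
inter-site heterogeneity, or intensity-distribution class differences.
Consequently, passing tests establish correctness and sensitivity of the
*pipeline*, not clinical performance on patient data. One emergent caveat:
rougher fields have higher local extremes, so the hotspot readout is not an
exact negative control on these phantoms — it separates the classes weakly
(through extreme-value statistics), far below the texture features.

## Problem sizes and numerical choices

Cohort-level checks run at the reference size (98 subjects); the
equal-texture null averages 10–20 cohort replicates and the selection-bias
margin uses 10 noise cohorts — sizes chosen to make the stochastic
assertions stable across seeds. Stochastic bands are asserted on means or
medians over replicates, not on single draws. Invariance tolerances are
relative (1e-9) with an absolute floor, since cluster-prominence values
reach 1e8 where absolute 1e-9 is below float64 resolution. Degenerate
inputs are defined, not NaN: constant VOIs quantize to level 1 with zero
entropy and unit energy; a degenerate operating threshold (all subjects one
class) still returns metrics, with a warning.

## Known limitations

* The tree is a C4.5-family reimplementation, not a bit-exact C5.0 clone
  (no boosting, winnowing, or subtree raising).
* MRMR discretization/MI differ from the mRMRe package internals, so
  published selected-feature lists are not expected to reproduce exactly.
* Hotspot placement is an automated surrogate for manual delineation and
  does not exclude vessels/necrosis (the phantoms contain neither).
* GLCM directions are in-plane only (by design, matching anisotropic
  5 mm-slice acquisitions); through-plane texture is not measured.
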