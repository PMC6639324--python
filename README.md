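# perfradiomics

Radiomic analysis of MR perfusion parametric maps for separating
**pseudoprogression (PsP)** from **progressive disease (PD)** in treated
glioblastoma. After chemoradiation, a substantial fraction of enhancing
lesions on follow-up MRI are treatment effects rather than true tumor
regrowth; conventional perfusion readouts (hotspot ROI means of K^trans and
rCBV) separate the two poorly. This package implements the quantitative
pipeline that replaces the hotspot readout with whole-lesion texture
analysis, for imaging scientists who have co-registered parametric maps and
3D lesion masks (NIfTI) and want a tested, reproducible implementation.

## What it computes

Per subject and per map (K^trans in min⁻¹, leakage-corrected rCBV in
mL/100 mL), inside the 3D volume of interest (VOI):

* **10 first-order features** of the masked intensity distribution:
  min, max, mean, SD, skewness, kurtosis, percentiles 1/5/95/99.
* **300 texture features** from gray-level co-occurrence matrices (GLCM):
  intensities are requantized to *G* ∈ {8, 16, 32, 64, 256} equal-width
  levels; co-occurrence counts are pooled over all axial slices at distance
  1 voxel in the four in-plane directions θ ∈ {0°, 45°, 90°, 135°} and
  symmetrized; 20 Haralick-family features (autocorrelation, contrast,
  correlation, cluster shade/prominence, dissimilarity, energy, entropy,
  homogeneity, maximum probability, variance, sum average/variance/entropy,
  difference variance/entropy, IMC1, IMC2, inverse difference moment and its
  normalized form) are computed per direction and summarized
  rotation-invariantly by the average, range and angular variance over the
  four directions: 20 × 5 × 3 = 300.

That is 310 features per map and 620 per subject when both maps are fused.
Downstream: **MRMR** (maximum-relevance-minimum-redundancy, greedy MID
objective on mean±σ three-state discretized features, plug-in mutual
information in bits) ranks features; a **linear-kernel SVM** or a
**gain-ratio decision tree** with pessimistic pruning (C4.5/C5.0 family) is
evaluated by leave-one-out or stratified 10-fold cross-validation with a
pooled out-of-fold ROC, Youden-point operating metrics, and a one-sided
exact binomial test of accuracy against the no-information rate. The
conventional **hotspot** baseline (four disjoint 10.55 mm² discs on the
highest disc-mean locations, four-ROI averaging, Mann–Whitney U group
comparison) is included as the comparator.

Because clinical cohorts cannot ship with the code, a **synthetic cohort
generator** produces two-class ellipsoidal lesion phantoms whose classes
differ only in texture correlation length (Gaussian-smoothed white noise;
PD-like = rough, PsP-like = smooth), at the reference class proportions
76 PD / 22 PsP. Every stage is tested against brute-force oracles and on
these phantoms; see `docs/methods.md` for the model details and what the
phantoms do and do not establish.

## Worked example

```sh
perfrad simulate --seed 7 --n-pd 76 --n-psp 22 --out cohort/
perfrad extract cohort/manifest.csv --out features.csv
perfrad train-eval features.csv --classifier svm --featureset-size 60 \
        --seed 7 --out cv.json
```

which prints (pooled MRMR selection, leave-one-out CV):

```
wrote 98 subjects to cohort/
wrote 98 x 620 feature table to features.csv
svm loocv (pooled): AUC=1.000 acc=1.000 sens=1.000 spec=1.000 binomial_p=1.51e-11
caveat: selection performed outside CV: feature selection saw the full cohort, so cross-validated metrics are optimistically biased
```

At the default class separation the texture classes are fully separable:
AUC/accuracy/sensitivity/specificity all 1.0, and the binomial test says
98/98 correct is far beyond the 77.6% no-information rate (p ≈ 1.5×10⁻¹¹).
The printed caveat is deliberate: with `--selection-mode nested` the
selection is re-run inside every training fold and gives an honest (lower
on noise, similar on strong signal) estimate. The hotspot comparator runs
with `perfrad hotspot cohort/manifest.csv --out hotspot.csv`, and
`perfrad predict` applies a saved model bundle to new subjects.

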