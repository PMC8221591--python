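# Methods

## In-situ dot quantification

### Model

A single-channel plane is modeled as `image = b + Σ_k A_k G(x − x_k; σ) + ε`,
where `b` is a locally flat background, each hybridization dot is an isotropic
2D Gaussian of integrated intensity `A_k` (the standard point-spread proxy for
a diffraction-limited smFISH spot), and `ε` is pixel noise. Under this model
the background-corrected total intensity of an ROI is `Σ_k A_k` over the dots
it contains, so dividing by a calibrated per-dot intensity `D` estimates the
dot count even where discrete spots merge. Counts are therefore real-valued by
construction.

### Procedure and numerical choices

1. **Denoising.** Non-local means (`skimage.restoration.denoise_nl_means`,
   fast mode, patch size 5, patch distance 6), with filter strength
   `h = 0.8 × σ̂` where `σ̂` is the wavelet-based noise estimate. A constant
   image is a fixed point and a noiseless image passes through essentially
   unchanged, so denoising never destroys calibration.
2. **Adaptive detection.** Seed pixels exceed `threshold_ratio` (default 2.0,
   i.e. 200 %) times the local mean over a square window of
   `surround_window_um` (default 40 µm ≈ 4 cell diameters; the protocol names
   no window, so it is configurable). Connected seed areas larger than a
   minimum area survive; in the default component mode each candidate must
   additionally have mean intensity ≥ `threshold_ratio` times the mean of its
   surround window excluding its own pixels. A pixel-only mode is available
   because the published wording does not fix whether the 200 % criterion is
   applied pixel-wise or per component. The area threshold "> 30 µm" is read
   as > 30 µm² (an area in µm is dimensionally inconsistent); it applies to
   cell-scale expression areas, while dot detection uses a much smaller
   minimum (`min_dot_area_um2`, default 0.2 µm²).
3. **ROI partition.** Pvalb⁺ cells come either from detection on the Pvalb
   channel or from a provided label mask; the non-Pvalb⁺ ROI is exactly the
   region pixels minus cell pixels, so the two classes partition each region.
4. **Background.** Mean intensity of ROI pixels outside every labeled
   expression area (dot masks are dilated first, see below). If labeling
   covers an ROI entirely, the estimate is refused rather than extrapolated.
5. **Single-dot calibration.** The manual "representative dots" step is
   replaced by an automatic rule: components with no neighbor centroid within
   2 equivalent diameters and area inside the interquartile range of the
   component-area distribution; explicit id lists are also accepted. Before
   integration each dot mask is dilated by `dot_dilation_um` (default 1 µm =
   2σ at the default dot σ of 0.5 µm) so Gaussian tails below the threshold
   are included; the added background is removed by the `− b·area` term.
   Without this dilation roughly half the integrated intensity of a
   threshold-limited dot core is missed and counts are biased upward.
6. **Counting and density.** `N = (Σ ROI − b·area)/D`, clamped at zero with a
   warning; densities in dots/mm² or dots/µm².
7. **Overlap.** A Pvalb⁺ cell is IEG⁺ when the overlapping IEG pixel fraction
   strictly exceeds `overlap_min_fraction` (default 0, i.e. any overlap — the
   protocol states only "overlapping fluorescence"). Proportion by area is
   the summed area of IEG⁺ cells over total cell area.
8. **Per-cell intensity.** Background-corrected mean pixel intensity per
   cell; distributions are returned as empirical CDFs for two-sample
   comparison.

Because every threshold is a ratio and every estimate is a ratio of
background-corrected intensities, the pipeline is invariant to a global
intensity rescaling (verified to < 10⁻⁶ relative) and to translations up to
border effects. The per-ROI report carries the single-dot intensity as a
column so its consistency across groups can be inspected; it is not used as a
gate.

## qPCR statistics

### Stability measures

All measures operate on replicate-averaged CT values of the candidate panel.

- **Model-based (NormFinder-style).** Within each group the gene × sample
  matrix is decomposed two-way. Residuals after removing gene means and
  per-sample loadings give the intragroup variance, bias-corrected by
  `G/((n−1)(G−1))` for the rank lost to centering. The gene-by-group
  interaction of the loading-free group means gives the intergroup difference
  `d_gj`. The combined stability value is `mean_j(|d_gj| + σ_gj/√n_j)`
  (the Andersen-type combination without shrinkage — transparent and exactly
  checkable against a brute-force least-squares oracle). Lower is more
  stable.
- **Pairwise M (geNorm-style).** `M_g = mean_h SD_samples(CT_g − CT_h)`.
- **Raw SD** of per-sample CT, and **comparative-ΔCt** (mean pairwise SD,
  which shares its computational core with M; both are kept as separate rank
  columns of the four-method aggregate).

Ranks are aggregated by geometric mean (RefFinder-style; the exact RefFinder
method set is unpublished, so this four-method aggregate is the documented
stand-in), ties broken by the model-based rank.

**Identifiability.** A group shift common to every gene of a sample is
indistinguishable from a loading difference, so intergroup differences are
defined relative to the candidate-panel average and sum to zero across the
panel. "Countervailing" is therefore a within-panel notion.

### Pair selection and fold changes

Among the `top_k` (default 4) genes by aggregated rank, the selected pair
minimizes `|d₁ + d₂|`; ties go to the smaller summed stability. As a final
check the pair's own group expression ratio (per-sample expression
`2^(−mean pair CT)`, group-mean ratio SD/sleep) and signed fold change are
reported — a good pair sits near 1.

ΔCT normalizes each target to the arithmetic pair mean; ΔΔCT is the group
difference of ΔCT means; `log₂FC = −ΔΔCT`; the propagated SE is the
root-sum-square of the two group SEMs (first-order, matching the error bars
of the published presentation). Signed fold changes use `F = r` if `r ≥ 1`
else `−1/r`, rounded to two decimals in report tables.

### Tests

All tests run on ΔCT values. Group contrasts use a Welch two-sample t — the
published omnibus/post-hoc family structure is under-specified, so the
package implements a documented Welch-t + Holm–Šidák approximation, with the
family being the genes of one (cell type × region × duration) report table.
Marker enrichment (affinity-purified vs input fraction) is the per-sample
paired ΔΔCT tested against 0 with a one-sample t. Holm–Šidák is the standard
step-down adjustment `p_i = max_{j≤i} 1 − (1 − p_(j))^(m−j+1)`
(statsmodels implementation, verified against the closed form). Degenerate
inputs are handled explicitly: two exactly constant equal groups give p = 1,
and all-zero enrichments report t = 0, p = 1.

## Behavioral screen

Scored bins are treated as interval-dominant labels. Percent sleep uses bins
fully inside the query window. The exclusion rule removes sleep-group records
whose wake fraction over the trailing 45 min strictly exceeds 0.60 (exactly
0.60 is kept); sleep-deprived records are never excluded. With 2-min bins,
45 min is not a whole number of bins; the rule uses the maximal suffix of
whole bins with total length ≤ 45 min (22 bins = 44 min).

## Synthetic data: what it emulates and what it does not

The scene generator produces exactly the model the quantifier assumes
(enabling exact-recovery tests at zero noise): flat background (default 20
a.u.), Gaussian dots with σ = 0.5 µm whose SNR (peak/background, default 4) and
count are designed, filled circular Pvalb⁺ somata (radius 5 µm), additive
Gaussian noise (default σ = 2 a.u.) with an optional Poisson mode, and a known
subset of IEG⁺ cells (default 30 %) carrying dots in their somata. Default
geometry is 1024 × 1024 px at 0.25 µm/px, the smallest field in which 200
uniformly placed dots keep the expected overlap fraction below 5 % (a
precondition of the ratio-based count formula, enforced at construction).
It does **not** emulate tissue autofluorescence, uneven illumination,
chromatic shift, out-of-focus light, or irregular cell morphology — passing
recovery tests show correctness of the estimator under its stated model, not
robustness to those artifacts.

The CT generator draws
`CT = baseline + effect·1[SD] + loading(sample) + N(0, σ_bio) + N(0, σ_rep)`
with defaults σ_bio = 0.15, σ_rep = 0.05, σ_loading = 0.3 cycles and three
technical replicates, values in the range reported for careful qPCR work.
The default panel uses target baselines and effects from the published 3-h
cortex group means (Arc −1.26, Homer1a −1.06, Bdnf −0.48, Clock −0.19 cycles)
and six reference candidates: a countervailing pair at ±0.15 cycles and four
unstable genes (+0.5, +0.7, +0.9, −2.1) arranged to sum to zero (see
identifiability above) with no near-cancelling competitor pair among the
well-ranked candidates. Group sizes default to the reported 4 sleep / 5 SD.

The sleep generator draws i.i.d. Bernoulli bins; real sleep is strongly
autocorrelated, so the generator is adequate for exercising bookkeeping and
the exclusion boundary, not for modeling sleep architecture.

## Problem sizes

Recovery and calibration checks run at sizes chosen to make the suite quick
while keeping estimates sharp: 10 seeded 200-dot scenes for count recovery,
100 seeded panels for pair-selection recovery, 10⁴ null simulations at
n = 6/group for test calibration, 200 seeded panels for fold-change recovery.
The end-to-end in-situ pipeline default for tests is 512 × 512 px scenes with
proportionally fewer dots (the overlap precondition scales with field area).

## Known limitations

- No amplification-efficiency (Pfaffl) correction; ΔΔCT assumes ~100 %
  efficiency for all genes.
- The Welch-t family is an approximation of the original ANOVA-based post hoc
  structure; published p values are not reproduction targets.
- Dot-count accuracy degrades when dots overlap heavily (> ~5 % overlap
  fraction) or when SNR < ~2, where threshold detection misses calibration
  dots.
- 3D stacks, stitching, and proprietary microscope formats are out of scope;
  masks arrive as integer label images.
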