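# Methods

This note records the models behind `tomoblast`, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot show.

## Physical model and units

A tomogram is a voxel grid of refractive index (RI) `n`, array axes
`(z, y, x)` with physical pitch `(dz, dy, dx)` in µm (1 µm³ = 1 fL). The
mounting medium is phosphate-buffered saline; its RI `n_m` defaults to
1.337 (a standard PBS value — the instrument-side value is not published —
and configurable everywhere). Default voxel pitch is 0.156 µm lateral /
0.312 µm axial, typical of commercial holotomography; every measurement
uses physical spacing, never voxel counts.

Dry mass uses the linear RI–concentration relation `c = (n − n_m)/α`. The
specific refractive increment defaults to α = 0.185 mL/g, back-derived from
the sensitivity statement that an RI contrast of 0.001 corresponds to
5.4 fg/fL; with these units `c` in g/mL times volume in fL gives mass in pg
directly. Voxels below `n_m` contribute negative mass (kept; a negative
region total is physically suspect and flagged by the caller if needed).

## Phantom generator

**What it emulates.** Single myeloblasts in suspension: a cell body with a
large wrinkled nucleus, 1–3 bright nucleoli, occasional high-RI lipid-like
droplets, intra-region RI heterogeneity (chromatin-like texture), and
additive measurement noise. Two genotype groups (NPM1 wild-type / mutant)
whose per-cell parameter distributions match the published group means ± SD:
cell volume and sphericity, N/C volume ratio, nucleus sphericity, total
nucleolus volume, and mean RIs of cytoplasm, nucleoplasm and nucleolus.

**Shape model.** Each body is a star-shaped surface `r(θ, φ) = r₀·exp(a·f)`
where `f` is a random band-limited real-spherical-harmonic field (degrees
2–11, spectrum weighted ∝ ℓ so low-sphericity shapes are wrinkly rather
than elongated, which keeps nuclei compact enough to fit their cells). The
amplitude `a` is found by bisection of the analytic amplitude→sphericity
map (quadrature on the angular table), then corrected against the
*measured* sphericity of the voxelized mask (up to 6 iterations, tolerance
0.005), so generator targets and morphometric measurements agree by
construction. The voxel mask is cut at the iso-level of the radial field
that matches the target volume to the nearest voxel, pinning volumes (and
hence N/C ratios) almost exactly.

**Nucleus parameterization.** The group statistics are mutually
inconsistent if cell volume and nucleus volume are drawn independently
(the mean N/C ratio is not the ratio of mean volumes, and independent draws
violate nucleus < cell in the tails), so the generator draws cell volume
and N/C volume ratio and derives nucleus volume. The implied nucleus-volume
mean (ratio mean × volume mean ≈ 193 fL for the mutant group) sits within
sampling error of the printed 201 fL at the tested sample sizes.

**Containment.** A deeply wrinkled nucleus (sphericity ≈ 0.5) at N/C ≈ 0.42
cannot always fit strictly inside a smooth cell envelope along every
direction. The generator first tries independent nucleus patterns with a
voxel-wise containment check; failing that, it re-voxelizes the nucleus
field *confined to the eroded cell* with the same volume-pinning iso-level —
containment and exact volume are then guaranteed, at the cost of a small
upward bias in realized nucleus sphericity (≈ +0.003 after correction,
well inside the 3-SEM recovery bands). This emulates a nucleus moulded by
the cell boundary.

**Sampling.** Parameters are truncated normals, symmetric in units of SD
(`k = min(3, distance to the nearer physical bound)`), which leaves the
expected value equal to the configured mean; heavily right-skew-bounded
parameters (volumes) therefore have slightly narrowed spread rather than a
shifted mean. The three region RIs are drawn jointly with correlations
(cyt–nucpl 0.5, nucpl–nucleolus 0.8, cyt–nucleolus 0.4): overall optical
density covaries within a cell, and the correlation keeps the
nucleolus-above-nucleoplasm ordering violated in < 1 % of draws (those are
clamped to a +0.0005 floor). Texture is a Gaussian random field smoothed at
0.5 µm, standardized per region to SD 0.002 RI units and mean-corrected, so
pre-noise region means equal the configured values exactly. Noise is
additive Gaussian (SD 0.001 RI) clipped at `n_m − 3σ`.

**Cohorts.** Per-patient parameter shifts are N(0, ICC·σ²) with ICC = 0.3
(dominant-clone similarity; cells within a patient correlate), cell-level
spread scaled by √(1 − ICC) so marginals are preserved; ICC = 0 collapses
to i.i.d. sampling. Default counts follow the study design: 900 WT images
across 26 patients and 1,173 MUT across 22; four validation patients per
group (144 WT / 189 MUT images) disjoint from training; the training images
split into optimization and generalization subsets using the published
proportions (the printed WT counts are internally inconsistent — 637 + 144
> 756 — so proportions, not absolute counts, are used; the MUT counts
574/410 are consistent and exact). Mutant patients get a VAF drawn
Uniform(0.2, 0.5) (no distribution is published); wild-type VAF is 0.

**What passing tests do not show.** The phantoms have piecewise-constant
base RIs with sharp region boundaries, no optical forward model (no
diffraction or missing-cone artifacts), no cell-to-cell contact, debris or
imaging failures, and Gaussian parameter distributions where real
morphology is skewed. Recovery of the printed statistics therefore
validates the generator–measurement chain, not performance on instrument
data.

## Morphometry

Volumes are voxel counts × voxel volume. Surface areas come from marching
cubes on the binary mask with a facet-normal projection correction: each
triangle contributes `A_t |n_t · n̂|`, `n̂` the unit gradient of the 1-voxel
Gaussian-smoothed mask at the triangle centroid. For a staircase
approximation of any plane this equals the projected (true) area exactly,
removing the ≈ +8–10 % bias of raw marching-cubes areas on oblique and
curved digital surfaces. Closed-form validation (≥ 20-voxel radius): sphere
+0.4 %, 2:1:1 prolate spheroid +0.5 %, axis-aligned cube −2.5 % (flat-facet
chamfer; all within the 3 % validation bound). Sphericity
ψ = π^{1/3}(6V)^{2/3}/A is dimensionless and invariant to isotropic
rescaling. The 2D N/C ratio uses axial (z) projections, the en-face
microscopy convention.

The rule-based segmenter replaces interactive pixel classification with
deterministic rules: Gaussian smoothing at 0.25 µm; cell = largest
connected component above max(whole-volume Otsu, `n_m` + 2·noise SD),
closed and hole-filled (a second similarly sized component raises an
ambiguity error; an empty field raises an empty-field error); nucleus =
largest hole-filled component above a two-means-refined threshold
initialized by Otsu over the cell interior (> 0.5 µm from the boundary,
because boundary voxels blend with the medium under smoothing and would
poison the histogram); nucleoli = closed components above the
sigma-clipped nucleoplasm mean + 2 SD, minimum 1 fL; lipid = cytoplasmic
components above RI 1.39, minimum 0.2 fL. Lipid droplets are excluded from
the cytoplasm mean RI but included in whole-cell dry mass.

Segmentation accuracy against ground truth on canonical (group-mean)
phantoms: Dice ≈ 0.986 for the cell (≥ 0.95 noiseless and ≥ 0.90 at the
default noise are asserted), ≈ 0.88 cytoplasm, ≈ 0.84 nucleus, ≈ 0.75
nucleoplasm, ≈ 0.5–0.7 nucleolus. The interior compartments are limited by
physics of the phantom population, not implementation: the
cytoplasm/nucleoplasm contrast (0.0057 ± 0.0036 RI across cells) is only
≈ 2.9× the intra-region texture SD and overlaps zero for ≈ 5 % of cells,
so a deterministic intensity rule cannot reach the whole-cell accuracy on
every phantom. Texture was deliberately not weakened to inflate these
figures. Statistical round-trip tests therefore measure through
ground-truth masks; the segmenter is validated separately.

## Group statistics

Per-parameter two-sided Mann–Whitney U: midranks; exact permutation
enumeration of all C(n, n₁) assignments when n₁ + n₂ ≤ 20 (correct under
ties); otherwise the normal approximation with tie correction and
continuity correction. Degenerate comparisons (all pooled values equal)
return P = 1 with a flag. Tiers: * P < 0.01, ** P < 0.001, *** P < 0.0001.
No multiple-testing correction is applied, and cells are pooled across
patients without a clustering adjustment — both deliberate mirrors of the
original per-cell analysis and statistical caveats for any reuse.

## Classifier

The tail–body–head topology: a stem convolution; a tail that alternates
residual bottleneck blocks with 2×2×2 max-pooling; a body that alternates
bottlenecks with 2×2×2 nearest-neighbour upsampling and, after each
upsampling, concatenates the first tail feature maps of equal resolution;
a head that downsamples again; global average pooling; a latent projection
(264-d at full scale — the embedding used for t-SNE-style analyses) and a
two-way output. Each bottleneck sums a 1³ convolution with a 1³→3³→1³
chain through reduced channels; a shared instance-norm + leaky-ReLU
pre-activation feeds both paths and each inner convolution has its own.
The published full-scale network fixes only this topology publicly
(~8.08·10⁷ parameters, 247 convolutional layers at 160×160×72), so channel
widths, stage counts and latent size are configuration: the `full` preset
reproduces the topology at reduced width, the `tiny` preset (32×32×16,
1 stage/component, width 4, latent 32, ≈ 1.2·10⁴ parameters) trains on a
CPU in minutes. Parameter counts are verified against an independent
layer-walk oracle.

The stack is implemented directly on NumPy (im2col/shifted-view
convolutions on BLAS, hand-derived backward passes validated by finite
differences). Training follows the published recipe: Adam with β₁ = 0.5,
β₂ = 0.999, initial learning rate 5·10⁻⁴, decay 10⁻⁴ read as decoupled
(AdamW-style) weight decay — the common reading for Adam configurations —
cosine annealing with a 32-epoch period (warm restarts), batch 16, at most
200 epochs, cross-entropy weighted inversely to optimization-set class
sizes (normalized so balanced classes give plain cross-entropy), each
optimization image fed once raw and once augmented per epoch. Batches are
stratified by class (proportional interleave of per-class shuffles): at
desk-scale cohort sizes (~15 batches per epoch) class-imbalanced batches
otherwise drive a noisy random walk of the output bias that can swamp the
early discriminative signal; with hundreds of epochs and thousands of
images the distinction is immaterial. Augmentation:
Gaussian noise, integer-voxel translation, in-plane (x and y, never z)
flips, rotation about the optical axis with medium-value padding.
Gradient updates use the optimization subset only; the generalization
subset (held-out training patients' images) is scored each epoch and the
checkpoint with the highest optimization + generalization accuracy sum is
kept (ties → earlier epoch, so selection is reproducible). At inference,
exactly equal raw outputs are called wild-type, so the screen errs toward
confirmatory genetic testing rather than mutation calls.

The test-scale separability check uses phantoms rendered at the fine
analysis grid and average-pooled to the network input
(`block_downsample`): very coarse grids cannot *realize* subtle sphericity
targets geometrically, but partial-volume averaging preserves the
fine-grid morphology as gray values. Even so, sphericity estimates at
~5-voxel nuclear radii carry ≈ ±0.1 digitization noise whatever the
method, so a 0.45-vs-0.60 sphericity contrast alone is not separable at
32×32×16; the toy cohort therefore exaggerates two further *printed*
genotype contrasts in their printed directions (N/C volume ratio, and
cytoplasm RI lower in the mutant) with tightened RI spreads, and uses a
learning rate of 2·10⁻³ — the published rate is tuned for ~200 epochs on
an 8·10⁷-parameter network and is far too slow for a 30-epoch toy budget.
The training-config *defaults* remain the published values throughout. Published real-data figures
(76.0 % single-cell validation accuracy, 20.4 %/25.8 % misclassification)
require the non-deposited patient tomograms and trained weights and are
out of scope.

## Screening

A patient's statistic is the positive prediction ratio r (fraction of
cells called mutant). Sweeping thresholds over all distinct ratios (call
mutant when r ≥ t, the closure that makes the published thresholds 93.3 %
and 39.2 % consistent with achievable points) yields the patient-wise ROC;
every point carries the half-open interval (t_low, t_high] of thresholds
achieving it. AUC is the trapezoid over the step curve and is cross-checked
at runtime against the pair-concordance statistic with ties counted ½
(identical by construction; a disagreement raises). Operating points are
the max TPR at FPR = 0 and the min FPR at TPR = 1 with their threshold
intervals.

## Problem sizes and numerical choices

Statistical round-trip checks run 200 phantoms per genotype on a 96×96×48
grid at 0.2 µm lateral / 0.35 µm axial pitch — a reduced analysis grid
chosen so the full suite runs on a single CPU; all measured quantities are
in physical units and do not depend on the grid choice. Shape calibration:
analytic bisection (48 steps) + measured-sphericity correction (tolerance
0.005, ≤ 6 iterations, amplitude cap 2.2/max|f|); sphericity floors ≈ 0.3
(the unreachable-target error names the achievable range). Random numbers
flow from a single seed through named SeedSequence substreams per stage;
identical seeds give bit-identical phantoms, manifests and non-training
artifacts (training is likewise deterministic for a fixed BLAS build).

## Known limitations

* No optical forward model: segmentation difficulty on real tomograms
  (halo, missing-cone elongation) is understated.
* Only the printed parameter subset is modeled (the study's full
  39-parameter panel is not public).
* The patient table reports 23/29 patients while the dataset flow reports
  22 MUT / 26 WT specimens; the generator follows the dataset flow and
  both counts are configurable.
* Intensity-only segmentation caps interior-compartment Dice well below
  the whole-cell level under realistic texture (see above).
* The NumPy network trains CPU-scale presets only; the full-resolution
  preset is exposed but impractical without accelerator hardware.
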