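# Methods

## Scope

`germcycle` packages two quantification procedures — five-phase cell-cycle
scoring of scRNA-seq data and nuclear/cytoplasmic (N/C) fluorescence ratio
measurement — together with synthetic-data generators that provide ground
truth for both. Alignment, UMAP embedding, graph clustering, RNA velocity
and enrichment analysis are deliberately out of scope; the package starts
from a count matrix (or image) and ends at labels, proportions, ratios and
their statistics.

## Count simulation

Counts are negative binomial with a mean/dispersion parameterization,
`Var = mu + phi * mu^2`; `phi = 0` degenerates to Poisson. Each cell draws
a true phase from its group's 5-vector of proportions (i.i.d. by default;
a stratified mode apportions exact counts by largest remainder, used when
a test needs deterministic composition). A marker gene of phase *k* has
mean `base_mean * marker_fold_change` in cells truly in *k* and
`base_mean` otherwise; background genes are phase-independent. All gene
baselines share `base_mean` — per-gene baseline heterogeneity is
deliberately omitted so that closed-form moment checks stay exact; the
phase classifier standardizes scores per phase, which removes baseline
differences anyway. Per-cell library size factors are log-normal with
mean 1 and configurable CV. One global seed is split into independent
substreams per group, so partial re-runs with the same seed reproduce
bit-identical output.

Defaults describe a moderately expressed cell-cycle panel in a balanced
fetal germ-cell population against a G1/S-depleted mutant: 1,000 cells
per group, control proportions (0.2, 0.2, 0.2, 0.2, 0.2), mutant
(0.02, 0.245, 0.245, 0.245, 0.245), 20 markers per phase, 500 background
genes, fold change 2.5, `base_mean` 5 counts, dispersion 0.1, library CV
0.1. An optional sixth "non-cycling" state (no marker elevation, default
fraction 0) stands in for G0-like cells.

What the generator does *not* emulate: UMI chemistry, doublets, ambient
RNA, per-gene baseline variation, developmental expression programs
overlapping the cell-cycle signal, or dropout beyond what NB sampling at
low means produces. Passing recovery tests therefore demonstrates the
correctness and noise tolerance of the scoring machinery, not its
performance on arbitrary real tissue.

## Cell-cycle scoring

1. **Reference filtering.** For each phase a provisional score is the
   per-cell mean expression of the phase's genes (the gene under test is
   included — a single exclusion pass, not an iterated one; an optional
   iterate-to-fixpoint mode exists for sensitivity analysis). A gene is
   kept iff its Pearson correlation with its own phase score is at least
   `r_min` (default 0.2). The correlation is signed: an anti-correlated
   gene is excluded even at `r_min = 0`, and zero-variance genes are
   excluded because their correlation is undefined. Spearman is available
   by flag. Genes absent from the matrix are dropped with a warning; a
   phase losing every gene is an error.

2. **Scores.** `s_k(c)` = arithmetic mean of normalized log expression of
   the retained phase-*k* genes in cell *c*. Normalization is
   library-size log1p (`ln(1 + 1e4 * count / total)`): the scoring
   contract (averages, correlations, standardization) does not depend on
   which variance-stabilizing normalization feeds it, and the choice is
   recorded in `.uns['normalization']` provenance.

3. **Scaling.** Stage 1 z-scores each phase column across cells
   (population SD; a zero-variance column is an error naming the phase).
   Stage 2 centers each cell's 5-vector, yielding the per-cell *pattern*.
   Both stages are kept: pattern similarity uses the row-centered stage-2
   matrix, while the "uniformly low" G1 rule below must consult the
   stage-1 z-scores, because a row-centered vector can never be entirely
   below zero.

4. **Assignment.** Idealized patterns: phase *k* expects 1 at itself,
   0.5 at its two cyclic neighbours (G1/S→S→G2→G2/M→M/G1→G1/S), 0
   elsewhere, row-centered — encoding the persistence of each phase's
   program into adjacent stages. Per cell, Pearson similarity against the
   five ideals (the ideal matrix is a parameter, so alternatives are
   testable); then, in order: best similarity < `sim_min` (0.3) →
   unclassified; all z-scores < `tau_low` (0) → G1; best phase G1/S or S
   with similarity margin ≥ `delta_margin` (0.3) over the runner-up →
   that phase; best phase in {G2, G2/M, M/G1} → G2/M/G1; otherwise
   unclassified. Ties break by the fixed phase order, making assignment
   deterministic and invariant to cell order.

   The collapsed G2/M/G1 category is part of the method: once a cell has
   passed S phase its marker pattern no longer discriminates G2 from M
   from the following G1. The numeric cutoffs separating G1 and
   unclassified are an interpretation — no published criterion fixes
   them — so they are explicit `AssignParams`, recorded in output
   provenance, and configurable.

   A note on invariances: assignment is exactly invariant to a positive
   affine transform *shared by all cells* (column z-scoring absorbs it)
   and to cell permutation. It is *not* exactly invariant to per-cell
   affine transforms — per-cell scale factors perturb the column means
   and SDs — but on well-separated data labels are empirically stable
   under moderate per-cell perturbations, which is what the test suite
   checks.

5. **Proportions and comparison.** Per-group label fractions with counts;
   homogeneity across groups is tested by chi-square on the group × label
   count table without continuity correction (all-zero categories are
   dropped, reducing the degrees of freedom).

## QC and expression statistics

Cells must detect **more than** `min_genes` (200) genes — a strict
inequality, with a flag for ≥. The filter is applied per sample before
merging. No mitochondrial or doublet filtering is performed. Zero-total
cells are a named error at normalization.

Wilcoxon rank-sum tests are two-sided; both groups ≤ 8 cells and tie-free
uses exact enumeration, otherwise the normal approximation with tie and
continuity correction; all-tied genes report p = 1. Marker detection
(one-vs-rest) tests only genes detected in ≥ `min_pct` (0.25) of either
group whose natural-log fold change of mean normalized expression
(pseudocount 1, i.e. `ln((mean_A + 1)/(mean_B + 1))` on the
back-transformed scale) clears 0.25 — positive only in `only_pos` mode —
and adjusts p-values by Bonferroni over the tested genes (Benjamini–
Hochberg by flag, never silently). Welch *t*-tests use the
Welch–Satterthwaite df and report `min(1, m * p)` under an m-fold
Bonferroni correction; degenerate zero-variance comparisons with equal
means return t = 0, p = 1 rather than NaN.

## Image simulation and N/C quantification

Synthetic cells are concentric disks: a nucleus (radius 9 px) inside a
cytoplasm disk (radius 18 px), placed without overlap and away from the
border; DAPI shows the nucleus at 180 over background 8, the signal
channel shows the nucleus at `true_nc_ratio * cytoplasm_mean` inside a
cytoplasm at 50. Both channels are multiplied by a horizontal linear
illumination field spanning `1 ± gradient/2`, perturbed by Gaussian noise
(default 2.5 ≈ 5% of the cytoplasm level), clipped and quantized to 8 or
16 bits. Because disk and annulus are concentric, a linear illumination
field leaves the true ratio exactly unchanged, so the truth table yields
exact oracle ratios. The geometry is deliberately minimal: no touching
nuclei (no watershed needed), no 3-D stacks, no chromatic aberration.

Thresholding: Bernsen marks a pixel foreground when the local contrast
(max − min over a replicate-padded disk neighborhood) reaches
`contrast_min` (15) and the value exceeds the local mid-range; low-
contrast regions are assigned wholly by comparing the mid-range to
`midgray` (half the bit-depth maximum). The local-mean rule marks
foreground where the value exceeds the neighborhood mean minus an offset
`c`; integer images use exact integer sums so the rule is bit-
reproducible. Both use disk neighborhoods (square by flag) and default
radius 15, the reference defaults of the ImageJ-style auto-local-threshold
family.

The end-to-end pipeline (`quantify_image`) departs from those single-op
defaults in one geometry-driven way: its Bernsen radius (6) is chosen
smaller than the cytoplasmic rim width, because a neighborhood wider than
the rim lets a bright nucleus dominate every cytoplasm pixel's local
maximum and erase the cytoplasm from the mask. The signal mask is then
hole-filled *before* opening — whichever compartment is dimmer (nucleus at
ratios < 1, cytoplasm interior otherwise) reappears as an enclosed hole —
while the DAPI mask is opened *before* filling, since local-mean
thresholding marks roughly half of the flat noisy background and filling
first would fuse that speckle into one blob. All radii and thresholds are
arguments recorded in the output.

Per-cell measurement: nuclei are 8-connected DAPI-mask components
(border-touching nuclei excluded by default, as partial cells bias
means); each nucleus is associated with the signal component of largest
overlap; nuclear region = component ∩ nucleus, cytoplasmic region =
component minus nuclear region, so the two pixel counts sum exactly to
the component size. Regions under `min_px` (10) pixels give an undefined
ratio with a reason code instead of an unstable number.

## Problem sizes and numerics

The validation suite runs at sizes chosen to make the statistical checks
sharp but cheap: 2,000 cells for recovery (binomial noise on a recall
estimate at n≈400/phase is ~±1%), 1,000 cells/group for the depleted-
subpopulation comparison, 2,000 genes × 200 cells/group for null
calibration, four 384×384 images (48 cells) across true ratios 0.5–4 for
ratio recovery, and 32×32 images for the exhaustive threshold oracles.
Scaling any of these up changes only runtime, not the contracts tested.

Floating-point conventions: population (ddof 0) SD in z-scoring; Pearson
similarity computed on centered, norm-normalized vectors (a zero-norm
pattern gets similarity 0 and falls through to unclassified);
morphological erosion treats out-of-image pixels as foreground and
dilation as background so border structures behave as if the image
continued.

## Known limitations

- The G1 / unclassified boundary is an explicit interpretation
  (`tau_low`, `sim_min`, `delta_margin`); different cutoffs shift cells
  between G1, G1/S and unclassified, though the depleted-G1/S contrast is
  robust across reasonable settings.
- Pattern matching against idealized patterns is the default; cell-to-
  cell agglomeration, a plausible alternative reading of "comparing each
  pattern across all patterns", is not implemented.
- The marker simulation gives every phase equally strong, equally sized
  marker sets; real reference lists are unbalanced and noisier, so real-
  data recall will be lower than the synthetic figures.
- Touching nuclei are not split; the N/C pipeline assumes segmentable,
  separated cells.
- Library-size log-normalization stands where a variance-stabilizing
  regression could be used; the provenance field declares it, and any
  matrix normalized elsewhere can be supplied directly.
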