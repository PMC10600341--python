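# germcycle

Cell-cycle phase scoring for single-cell RNA-seq and nuclear/cytoplasmic
(N/C) fluorescence ratio quantification, with synthetic ground-truth
generators for both.

## The problem

When fetal mouse germ cells enter meiosis they pass through a pre-meiotic
G1/S transition. Whether that subpopulation is present in a mutant — for
example in germ cells carrying a STRA8 variant that cannot bind RB-family
pocket proteins — can be read out two ways:

1. **Transcriptomically**: score each cell of an scRNA-seq dataset against
   reference gene sets for five expression-defined cell-cycle phases
   (G1/S, S, G2, G2/M, M/G1) and compare the phase composition of control
   and mutant populations.
2. **Microscopically**: segment two-channel immunofluorescence images
   (DAPI + signal, e.g. STRA8) with local adaptive thresholds and measure
   each cell's ratio of mean nuclear to mean cytoplasmic signal intensity,
   which reports nuclear import of the protein.

`germcycle` implements both quantifications as a tested, reusable library
plus CLI, and ships generators that produce count matrices and images with
*known* phase composition and *known* N/C ratios, so every pipeline stage
can be validated end to end against ground truth.

## The method

**Cell-cycle scoring.** For cells with normalized log expression
`x(c, g)` and phase gene sets `G_k` (k = G1/S, S, G2, G2/M, M/G1):

- reference genes weakly correlated with their own phase score are
  excluded (Pearson `R < 0.2` by default);
- phase score `s_k(c) = mean_{g in G_k} x(c, g)`;
- scores are z-scored per phase across cells, then each cell's 5-vector is
  row-centered, giving a per-cell *pattern*;
- each pattern is matched (Pearson similarity) against idealized phase
  patterns. Cells matching G1/S or S with a clear margin keep those
  labels; cells best matching G2, G2/M, or M/G1 are collapsed into a
  single **G2/M/G1** category (post-S-phase expression programs blend
  across those stages); cells with uniformly low phase scores are called
  **G1**; the remainder is **unclassified**.

Group compositions are compared with a chi-square test of homogeneity;
per-gene comparisons use two-sided Wilcoxon rank-sum tests, replicate-level
fractions and per-cell ratios use two-sided Welch *t*-tests with optional
Bonferroni correction.

**N/C quantification.** The whole-signal mask comes from Bernsen's local
mid-range threshold, the nuclear mask from a local-mean threshold on DAPI,
each optionally refined by binary erosion/dilation/hole-filling. Per
nucleus (8-connected DAPI component), the nuclear signal region is the
signal mask intersected with the nucleus; the cytoplasmic region is the
rest of the cell's signal component; the N/C ratio is the quotient of the
two regions' mean intensities.

## Worked example

Simulate a control population with 20% true G1/S cells and a mutant with
2%, run QC, scoring and classification, and compare compositions:

```python
from germcycle import (SimDesign, simulate_counts, filter_cells,
                       lognormalize, score_and_assign, phase_proportions,
                       compare_proportions)

design = SimDesign(n_cells_per_group=1000, stratified=True, seed=7)
adata, sets = simulate_counts(design)
expr = lognormalize(filter_cells(adata))
labels = score_and_assign(expr, sets)
props = phase_proportions(labels["label"], expr.obs["group"])
print(props.filter(like="prop_").round(3))
print("chi2 = %.1f, df = %d, p = %.3g" % compare_proportions(props))
```

```
label    prop_G1  prop_G1/S  prop_S  prop_G2/M/G1  prop_unclassified
group
control      0.0       0.20   0.187         0.598              0.015
mutant       0.0       0.02   0.224         0.734              0.022
chi2 = 165.8, df = 3, p = 1.02e-35
```

The classifier recovers the planted compositions: the control's G1/S
fraction is estimated at 0.20, the mutant's at 0.02 (the depleted
subpopulation), true G2/G2-M/M-G1 cells are pooled into G2/M/G1, and the
homogeneity test rejects decisively.

The imaging arm, on a synthetic field whose true N/C ratio is 2.0, with
5% Gaussian noise and a 10% illumination gradient:

```python
from germcycle import ImageSpec, simulate_cell_image, quantify_image

spec = ImageSpec(true_nc_ratio=2.0, noise_sd=2.5,
                 illumination_gradient=0.1, seed=3)
image, truth = simulate_cell_image(spec)
rec = quantify_image(image).dropna(subset=["ratio"])
print(rec[["cell_id", "nuclear_mean", "cytoplasmic_mean", "ratio"]].head())
```

```
 cell_id  nuclear_mean  cytoplasmic_mean  ratio
       0        96.395            48.078  2.005
       4        97.727            48.794  2.003
       5       102.842            51.222  2.008
       9       101.304            50.660  2.000
      10        99.379            49.870  1.993
```

Every recovered per-cell ratio sits within 1% of the true value of 2.0
(median 1.999).

The same workflows are available from the shell:

```bash
germcycle simulate counts --config design.yaml --out sim/
germcycle qc --in sim/ --out qc/ --min-genes 200
germcycle cellcycle --expr qc/ --genesets sim/genesets.gmt --out cc/
germcycle ncr --image img.tif --out ncr/
germcycle run --config run.yaml --out run/     # full pipeline + manifest
```

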