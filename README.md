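# podmap

Joint dose–time modeling of transcriptomic responses and bronchoalveolar
lavage (BAL) immune-cell counts from dose-range, multi-time-point exposure
studies — the kind of design used for pulmonary hazard assessment of
engineered nanomaterials (several instilled doses, several sacrifice days,
vehicle controls per day).

Instead of treating each dose–time condition separately, `podmap` models each
gene's (and each BAL cell type's) response as a single surface over the joint
dose–time plane, then asks *where* on that plane a monotonic dose response
begins. That location — the **dynamic point of departure (dPOD)** — summarizes
both how sensitive a gene is (the dose at which it departs) and how early it
responds (the time at which it departs). Genes whose maps resemble the
activation map of an immune-cell count are candidate transcriptional
correlates of the inflammatory phenotype.

## Method

For each gene, sample-wise log2 fold changes are computed between every
treated sample and every vehicle control sacrificed on the same day. With
dose and time log10-transformed and min–max scaled to the unit square, two
nested models are fit by ordinary least squares:

- linear: `z = β₀ + β_d·d + β_t·t`
- quadratic: `z = β₀ + β_d·d + β_t·t + β_dd·d² + β_tt·t² + β_dt·d·t`

The candidate with the smaller overall F-test p-value (goodness of fit
against the intercept-only model) is kept; genes whose best p-value exceeds
0.05 are removed. The selected polynomial is evaluated on a 50×50 grid to
give the gene's **activation map** of predicted log2FC, interpolating between
the tested doses and times.

On each map, every time column is scanned along the dose axis: the maximal
strictly monotone run of dose bins ending at the top dose is located via the
finite-difference dose gradient, and the column's POD is the lowest dose bin
in that run whose |log2FC| reaches the activity threshold (linear fold change
1.5, i.e. |log2FC| ≥ 0.585), provided the top dose is itself above threshold.
The gene's dPOD is its earliest responsive column and that column's POD dose
bin; splitting both axes into thirds yields the 3×3 label grid —
*sensitive/intermediate/resilient* × *early/middle/late*.

BAL cell counts go through the same machinery after control normalization
`cc = log2((count_tr + ½)/(count_ctrl + ½))` over all treated×control animal
pairs per condition, with one difference: a cell type is never dropped — if
neither model passes the goodness-of-fit gate, the lower-AIC model is kept.

Gene and cell maps are compared by a region-weighted binary correlation: the
grid is partitioned into region A (both dose-dependent), B (exactly one) and
C (neither); each map is binarized against its regional mean; and the phi
coefficients are combined as `0.7·r_A + 0.2·r_B + 0.1·r_C` (weights
renormalized over defined regions). Pairs with |combined| > 0.6 are called
correlated.

A synthetic-data generator plants flat, time-only, monotone-dose and
non-monotone surfaces (plus overdispersed BAL count trends) in the canonical
18/54/162 µg × 1/3/28 day design, so every stage can be tested against known
ground truth. Cross-exposure summaries (DEG∩dPOD intersections, shared genes,
label-profile clustering, Fisher's combined p, GMT over-representation) live
in `podmap.summarize`.

## Worked example

```sh
podmap simulate --outdir demo/sim --seed 1
podmap run-all --expression demo/sim/expression.tsv \
               --annotation demo/sim/annotation.csv \
               --counts demo/sim/counts.csv \
               --out demo/results --seed 1
```

The first command writes a 200-gene × 60-sample study (45 treated, 15
control) with 50 planted monotone-dose genes, plus BAL counts for four cell
types. The second prints the stage tallies:

```
"foldchange":            200 genes, 45000 fold-change records, 76 DEGs (union)
"dosetime_fit":          200 fitted, 192 pass the goodness-of-fit gate
"pod_detection":         51 dynamic dose-dependent genes
"summarize":             76 DEGs vs 51 dPOD genes, intersection 50
"bal_dose_time":         4 cell types, 900 normalized records, 3 responsive
"gene_cell_correlation": 204 gene-cell pairs, 99 pass |r| > 0.6
```

51 of the 200 genes are called dynamic dose-dependent — all 50 planted
monotone-dose genes plus one false positive — and 50 of them are also
differentially expressed by the classical per-condition screen. The 3×3
label grid (`demo/results/gene_label_grid.csv`) concentrates in the *early*
column, as expected for responses planted to scale with dose from the first
day:

```
dose_section,early,middle,late
sensitive,15,1,0
intermediate,31,0,0
resilient,4,0,0
```

The per-cell summary shows the planted structure: the dose-trending
neutrophil and eosinophil maps correlate with ~96–98% of the responsive gene
maps, while the flat macrophage and the late, interaction-driven lymphocyte
map correlate with none:

```
cell_type    n_genes  n_passing  proportion_passing
eosinophil   51       49         0.96
lymphocyte   51       0          0.00
macrophage   51       0          0.00
neutrophil   51       50         0.98
```

Every constant above (0.58 DEG cut, 0.05 gates, 50 bins, 1.5 activity
threshold, 0.7/0.2/0.1 weights, 0.6 pass cut, pseudocount 0.5, 7 clusters)
lives in `PipelineConfig` and can be overridden from a YAML file or CLI
flags.

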