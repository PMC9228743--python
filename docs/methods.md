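# Methods

This note records the model, the conventions the implementation commits to
where the underlying procedure admits choices, what the synthetic data do and
do not emulate, and the known limitations.

## Coordinates

All fitting, map prediction and planted synthetic truth share one coordinate
convention: dose and time are log10-transformed and min–max scaled to [0, 1]
over the design range. The canonical designs are geometric (18/54/162 µg,
1/3/28 days), so the transformed levels sit near 0, ½, 1 — 54 µg maps to
exactly ½ because log(54/18)/log(162/18) = log3/log9. Whether to fit on raw
or transformed axes is a genuine free choice; the log/min–max convention is
declared once and applied everywhere, which is what matters for internal
consistency (planted class labels, detector output and grid arithmetic all
agree). Both 50-point grid axes are equally spaced in [0, 1] with endpoints
included: `grid_value[i] = (i−1)/49`.

## Fold changes and the DEG stand-in

Sample-wise log2 fold changes are differences of log2 expression between
every treated sample and every time-matched vehicle control (n·m records per
condition for n treated, m controls). All records enter the surface fit as
independent observations, with no pre-averaging of pairs.

The differential-expression screen is a deliberately plain stand-in for a
moderated linear-model analysis with batch covariates: a Welch two-sample
test per gene per condition, BH-adjusted across genes within each condition
(nine families in the canonical design), gated at |mean log2FC| > 0.58
(= log2 1.5) and adjusted p < 0.05. It exists so that DEG∩dPOD comparisons
can be made on synthetic data; it makes no claim to match a moderated fit on
real microarray data, and no probe handling, normalization or batch
correction is implemented.

## Surface fitting and model selection

Two nested OLS models are fit per entity: linear (3 terms) and the full
bivariate second-order polynomial (6 terms, interaction included — needed to
represent dose trends whose steepness changes with time). Goodness of fit is
the overall F-test p against the intercept-only model; AIC comes from the
Gaussian log-likelihood. The lower-p candidate is selected; ties go to the
simpler linear model. Genes whose best p exceeds `gof_alpha` (0.05) are
dropped; cell types instead fall back to the lower-AIC candidate (again ties
to linear) and are never dropped.

Degenerate cases are pinned down: a perfect fit (residual SS = 0) with
structure gets p = 0; all-constant data (model SS = 0 too) gets p = 1, so a
noise-free flat gene is always rejected by the gate. Fits require ≥ 7
observations spanning ≥ 2 doses and ≥ 2 times; rank-deficient designs raise
an error rather than returning garbage.

Two calibration facts are worth knowing, both measured by the test suite and
the acceptance script:

- With iid records, each candidate's F-test p is exactly uniform under the
  null (verified by Kolmogorov–Smirnov at 1000 simulations). But the *gate*
  operates on the minimum of two correlated p-values, so its null rejection
  rate is necessarily below the nominal 95% — about 91–92% in practice.
- On pairwise fold-change records the F-test is strongly anticonservative,
  because records sharing a treated or control sample are correlated (at the
  default design ~9 of 10 flat genes pass the gate). The practical
  specificity of dose-dependence calls comes from the downstream activity
  threshold: the measured false-positive rate of the full pipeline on the
  default panel is below 1%.

## Responsive-region detection and the dPOD

Per time column of the activation map, the finite-difference dose gradient
defines the maximal strictly monotone run (constant, nonzero sign) of dose
bins ending at the top dose. Conventions, each of which the brute-force
oracle in the tests checks directly:

- Zero gradient breaks a run: monotone means strictly monotone. A run must
  contain at least one gradient step (two bins) — otherwise any sufficiently
  high flat column would count as trivially "monotone".
- The run must end at the top dose, and the top-dose value must itself be
  above the activity threshold. A response that fades below threshold at the
  highest dose is not a monotone dose response in this sense; interior
  responsive islands are not marked.
- The column POD is the lowest dose bin within the run at or above the
  activity threshold (|log2FC| ≥ log2 1.5 by default, matching the DEG cut).
- Direction is the common gradient sign over responsive columns; when signs
  conflict, the majority wins and a mixed-direction flag is set.
- "Earliest, most sensitive" is resolved lexicographically: the earliest
  responsive time column first, then its POD dose bin.

Section labels split both normalized axes into thirds with lower-inclusive
boundaries (value < 1/3, < 2/3, else top third), giving
sensitive/intermediate/resilient × early/middle/late.

One behaviour follows from these conventions and is worth stating: a fitted
*linear* model has a spatially constant dose gradient, so any nonzero fitted
dose coefficient — including one that is pure noise — makes every column's
full dose range a monotone run. A strong purely time-dependent response can
therefore be flagged as dose-dependent under noise if its amplitude crosses
the activity threshold, even though at zero noise it never is (the gradient
is then exactly zero). The detector deliberately has no minimum-gradient
tuning knob; see the synthetic-data section for why such genes are expected
to be modest in fold-change space.

## BAL cell counts

Counts are normalized per condition as `log2((tr + pc)/(ctrl + pc))` over
all treated×control pairs, with pseudocount pc = 0.5 (half-count continuity
correction) because eosinophil counts are frequently zero and the ratio is
otherwise undefined. Cell maps use the gene activity threshold by default;
both are exposed in the config. No hypothesis testing on counts is done —
the cell pathway exists to produce activation maps and dPOD labels, not
ANOVA-style statistics.

## Gene–cell map correlation

Region A/B/C is the AND/XOR/NOR partition of the two dose-responsive masks.
Binarization is strictly "greater than the regional mean" (a value exactly at
the mean codes 0), in fixed row-major (dose-major) traversal. The phi
coefficient of two binary vectors is undefined when the region is empty or
either vector is constant; such regions are excluded and the 0.7/0.2/0.1
weights renormalized over the rest. Renormalization keeps the combined value
a correlation — identical maps score exactly 1 even when region B is empty —
and is the default; the alternative (undefined regions contribute zero,
weights kept) is available as `undefined_region_policy: zero`. If no region
is defined the pair has no correlation and never passes.

## Cross-exposure summaries

Shared-gene clustering encodes each (dose, time) label pair ordinally
(sensitive/early = 0 … resilient/late = 2), concatenates across exposures,
and clusters agglomeratively with Manhattan distance and complete linkage,
cut at k = 7 by default. The clusterer is written in-package so its
tie-break is defined (on equal merge heights the lexicographically first
cluster pair merges) and the partition is invariant to input order; it is
cross-checked against scipy on tie-free data. Fisher's method is the exact
chi-square tail of −2Σln p with 2k df; over-representation is the
hypergeometric upper tail against the universe of genes entering the
dose–time fit, BH-adjusted across sets.

## Synthetic data

The generator emulates: the factorial instillation design with time-matched
vehicle controls; genes as planted polynomial surfaces in the shared
normalized coordinates plus iid Gaussian log2 noise (default sd 0.2, a
typical residual scale for normalized microarray data); and BAL counts as a
baseline times 2^trend with multiplicative overdispersed integer noise.
Count noise is rounded-Gamma with coefficient of variation equal to the
dispersion parameter: overdispersed relative to Poisson at realistic
dispersions, and degenerating to the exact planted counts as dispersion → 0,
which is what makes zero-noise ground-truth tests possible (a Poisson-mixture
family cannot do this — its variance never falls below the mean).

Default panel (200 genes): 25 linear-dose and 25 saturating-quadratic genes
with top-dose amplitudes |log2FC| ∈ [1.0, 2.5] (clear responders), 100 flat
genes, 25 non-monotone genes rising to a mid-dose peak of [0.8, 1.5] and
returning to baseline at the top dose, and 25 time-only genes with modest
amplitude |log2FC| ∈ [0.2, 0.5]. The time-only amplitude is deliberately
small: fold changes are taken against same-day vehicle controls, which
cancels kinetics shared by treated and control animals, so purely
time-dependent *fold-change* drift reflects residual artifacts rather than
exposure response and is expected to be well below the amplitude of genuine
dose responders. The four default cell trends (dose-surging neutrophils,
dose×time eosinophils, flat macrophages, slow interaction-driven
lymphocytes) caricature the BAL profile of insoluble-particle instillation.

What the generator does not emulate — and hence what passing tests do not
establish about real data: probe-level microarray structure, batch and
surrogate-variable effects, correlated noise across genes, heavy-tailed or
heteroscedastic residuals, animal-level random effects shared across the
four cell counts, and real biological coupling between transcription and
cell influx (the planted gene and cell surfaces are independent unless a
test constructs them otherwise).

## Problem sizes and determinism

Default analyses run at 200 genes × 60 samples (45 000 fold-change records),
1000-gene null-calibration simulations and 100-surface oracle comparisons;
the full pipeline completes in seconds on one core. All randomness flows
from explicit seeds through `numpy.random.default_rng`; reruns with the same
seed and config are byte-identical, which the acceptance script verifies by
comparing two complete runs.

## Known limitations

- The DEG screen is not a moderated-statistics analysis; on real microarray
  data its p-values will be noisier than a moderated fit's.
- The goodness-of-fit gate is miscalibrated in both directions described
  above; its thresholds should be read as operational, not as type-I error
  rates.
- Only linear and full second-order surfaces are considered; responses with
  sharper-than-quadratic saturation are approximated, not captured.
- The dPOD is a grid construct on the fitted surface, not a benchmark-dose
  estimate in the BMDS sense; no confidence interval accompanies it.
- Correlation pass calls use the fixed |r| > 0.6 cut; no significance or
  multiplicity correction is attached to them.
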