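# Methods

## Quantification model

A TaqMan well reports the cycle threshold `Ct`, the cycle at which
fluorescence crosses a fixed threshold; under perfect doubling, expression is
proportional to `2^−Ct`. We quantify each gene relative to the mean of a
15-gene housekeeping panel:

* **Reference.** Per sample, the arithmetic mean Ct of the detected
  housekeeping genes. Arithmetic mean on the Ct scale equals the geometric
  mean in linear-expression space, the standard choice for multi-gene
  references. A sample must have at least 8 of the 15 housekeeping genes
  detected; fewer leaves the reference unstable and the sample is rejected
  rather than silently normalized.
* **Relative expression.** `r = 100 · 2^−(Ct_gene − Ct_ref)` percent of the
  housekeeping mean. Amplification efficiency is fixed at 2.0; no
  standard-curve correction is attempted. `r` is shift-invariant (adding a
  constant to every Ct, housekeeping included, changes nothing), which makes
  the scheme robust to global offsets such as threshold placement.
* **Undetermined wells.** Held at the instrument ceiling Ct = 40 so every
  well yields a finite `r` (a conservative lower bound on expression). The
  undetermined mask is carried alongside: a gene undetermined in **every**
  replicate of a condition is reported Absent outright, so the sentinel never
  manufactures a Trace call.
* **Replicates.** `r` is computed per replicate and averaged on the linear
  scale, then the class is assigned to the mean — matching how array
  experiments report "average mRNA expression" across independent runs.

## Stratification

Three strata on the percentage scale, boundaries inclusive upward (a value
exactly at a threshold joins the higher class, resolving the overlap between
"> 0.1 %" and "0.01–0.1 %" in the usual verbal definitions):

* Expressed: `r ≥ 0.1 %`
* Trace: `0.01 % ≤ r < 0.1 %`
* Absent: `r < 0.01 %` or never determined

Percentages are primary; Ct cutoffs are derived. With a housekeeping mean of
Ct 20, `ct_class_boundaries` gives 29.97 and 33.29 — the familiar
whole-cycle "Ct 30 / Ct 33" rules of thumb.

Category summaries count every panel gene exactly once (never-assayed genes
are Absent), so Expressed + Trace + Absent always equals the panel size —a
conservation law the tests enforce on every synthetic run.

## Panel resources

The bundled manifests define the gene universes: 352 mouse non-visual GPCRs
(the array panel) plus the 15 housekeeping genes, and a 356-gene human
counterpart. The mouse and human panels are linked by explicit per-record
ortholog symbols — by default the case convention (mouse `Adgrf5` ↔ human
`ADGRF5`), with exceptions stored in the manifest (e.g. `Agtr1a` ↔ `AGTR1`)
and species-specific receptors (mouse `Mrgprb3`, human `MCHR2`, …) left
unmapped and reported rather than dropped. The manifests are replaceable TSV
resources; no pipeline logic hard-codes their contents.

## Cross-condition comparison

"Detected" means Expressed ∪ Trace. Venn partitions assign each gene of the
union to the unique region given by its membership pattern (regions are
disjoint and cover the union — a property test). Exclusive lists are the
two-set special case. Rankings:

* *top-N expressed*: detected genes by `r` descending;
* *top-N enriched*: genes detected in both conditions by the ratio
  `r_a / r_b`, both floored at the trace threshold (0.01 %) so a ratio against
  a barely-detected gene stays bounded (max 10,000-fold against the floor).
  A ratio was chosen over a difference because the published "enriched"
  rankings are not defined numerically and a ratio is the scale-free choice.

Ties break alphabetically everywhere, making every output deterministic.

## Differential statistics

* **qPCR fold change** (ΔΔCt): `log2FC = mean ΔCt_ref − mean ΔCt_cond`; one
  cycle is one log2 unit, positive means up in the condition of interest.
  Genes undetected in one condition enter with the sentinel ΔCt, bounding the
  fold change instead of dropping the gene.
* **RNA-seq fold change**: `log2((mean CPM_cond + ε)/(mean CPM_ref + ε))`
  with pseudocount ε = 1 CPM. Tests run on per-sample `log2(CPM + 1)`;
  fold changes use linear mean CPM. The pseudocount mildly shrinks large
  fold changes of low-expressed genes — visible as attenuation when mean CPM
  is within an order of magnitude of ε.
* **Test**: two-tailed Student t with pooled variance (Welch behind
  `equal_var=False`). Degenerate variance is flagged, not dropped: both
  groups constant and equal gives t = 0, p = 1; constant but different gives
  the smallest representable p with a `degenerate` flag.
* **Multiplicity**: Benjamini–Hochberg step-up within each contrast
  (per volcano panel), not globally across contrasts. The published methods
  text says adjusted p values "higher than 0.05" were considered significant;
  this is read as a typo for "lower than" and implemented accordingly.
* **Significance rules** per contrast family: raw-p volcano rule
  `−log10(p) > 1.3` for differentiation time-course contrasts (this admits
  p = 0.05 itself, as the published plots do), FDR < 0.05 for the human
  obesity contrasts, FDR < 0.01 for the mouse high-fat-diet contrast.

## RNA-seq branch

Counts are CPM-normalized per sample (`counts · 10⁶ / column sum`; columns of
the result sum to 10⁶ exactly up to float tolerance, and classification is
invariant to scaling any sample's library). The matrix is then restricted to
the panel, case-insensitively, with zero rows for panel genes missing from
the matrix (reported). Stratification transports the qPCR scheme to CPM
space: `r = 100 · meanCPM(gene) / mean over housekeeping genes of their mean
CPM`, same thresholds — one definition of Expressed/Trace/Absent across
platforms, using the same 15 reference genes.

## Synthetic experiments

The generators create data with known truth so every stage is testable
offline; they emulate the statistical structure of the two designs, not any
particular deposited dataset.

* **qPCR**: each receptor gene gets a class (default proportions
  0.60/0.15/0.25 Expressed/Trace/Absent, the rough split seen in adipose
  depots) and a mean Ct uniform inside its class band, keeping a 2σ margin
  from the band boundaries so recovery is a property of the pipeline rather
  than of boundary luck. Replicate noise is normal on the Ct scale with
  σ = 0.2 cycles by default — typical TaqMan replicate variation. Absent
  genes are emitted as undetermined wells with probability 0.5, otherwise
  with a Ct beyond the absent boundary. Housekeeping genes sit near Ct 20,
  the value that reproduces the Ct 30/33 cutoffs.
* **RNA-seq**: negative-binomial counts with `var = μ + φμ²` (default
  μ = 100, φ = 0.05), planted log2 fold changes multiplying the mean in
  non-reference groups, groups of ≥ 2 samples. Housekeeping genes get high
  means (20,000) with their own small dispersion (0.005): they are stable by
  definition, and because they dominate the small synthetic library, giving
  them receptor-level dispersion would inject correlated library-size noise
  into every CPM and bias fold-change estimates by up to ~0.1 log2 units.
* **Scoring**: `truth_report` gives class-recovery accuracy (qPCR) or
  fold-change bias/RMSE, direction recovery, sensitivity and specificity
  (RNA-seq).

What passing these simulations does **not** show: robustness to batch or
plate effects, probe-efficiency variation, outlier samples, non-NB count
behavior (zero inflation, length/GC bias), or the cell-composition shifts of
real adipose tissue — none of which the generators model.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own scales: the 352-gene
panel with 2–3 replicates for qPCR; 10 + 10 samples, 40 planted genes for
the count simulation; 2000 genes for null calibration of the t-test. All
complete in seconds. Randomness flows from a single integer seed through
`numpy.random.default_rng`; same seed, same bytes. Fold-change and p-value
columns are written at 6 significant digits; comparisons in tests use
absolute/relative tolerances stated per test, with the BH step checked
exhaustively against a brute-force step-up implementation for vectors up to
length 12.

## Known limitations

* The bundled panels are a reconstruction of the commercial array's gene
  list, which is not public; counts computed on real data with these
  manifests can differ by a few genes from published tallies.
* No moderated-variance (empirical-Bayes) estimator; with 2–3 replicates the
  per-gene t-test is noisy, which is faithful to the original analysis but
  not state of the art.
* No multi-plate batch correction or melt-curve QC on the qPCR side; no
  alignment/quantification on the RNA-seq side (the input is a count
  matrix).
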