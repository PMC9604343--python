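# Methods

## Model and procedure

`corrshift` analyzes a dense genes × samples abundance matrix (FPKM-like,
non-negative, unitless) split into a control and a cancer group. The
pipeline runs four stages in order; each is available as a standalone
function and the whole chain as `run_pipeline` / `run_all`.

### Differential expression

Per gene, the effect size is

    log2FC = log2((mean_cancer + c) / (mean_control + c)),   c = pseudocount

on the raw abundance scale, and significance is a two-sided Welch
(unequal-variance) two-sample t-test on `log2(x + c)`. Working on the log
scale makes the test statistic approximately location-scale well-behaved for
skewed abundance data; Welch's correction avoids assuming equal variances
between a 41-sample and a 471-sample group. This is a deliberately simple,
fully specified test — the package does not attempt to reproduce any
particular external DEG tool's internal normalization or sampling model.

Calls use `|log2FC| ≥ fc_cutoff` (boundary **inclusive**) and
`p < p_cutoff` (boundary **strict**). Defaults: `fc_cutoff = 2.50`,
`p_cutoff = 0.001`, `pseudocount = 1.0`, top-N lists of 20 ranked by
`|log2FC|` with alphabetical tie-break. No multiple-testing correction is
applied by default (the cutoffs are on raw p-values); Benjamini–Hochberg is
available behind `bh_correct=True`.

Degenerate inputs: a gene constant and equal in both groups gets `p = 1`; a
gene constant in both groups at *different* levels gets `p = 0` (the
difference is detected with certainty under the zero-variance model).

### Pathway overrepresentation

One-sided hypergeometric upper tail (Fisher-exact enrichment): with a
universe of `N` genes, `K` of them in the pathway, and `n` DEGs, the p-value
for an observed overlap `k` is `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`
(computed via `scipy.stats.hypergeom.sf`). The default universe is the
intersection of matrix genes with the union of all supplied pathway sets, so
genes that could never be drawn do not inflate significance; `universe=
"matrix"` switches to all measured genes. Pathways are ranked by ascending
p, ties broken by larger overlap then name, truncated to `top_pathways`
(default 10).

### Differential correlation (ΔCC)

For each retained pathway, the gene subset is `pathway ∩ DEGs ∩ matrix`
(lexically sorted; pathways with < 2 such genes are skipped with a warning).
Pearson product-moment correlation matrices are computed per group over that
subset — by default on **raw** abundances; `corr_space="log2"` correlates
`log2(x + c)` instead (raw-space Pearson is sensitive to high-abundance
outliers; both spaces are recorded in the run metadata). Spearman is
available via `correlation="spearman"` (Pearson on per-gene ranks, average
ties).

`ΔCC = CC_cancer − CC_control` elementwise, so `ΔCC ∈ [−2, 2]`. Pairs with
`|ΔCC| ≥ delta_cc_cutoff` (default 0.70, inclusive) are selected, each
record carrying its signed per-group coefficients and source pathway. Pairs
involving a gene with zero variance in either group are masked invalid and
reported in `diagnostics.tsv` rather than silently dropped (all-zero genes
in a small control group are common in FPKM matrices). Each group needs at
least 3 samples for a correlation to be computed at all.

### Panel assembly

Shifted pairs are deduplicated across pathways by unordered gene pair,
merging pathway provenance. If duplicate records disagree on ΔCC (possible
when masking differs between pathway contexts), the maximum-|ΔCC| record is
kept and the range logged — a conservative, reproducible tie-break. The
panel is the exact set union of top-up, top-down, and pair genes; each gene
appears once with merged source tags, its fold-change estimate, and its
surviving pair evidence, sorted by (source count desc, |log2FC| desc,
symbol). An overlap between the top-up and top-down lists is impossible
under valid calls and raises.

### Visualization

Per pathway, side-by-side control/cancer heatmaps with a diverging colormap
fixed to [−1, +1] (blue positive, red negative, gray masked), gene labels on
both axes, written as SVG and PNG. The fixed scale keeps the two panels
directly comparable.

## Synthetic cohorts

The generator draws, per group, log2-scale expression from a multivariate
normal: mean = `baseline_log2_mean` (+ per-gene `baseline_offsets`)
(+ planted δ, cancer group only), standard deviation `noise_sd`, correlation
= identity except for planted gene-pair blocks with group-specific ρ.
Abundances are `max(2**z − pseudocount, 0)`. Because both groups share the
same log-normal variance, the planted δ is recovered *exactly in
expectation* by the pipeline's fold-change estimator, and the zero-floor is
only reached when a group's log2 mean approaches 0 — which the benchmark
avoids by giving strongly downregulated genes a higher baseline (a gene that
falls 8 log2 units must have been highly expressed to begin with).

Correlations are planted on the log2 scale (a copula-style construction that
guarantees a valid covariance and non-negative abundances). The raw-space
Pearson coefficient is therefore slightly attenuated relative to ρ — about
0.01 at the benchmark noise level, ~0.013 at `noise_sd = 0.5` — which the
±0.05 large-n recovery tolerance absorbs. Planted blocks must be disjoint;
overlapping blocks are rejected naming the offending gene, keeping ground
truth unambiguous. All randomness derives from a single seed through
deterministic substreams; identical configs reproduce byte-identical files.

### The benchmark cohort (`make_paper_shaped_fixture`)

41 controls / 471 cancers (a realistic tumor-heavy cohort imbalance), 2000
genes, ten pathway sets named and sized after the ten most-perturbed KEGG
pathways in colon adenocarcinoma (275, 126, 258, 329, 72, 140, 144, 73, 67,
135 genes). Planted truth:

* 22 gene pairs distributed round-robin across the pathways: 12 "full-swing"
  pairs (ρ_control = 0.8, ρ_cancer = −0.2, Δρ = −1.0), 2 borderline pairs
  (0.9 → 0.15, Δρ = −0.75), and 8 no-effect pairs (0.5 → 0.5) used to
  measure selection specificity. Pair genes are themselves planted DEGs
  (δ = ±3.0) so they enter the per-pathway DEG subset.
* 20 further standalone DEGs with |δ| uniform in [2.6, 10], alternating
  sign, embedded in the pathways.
* Baseline log2 mean 5.0 (FPKM ≈ 32); `noise_sd = 0.3`. The noise level is
  an a-priori error budget: the fold-change standard error at n = 41 is
  ≈ `noise_sd/(√41·ln 2·…) ≈ 0.05` log2 units, so ±0.2 recovery holds for
  all 64 planted genes simultaneously with wide margin, while the cutoffs
  (2.5 log2 units, |ΔCC| 0.7) sit tens of standard errors away from any
  null gene or pair.

### What the generator does and does not emulate

It reproduces the two-group design, FPKM-like non-negative skewed values
with zeros, group mean shifts, and group-specific pair correlations — the
statistical structure the pipeline consumes. It does **not** emulate
library-size or gene-length artifacts, batch effects, outlier samples,
heavy-tailed biological variance, correlated *blocks* larger than pairs, or
tumor heterogeneity/purity gradients. Passing tests therefore demonstrate
that the pipeline's statistics are implemented correctly and are well
calibrated under the generative model — not that the thresholds are optimal
for any particular real cohort.

## Numerical choices

* Correlation entries are clipped to [−1, 1] and the diagonal set to exactly
  1 where defined, so boundary tests are exact.
* Matrix TSVs are written with Python's shortest-round-trip float repr and
  read back through strtod, so write-then-read is bit-exact and reruns are
  byte-identical.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, validated in
  the test suite against exhaustive enumeration for universes ≤ 12.
* All orderings (rankings, pair lists, panel) have total, documented
  tie-breaks, making every output deterministic.

## Problem sizes used in verification

Unit and property tests run on hand-sized fixtures (≤ 50 genes). The
planted-recovery suite runs the full benchmark cohort (2000 × 512) once for
fold-change recovery and 100 replicate cohorts for pair-selection rates;
null calibration uses 1000 null genes at 41/471 samples. These sizes give
binomial standard errors of ~1–2% on the measured rates.

## Known limitations

* The DEG test is a Welch t-test on log2(FPKM+1); it is well calibrated
  under the generative model but is not a count-model test (no dispersion
  shrinkage), and FPKM input precludes count-based inference entirely.
* Raw-space Pearson (the default correlation) is outlier-sensitive; the
  log2 space flag is the robust alternative and the choice is recorded in
  `run_summary.json`.
* ΔCC thresholding is a point estimate rule — no significance test or
  Fisher z confidence interval is attached to individual pair shifts; with
  41 controls the control-side correlation carries sampling error ≈ 0.12
  for weakly correlated pairs.
* Gene identifiers are matched as case-sensitive symbols; no alias or
  transcript-to-gene mapping is performed.
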