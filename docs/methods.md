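# Methods

## Model and assumptions

The package ranks TF-bound genes by fusing two independent rank sources.

**Compendium standardization.** Input is an already-normalized
probeset×sample or gene×sample matrix (normalization of raw arrays, e.g.
fRMA, is upstream and out of scope). For genes with multiple probesets only
the probeset with the largest pre-standardization sample variance is kept
(ties broken by lexicographically smallest probeset id, for determinism).
Each gene row is then standardized to zero mean and unit standard
deviation; variances use the sample convention (denominator n−1)
throughout. Constant genes are retained as all-zero rows with a
`zero_variance` flag rather than dropped, keeping the gene universe stable;
the correlation layer marks them invalid. The coefficient of variation for
a zero-mean gene is recorded as +inf (written as `inf` in the sidecar).

**Truncated absolute correlation.** For cutoff c (standardized units,
−∞ allowed), C = {i : x_ti ≥ c} and r_tg is the Pearson correlation of TF
and gene restricted to C, using within-C means; a_tg = |r_tg|. The cutoff
is applied to the standardized TF row, so c = 0 means "TF above its own
average". A result is invalid when |C| < `min_samples` (default 3 — Pearson
is not meaningful below that, configurable) or when either variable is
constant within C; invalid results propagate as missing rather than as
errors, and downstream ranking places them last. The z-score diagnostic
standardizes a gene's r_tg against the null formed by the TF's truncated
correlations with every valid compendium gene (the TF itself included; its
self-correlation of 1 is negligible at compendium scale), with the sample
standard deviation; it errors on nulls smaller than 10 genes or with zero
spread.

**TF expression diagnostics.** The TF's pre-standardization mean, variance
and CV are located within the all-gene empirical distributions (fraction of
genes strictly below). Below the 5th percentile ⇒ `strong` warning, below
the 25th ⇒ `mild`, else `none`; the same two-tier rule is applied to all
three statistics.

**Peak-to-gene assignment.** A gene is bound when a ranked peak falls in
the strand-oriented window 10 kb upstream to 5 kb downstream of any of its
TSS records, both endpoints inclusive ("within 10 kb" read as ≤ 10,000 bp).
The default test is the peak midpoint (floor of (start+end)/2) inside the
window — the stricter, caller-agnostic reading — with an `overlap` mode
(≥ 1 bp) available for wide ChIP-chip regions. Each bound gene takes the
best (minimum) rank among its assigned peaks; genes sort by that rank, ties
by gene_id, giving P ∈ {1..G}. Coordinates are 0-based half-open (BED);
BED6 gene bodies yield TSS = start on `+` and end−1 on `−`. Peak ranks come
from descending score when every line carries a parseable score, else from
file order.

**Rank fusion.** Bound genes absent from the compendium are reported as
unranked; the remaining G′ genes have P re-ranked to 1..G′ preserving
order, so P and A share one scale (mixing 1..G with 1..G′ scales would
silently reweight w). A is assigned by a descending with ties broken by
smaller P then gene_id; invalid correlations take the worst A ranks,
ordered by gene_id. R = w·P + (1−w)·A is sorted ascending with the same
tie-break. The TF itself, if bound, stays in the ranking (its a = 1); the
CLI offers `--exclude-tf`. Defaults c = 0, w = 0.1.

**Evaluation.** Gold standard = bound ∩ differentially expressed (the DE
calling itself is out of scope; gene sets arrive as files). PPV(k) counts
gold genes among exactly the top k; nAUC(n) = mean PPV over k = 1..n. The
comparison harness scores ChIP-only, correlation-only and fused rankings
against the same gold standard; the correlation-only baseline is reported
both restricted to the shared evaluable universe (bound genes present in
the compendium — the fair comparison) and unrestricted over all compendium
genes (its native definition). Both views are labeled in the output.

## Synthetic generator

The generator emulates the situation the truncated correlation was designed
for, at benchmark scale (defaults): 1,000 samples, 2,000 genes plus a TF
row, 100 functional targets among 500 bound genes.

* **TF expression** is Exponential(1): right-skewed and unimodal, i.e. a
  background floor in most samples with a long expressed tail, as for a
  tissue-restricted regulator on a log-intensity scale. The TF is "on" in
  the top `tf_on_frac` (default 0.5) of samples.
* **Functional targets** follow the TF dose only in on-samples, with
  per-target amplitude `coupling`·Uniform(0.1, 1) (real targets span a wide
  range of effect sizes; a shared effect size would make the correlation
  ranking artificially clean) and sign flipped for a `frac_repressed`
  fraction (default 0.3), exercising the absolute-value step. In
  off-samples each target is, with per-sample probability `alt_reg_prob`
  (default 0.7), driven by an independent alternative regulator, else
  baseline Gaussian noise.
* **Bystander genes** (`bystander_frac` = 0.3 of non-functional genes) are
  elevated exactly where the TF's context is active, with amplitude drawn
  like the targets' and a partial within-context dose coupling
  (`coregulation` = 0.5) from shared upstream programs. They reproduce the
  classic confounder of correlation-only rankings: strong global
  correlation with the TF without being its targets. Truncation removes
  their context component but, realistically, not the co-regulated part —
  which is exactly the ambiguity that binding evidence resolves.
* **Binding** assigns each bound gene (all functional targets plus random
  noise genes) a latent strength 1{functional} + Normal(0, `binding_noise`,
  default 1.0 — signal-to-noise of one, a moderately informative peak
  list). Peaks are placed at each bound gene's TSS on a synthetic genome
  with 100 kb gene spacing, scored so that peak-to-gene assignment recovers
  the intended bound order exactly; the gold standard is the planted
  functional set.

One integer seed drives all stages through a single generator
(`simulate_scenario`); noise is Gaussian since standardization makes the
method scale-free. The generator does **not** emulate probe-level effects,
batch structure, correlated noise among noise genes, multiple TFs, or
genes missing from the compendium — so passing benchmarks show that the
method ranks planted context-dependent targets above confounders under
heterogeneous effect sizes, not that it meets any particular accuracy on
real arrays.

## Numerical choices

* Batch correlations are computed by centered matrix products and clipped
  to [−1, 1] against rounding; constancy within C is detected exactly
  (zero peak-to-peak), not by tolerance.
* Standardization is idempotent to ~1e−15 (tested at 1e−9); text I/O writes
  floats with full repr precision and reads them back with round-trip
  parsing, so write∘read is exact to < 1e−12.
* All orderings are total and deterministic: every sort carries an explicit
  tie-break ending in gene_id.
* `nauc` requires n ≤ ranking length; the comparison harness clamps the
  horizon to the ranking length for short universes.

## Problem sizes in the test suite

The oracle suites use 200 random compendia (≤ 60 genes × ≤ 40 samples) for
the correlation and 100 random instances (≤ 200 peaks, ≤ 100 genes) for the
peak assignment; the benchmark recovery test runs the default scenario for
50 seeds and requires the fused ranking's mean nAUC(100) to exceed both
baselines by more than twice the Monte-Carlo standard error of the paired
difference, and the truncated correlation-only mean to exceed the
untruncated one. These sizes give stable Monte-Carlo margins while keeping
the whole suite around fifteen seconds.

## Known limitations

* The re-ranking of P to 1..G′ after removing compendium-absent genes is a
  deliberate design choice so P and A share a scale; pipelines that keep
  the original 1..G scale will weight w slightly differently.
* Peak "within" semantics (midpoint vs. summit vs. any overlap) differ
  across callers; both provided modes are approximations of upstream
  summit-based definitions.
* The two-tier diagnostic rule applies the same 5%/25% thresholds to mean,
  variance and CV; with heavy-tailed CV distributions the CV flag is the
  least specific of the three.
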