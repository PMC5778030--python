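# Methods

## The problem

Functional-annotation databases (Gene Ontology annotations, pathway
databases, drug-target tables, publication indexes) do not cover the genome
evenly: a small set of genes carries most of the annotations while
thousands of protein-coding genes remain nearly blank.  When researchers
interpret omics experiments through these databases, the unevenness feeds
back into which genes get studied next — a "streetlight" bias.  This
package measures that unevenness, models how it grows across database
releases, and tests whether the literature's attention to disease genes
tracks molecular evidence or annotation richness.

## Inequality metrics

All metrics operate on the per-gene annotation counts `x_1..x_n` of the
genes with at least one annotation in one release of one source.  Absence
of a gene from a count table means "no annotation"; zero counts are never
materialised, so `n` is always the annotated-gene count.

The Gini coefficient is computed as

    G = sum_i sum_j |x_i - x_j| / (2 n sum_i x_i),

implemented through the equivalent sorted form
`G = sum_i (2i - n - 1) x_(i) / (n^2 mu)` (O(n log n)); the test suite
checks the two forms against each other to 1e-12.  `G = 0` for equal
counts, and a single annotated gene is defined as `G = 0`.  Seven
companion metrics follow the classical econometric definitions: the
Ricci–Schutz (Pietra) coefficient `sum|x_i - mu| / (2 n mu)`; Atkinson's
index with inequality aversion `epsilon` (default 0.5); Kolm's absolute
index with parameter `kappa` (default 1), computed through log-mean-exp
for overflow safety; Theil's entropy `mean(s log s)` with `s = x/mu`; the
coefficient of variation with the population (divide-by-n) standard
deviation, and its square; and generalized entropy GE(alpha) (default
alpha 0.5, with alpha = 0 the mean-log-deviation and alpha = 1 Theil).
The parameter defaults are the conventional ones in the inequality
literature and are all overridable.  All eight are zero on equal counts
and nonnegative; only the Gini and the relative measures are
scale-invariant, which is why the Gini is the headline statistic.

## Bootstrap confidence intervals

Uncertainty is quantified by resampling annotation *records*: the
`N = round(total)` annotations of a table are thrown back onto genes with
probability proportional to their counts (a multinomial draw), B = 1000
times by default, and the metric is recomputed per replicate on the
positive resampled counts.  Record-level resampling keeps the sampling
unit the same as the thing being counted; gene-level resampling would
change the annotated-gene count `n` itself.

Multinomial resampling adds Poisson-like dispersion to every gene's count.
At per-gene mean counts typical of annotation data (3–30), that extra
dispersion shifts the replicate inequality statistics upward relative to
the point estimate, so a raw percentile interval sits systematically above
the point value.  The default interval is therefore the bias-corrected
percentile interval: the percentile bounds minus the bootstrap bias
estimate `mean(theta*) - theta_hat`, clipped at zero (all eight metrics are
nonnegative).  The raw percentile interval remains available via
`ci_method="percentile"`.  A degenerate single-gene table yields the exact
interval [0, 0] under either method.  Fractional (simulated) totals are
rounded to an integer record count with a logged notice.

## GAF handling and curation filters

GAF 1.0 (15 columns) and 2.x (17 columns) are both read; the dialect is
taken from the `!gaf-version` header when present, otherwise from the
per-line column count.  Malformed lines are counted and skipped, never
fatal; a stream with zero parseable lines is an error.  Default filters:
evidence codes IEA, ND and NR are excluded (uncurated or placeholder
evidence), and only the biological-process and molecular-function
namespaces are kept (the two that describe gene function).  Records
identical in (gene, term, namespace, qualifier) are counted once, so the
same assertion supported by several evidence codes — or re-curated with a
new reference or date — contributes a single annotation; a strict
full-record key is available.  Records with a NOT qualifier are kept by
default (dropping them is a switch); their number is logged either way.
Gene identity is the DB Object Symbol column matched case-sensitively
against a user-supplied gene universe; no synonym resolution is attempted,
because any mapping table would itself be a curation choice.

## Growth models

A release series contributes only two things to the simulation: the
baseline (first release) counts and the sequence of release totals.  Each
release adds `delta_j = max(0, n_j - n_{j-1})` annotations (shrinking
releases add nothing), distributed over the baseline genes by one of seven
weight models applied to the baseline annotation shares
`p0_i = x_i / sum x`:

| model                | raw weight                           |
|----------------------|--------------------------------------|
| exp_initial          | exp(p0_i)                            |
| cubic_initial        | p0_i^3                               |
| squared_weight       | (previous round's probability_i)^2   |
| squared_initial      | p0_i^2                               |
| initial              | p0_i                                 |
| initial_random_focus | p0 values permuted anew each release |
| equal                | 1 for every baseline gene            |

Raw weights are normalised to a probability simplex each step — the
formulas above are unnormalised, and normalisation is what makes
"distribute `delta` new annotations" conserve the release total.  The
deterministic update `counts += delta * p` is the default (it is the exact
expectation); multinomial sampling of `round(delta)` draws is available for
uncertainty bands and converges to the deterministic update as `delta`
grows.  The random-focus model redraws an independent permutation per
release from a (seed, version)-indexed substream, so simulating release j
does not depend on how many earlier releases were simulated.

Two models have exact closed-form behaviour used as test oracles: `initial`
scales all counts uniformly, so its Gini trajectory is exactly constant;
`equal` adds a constant to every baseline gene, which strictly lowers a
positive Gini.  Note that `exp_initial` is nearly uniform when individual
shares are small (exp(p0) ≈ 1 + p0), so in large gene sets it behaves like
mildly perturbed equal growth rather than strongly concentrating growth;
it is retained as specified but excluded from self-recovery checks, since
its trajectory is practically indistinguishable from `equal`'s.

Candidate models are ranked against the observed Gini trajectory by the
root-mean-square difference over versions 1..V (the baseline point is
shared by construction).  `AnnotationGrowthModel(series).fit()` wraps
simulation plus ranking and returns a results object with the ranking
table, per-model trajectories and a `summary()` frame.

## Disease-gene concordance

The association table has one row per (disease, gene) with the number of
supporting publications, the Hedges' g expression effect size and its FDR
from multi-cohort meta-analysis, the gene's non-IEA GO annotation count,
and optionally a best SNP p-value.  Genes are ranked within disease by
ascending FDR with average ranks for ties.  Only associations with at
least 10 publications enter the analyses (the cutoff limits false-positive
literature associations).  Concordance is Spearman's rank correlation on
pairwise-complete observations, with the large-sample t approximation for
the p-value by default and a seeded permutation option for small n.  The
replicated fraction is the share of (publication-filtered) associations
with `effect_fdr < 0.05`, strict by default with the boundary value
excluded (switchable to inclusive).  A top-k-by-rank export (default
10,000 per disease) exists for plotting only and is never used in
correlations.

## Synthetic data

`gen_goa_series` emulates the human GO annotation archive.  Defaults:
10,000 genes with baseline counts from a lognormal with sigma = 0.45 and
mean count 3.34 — a lognormal's Gini is `2*Phi(sigma/sqrt 2) - 1`, so this
baseline has Gini 0.25 and a total of ~33k annotations over ~10k genes,
the scale of the earliest archived release; 17 releases; 9,563 annotations
added per release, carrying the total to ~185k, the scale of the 2017
release; growth biased as the squared initial weight (the regime observed
trajectories match), stochastic by default.  Zipf and uniform baselines
are available.  The generator reuses the growth module's own `step`, so a
deterministically generated series is recovered exactly (distance 0) by
the matching candidate model.

`gen_goa_file` renders an integer count table as a syntactically valid
GAF 2.2 file whose parse → filter → dedupe → count round trip reproduces
the table exactly (distinct GO term per annotation, evidence codes from
the curated set, aspects in {P, F}).  It makes no attempt at realistic GO
accessions, ontology structure or annotation obsolescence.

`gen_assoc_table` couples publication counts (negative binomial, size 0.3,
mean 12 — heavy-tailed, with a minority of associations above the
10-publication cutoff and a few in the thousands), raw effect p-values and
GO counts (negative binomial, size 0.6, mean 20) through a trivariate
Gaussian copula.  P-values are an exact two-group mixture — nulls
Uniform(0,1), signals Beta(a,1) with a = 0.01, i.e. strong signals —
attached to the latent variable by rank reordering, so the marginal is
exact and the signal flags travel with the values; FDRs are
Benjamini–Hochberg within disease.  Defaults: 104 diseases, 2,000 genes
per disease, target Spearman(publications, FDR rank) = -0.003 and
Spearman(publications, GO count) = 0.110, and a true-signal fraction of
0.195 so that with strong signals the FDR<5% replicated fraction sits
near 19.5%.

Because BH adjustment ties most null FDR values into large plateaus (and
the count marginals tie at small values), the classical
`2 sin(pi rho / 6)` latent-Pearson mapping under-delivers the target rank
correlation.  The generator therefore calibrates the latent correlation by
a short seeded internal simulation (proportional correction plus one
secant step), hitting the target Spearman on the generated table to within
about ±0.01 at 2,000 genes per disease before sampling noise.  Targets
within ±0.02 of zero skip calibration.  The two latent couplings share the
publication axis; their cross term is the product of the two (conditional
independence given the publication latent), which is always positive
semidefinite.  Note the targets apply to the full generated table; the
≥10-publication filter truncates the publication axis and attenuates the
realized rank correlations of the filtered subset below the targets.

What the synthetic data does *not* emulate: gene birth (genes absent from
the baseline never gain annotations, whereas real releases add newly
annotated genes), annotation removal and ontology restructuring, gene-gene
dependence within a disease, shared gene effects across diseases, and any
ontology DAG structure.  Passing tests therefore show the pipeline's
statistical machinery is correct under the stated generative assumptions,
not that real archives follow these models.

## Numerical and degenerate-input choices

* Empty tables and all-zero counts raise; a single annotated gene has
  Gini 0 and bootstrap CI [0, 0].
* Positive-count threshold for simulated fractional counts is `> 0`: any
  positive mass counts as annotated.
* Negative release-to-release total changes are clamped to zero.
* Atkinson requires epsilon > 0; Kolm kappa > 0; unknown metrics raise.
* All randomness flows through `numpy.random.Generator` with explicit
  seeds; every result object and output directory records the seed, and
  fixed seeds give bit-identical outputs in deterministic modes.

## Problem sizes

The test suite exercises the pipeline at 100–2,000 genes, 3–10 releases
and bootstrap sizes of 200–300, which characterises every property the
package claims while keeping the suite fast; the acceptance script runs
the full default study conditions (10,000 genes, 17 releases, B = 1000,
104 diseases x 2,000 genes).
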