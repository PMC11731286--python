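# Methods

## The screening problem

Two genotypes (KPC, a pancreatic-cancer-prone model; CRE, its control) are
profiled by bulk RNA-seq at five ages (weeks 4, 6, 8, 10, 12) with
replicate fibroblast cultures. Early timepoints show almost no
differential expression, so a per-timepoint test alone misses genes whose
divergence accumulates slowly. The screen therefore combines (a)
per-timepoint negative-binomial testing, (b) a per-gene linear regression
of log2 fold change on age with a coefficient-of-determination gate, (c)
biological gates (expression, coding biotype, secreted/cell-surface
localization) aimed at paracrine candidates, and (d) unweighted preranked
enrichment to read out pathway-level drift.

## Synthetic data model

Counts are gamma-Poisson (negative binomial) draws:
`y ~ Poisson(lambda)`, `lambda ~ Gamma(1/phi, phi * mu)`, giving
`Var(y) = mu + phi mu^2`. The per-sample mean is
`mu(g, s) = L_s * r_g * 2^{lfc(g, w(s))}` for KPC samples (CRE uses
lfc = 0), where `L_s` is a log-normal library size and `r_g` a log-normal
relative abundance normalized on the CRE baseline, so the KPC group mean
is exactly `2^lfc` times the CRE mean at equal depth — the quantity the
fold-change estimator targets.

Planted classes: `trend_up`/`trend_down` genes have
`lfc(w) = ± slope * (w - w_0)`, anchored at zero at the first week so the
earliest timepoint is genuinely null-like and trend recovery is
nontrivial; `late_only` genes have a fixed lfc at the final week only
(they fit a line poorly — the expected R^2 of the step profile is 0.5 —
and thus probe the screen's specificity for *continuous* change).

Defaults, chosen as a realistic fibroblast-like detected transcriptome and
fixed once:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | desk-scale detected transcriptome |
| `baseline_log_mean/sd` | 3.0 / 2.0 (ln scale) | long-tailed abundance; median count ≈ 10^2 at 2M depth |
| `dispersion` | 0.05 | biological CV ≈ 22%, typical for cultured cells from inbred mice |
| `libsize_mean/cv` | 2e6 / 0.3 | moderate depth with realistic depth spread, so TMM has work to do |
| `n_replicates` | 3 | common design when the source never states replicate counts |
| `trend_slope` | 0.5 log2FC/week | reaches |log2FC| = 4 by week 12 |
| `late_log2fc` | 3.0 | a strong final-week effect |
| `frac_coding` | 0.70 | coding fraction of a detected universe incl. non-coding RNA |
| `frac_secreted_or_surface` | 0.12 | secretome+surfaceome over the whole detected universe (union of the two GO-style flags; below coding-only estimates because non-coding genes carry no such annotation) |

Annotation flags are assigned independently of expression class by
default; `enrich_planted_annotation=True` marks every planted trend gene
coding and secreted-or-surface, which is how the full cascade is exercised
end-to-end. A `per_gene_dispersion` switch draws log-normal per-gene
dispersions to stress the common-dispersion estimator.

What the generator does **not** emulate: batch effects, gene-length biased
counting, correlated genes, compositional interference between planted
classes, sample swaps, or count artifacts of UMI/duplicate handling.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every failure mode of
real libraries.

## Normalization

TMM follows the published estimator exactly: reference sample = the one
whose upper quartile of nonzero CPM is closest to the mean upper quartile;
per test sample, gene-wise `M = log2((obs/N_obs)/(ref/N_ref))` and
`A = (log2(obs/N_obs) + log2(ref/N_ref))/2` over genes nonzero in both;
double trimming keeps ranks within [30%, 70%] of M and [5%, 95%] of A;
the factor is `2^(weighted mean M)` with inverse asymptotic binomial
variance weights, and factors are recentred to geometric mean 1. Because
the precision weights depend on absolute counts, rescaling one sample's
counts changes the factor slightly (M-values are unchanged); exact
invariance holds only for the unweighted trimmed mean, so the invariance
test asserts normalized abundances at 3% rather than bitwise equality.

CPM uses a pseudo-count proportional to effective library size:
`cpm = (y + p * L_j / mean(L)) / L_j * 1e6` with `p = 0.25` by default, so
the prior contributes the same CPM offset in every sample. FPKM is
`y / ((len/1e3) * (L_eff/1e6))`; both invert algebraically to counts,
which the tests exploit.

## Dispersion and the exact test

The common dispersion maximizes the summed per-gene conditional
log-likelihood of within-group counts given group totals, over all
(genotype, week) groups with ≥ 2 replicates, after rescaling counts to the
geometric mean of effective library sizes (a deliberate simplification of
full quantile adjustment — adequate when factors are near 1, and the
residual depth mismatch is second-order for the conditional argument).
Optimization is bounded 1-D search on log(phi) over [1e-6, 10]; an
estimate pinned at the lower bound reports 0 (Poisson).

The exact test conditions on the total of the two groups' (equalized,
rounded) sums; group-A's conditional pmf is computed by direct log-space
summation over the full support, so totals of ~10^6 remain exact and
affordable. `phi = 0` degenerates to the binomial conditional. Two-sided
p = `min(1, 2 * min(lower tail, upper tail))`; a zero total returns p = 1
by convention. The test is discrete and therefore conservative: the null
p < 0.05 rate on simulated nulls sits near 0.04, which the acceptance
checks pin to [0.03, 0.06].

Genes with CPM > 1 in fewer than 2 samples of a week's contrast are not
tested that week (configurable, including off). log2FC is the ratio of
prior-augmented group-mean CPM — a mild shrinkage that keeps low-count
fold changes finite. BH is applied within each timepoint, matching
per-timepoint DEG reporting.

## Trend screen

OLS of log2FC on week (with intercept), R^2 = 1 − SSE/SST, vectorized via
the correlation identity. Conventions: genes lacking a tested log2FC at
any week are ineligible ("incomplete profile"); a constant profile gets
R^2 = 0 and direction "flat" so it can never pass the gate; the R^2 gate
at 0.8 implies a nonzero slope, so candidates split cleanly into up/down.
Under the null, R^2 for 5 points follows Beta(1/2, 3/2); the upper tail at
0.8 is ≈ 0.0406, the screen's per-gene false-positive rate before the
annotation gates — this analytic value anchors the calibration test.

The expression gate reads "mean FPKM ≥ 1 in either genotype at all
timepoints" in its genotype-fixed sense (one genotype must clear the bar
at every week); the per-week-either reading (the clearing genotype may
change with week) is implemented behind `expression_rule` because the
phrasing is genuinely ambiguous. Genotype-fixed is the default as the
stricter and more biologically coherent reading (sustained expression in
at least one condition).

Localization is consumed as precomputed boolean flags (secreted OR cell
surface); ontology traversal is out of scope. The final candidate set is
the plain intersection of the gate survivors with the final-week DEG list
— set algebra with no tolerance, which the tests assert literally against
the emitted files.

## Unweighted GSEA

With exponent 0, ranking scores only order the list; the running sum gains
`1/N_hit` at members and loses `1/N_miss` elsewhere, and ES is the extreme
of maximal absolute deviation. The running sum times `N_hit * N_miss` is
an integer, so ES comparisons and tie decisions are computed in integer
arithmetic: exact magnitude ties (peak = −trough) take the positive
extreme by convention. Reversal antisymmetry (`ES -> -ES`) holds exactly
except at such ties, where any fixed sign convention must break it.

Preranked lists carry no sample labels to permute, so the null is
gene-label permutation: random same-size sets drawn without replacement
from the ranked universe. One pool of partial Fisher–Yates shuffles per
ranked list is shared across set sizes (the first k slots of a shuffle are
a uniform k-subset), which makes 10^4 permutations across ~150 sets cheap
and introduces only the usual mild dependence between set-level nulls.
p-values are one-sided in the observed direction with the +1 correction
`p = (1 + #{same-sign |null ES| >= |ES|}) / (1 + #same-sign)`; for small
problems the null enumerates all subsets exactly. NES divides ES by the
mean same-sign null magnitude (sign preserved; undefined when no same-sign
null exists, reported NA). BH runs across sets within a collection and
timepoint; collections (canonical-like, hallmark-like) are adjusted
separately. Default set-size window after universe restriction: 5–500.
Ties anywhere break lexicographically for determinism.

Because planted trends are anchored at zero at the first week, the
synthetic consistency analysis (sets significant at *every* timepoint)
correctly returns zero — the week-4 ranking is noise. The per-week counts
at weeks 6–12 recover the planted sets.

## Pipeline and determinism

A master seed feeds a spawned `SeedSequence` hierarchy (generator, gene
sets, per-collection-per-week GSEA), so stages are individually
reproducible and a rerun is byte-identical, including the JSON report and
every TSV. The run report's counts are defined as the cardinalities of the
emitted files and tested as such.

## Problem sizes

Defaults are desk-scale by design: 2000 genes, 30 samples, 150 gene sets,
10^4 permutations per list — a full run takes well under a minute, and the
calibration experiments (10^5 null regressions, 2000-gene null DE) run in
seconds, so the whole validation path is routinely re-runnable.

## Known limitations

- Common dispersion only (no tagwise/empirical-Bayes shrinkage); the exact
  test inherits the usual conservatism of discrete tests at small counts.
- Library-size equalization by global rescaling + rounding, not full
  quantile adjustment; fine near factors of 1, increasingly approximate
  for badly imbalanced depths.
- The gene-label GSEA null ignores inter-gene correlation, as all
  preranked approaches do; p-values on correlated real data are
  optimistic relative to a sample-permutation null.
- The trend regression treats per-week log2FC estimates as equally
  precise; no weighting by their standard errors.
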