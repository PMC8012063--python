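# Methods

`xte` re-implements, as a tested and reusable pipeline, the statistical
machinery used in multi-tissue breeder/non-breeder transcriptome
comparisons: threshold-free pathway enrichment against empirically
resampled nulls, an expression-weighted cross-tissue p-value
combination, fold-change analogues of both, signed co-expression
network connectivity between gene sets, downstream overlap and
direction-concordance comparisons, and actuarial mortality rates.
This note documents the models, assumptions, parameters and design
decisions.

## Per-tissue set enrichment

For a gene set X with member p-values p_1..p_m in one tissue, the test
statistic is Fisher's combination

    F_X = -2 * sum_i ln(p_i),

with the fold-change analogue L_X = sum_i |log2FC_i|. Under
independence F_X ~ chi-square(2m), but gene-level p-values within a
tissue are correlated (regulatory cascades, co-expression), so the
reference distribution is estimated empirically: the statistic is
recomputed on random draws of m genes from the tissue's complete
post-filter background, each draw without replacement within itself
and independent across draws. The right-tail estimate is

    p_hat = (r + 1) / (N + 1),  r = #{null >= observed},

which can never be zero. Draw counts escalate through a schedule
(default 1,000 -> 10,000 -> 100,000) while p_hat sits at or below the
resolution bound of the previous stage (1/1,000 after the first stage);
fresh draws are taken at every stage rather than pooled. Large values
of F or L indicate enrichment, so the right tail is the only relevant
one. Ties count toward the tail; in the degenerate case m = background
size every null draw reproduces the background and p_hat = 1.

The ratio F_up / F_down — the statistic evaluated separately on the
members with positive and negative fold-change — indicates net
functional up- or down-regulation of a set. Degenerate splits are
flagged rather than silently coerced: all members up reports +inf
("all_up"), all down reports 0 ("all_down"), a down-statistic of
exactly 0 with a nonzero up-statistic reports +inf ("down_zero"), and
an empty comparison reports NaN ("undefined"). Members with a
fold-change of exactly 0 join neither side.

BH-FDR is applied across sets within each tissue (per-tissue families
by default; a joint family across tissues is a caller choice by
concatenating results before adjustment).

## Expression-weighted cross-tissue statistics

Evidence for one gene g is combined across the l tissues with signed
expression-share weights

    w_gt = expr_gt * sgn(log2FC_gt) / sum_t expr_gt
    f_g  = | 2 * sum_t ln(p_gt) * w_gt |
    l_g  = | sum_t log2FC_gt * w_gt |

where expr_gt is the normalized mean expression. A ubiquitously
expressed gene is judged by all tissues roughly equally; a gene whose
expression is concentrated in one tissue (a pituitary hormone, say) is
judged almost entirely by that tissue — with a 99.96% expression share
the statistic is within a small fraction of a percent of the dominant
tissue's single-tissue Fisher statistic. Because the weights carry the
fold-change sign, direction-consistent regulation accumulates while
conflicting evidence cancels: the statistic rewards cross-tissue
consistency.

Handling of edge cases: missing (gene, tissue) entries get weight 0 and
are dropped from the weight denominator; a fold-change of exactly 0
gives sgn = 0, zeroing that tissue's weight while its expression still
counts in the denominator (literal reading of the formula); genes with
zero total observed expression are excluded and reported.

Gene-level p-values for f_g (and l_g) come from a resampling null
that holds the gene's weights fixed and redraws, per tissue, one value
uniformly from that tissue's observed background (p-values for f,
fold-changes for l), with the same (r+1)/(N+1) estimate and escalation
schedule. This choice keeps the gene-level null consistent with the
set-level philosophy — the null reflects the observed background
distributions, not a parametric assumption. As an independent
cross-check, `crosstissue_analytic_p` evaluates the closed-form tail
valid under independent-uniform backgrounds and single-sign weights:
-ln p_t ~ Exp(1), so f is a weighted sum of exponentials
(Erlang/gamma for equal |w|, hypoexponential for pairwise-distinct
|w|). The analytic mode is a verification tool, never the production
p-value.

Set-level cross-tissue enrichment applies the Fisher machinery to the
gene-level cross-tissue p-values, with the background being all scored
genes; the direction ratio splits member genes by the sign of
sum_t log2FC_gt * w_gt.

## Co-expression connectivity

Robust pairwise correlation uses the biweight midcorrelation: each
gene is centered at its median and Tukey-biweighted with
u = (x - med) / (9 * MAD); observations with |u| >= 1 get zero weight.
The `max_p_outliers` parameter (default 0.1) caps how much of each tail
may be zero-weighted by rescaling u so the value at the corresponding
quantile sits at |u| = 1. Genes with zero MAD fall back to Pearson
centering for that gene (with a warning); outright constant genes get
correlation 0, flagged.

The signed adjacency is a_ij = ((1 + cor_ij)/2)^beta; the topological
overlap is

    tom_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with the diagonal excluded from internal sums and reported as 1. The
default beta = 26 corresponds to a soft threshold selected by
scale-free-fit diagnostics at full study scale; `scale_free_fit`
reports fit R^2 and mean connectivity per candidate beta but never
auto-chooses. Computation is single-block (block-size tuning is
irrelevant at desk scale).

Connectivity between two gene sets is defined on their non-shared
members, k_XY = sum over X\Y x Y\X of tom entries, so nested sets have
connectivity 0 and identical sets are undefined (flagged). The
one-sided (right tail) p-value compares k_XY against 10,000 (default)
random pairs of index sets of matched sizes, each drawn without
replacement from all TOM indices; the two drawn sets may intersect each
other, and the same X\Y / Y\X restriction is then applied — mirroring
the observed-statistic computation exactly.

A calibration subtlety: exact null uniformity of the connectivity p
holds when the tested pair is itself exchangeable with the random
draws (random gene sets). Module-aligned cross-module pairs are
conservative by construction, because random null sets occasionally
contain same-module gene pairs that inflate the null. The validation
suite therefore checks three things separately: within-module power,
uniformity for exchangeable random pairs, and a cross-module
false-positive rate at or below nominal.

## Downstream comparisons

Set overlaps are tested with the two-sided Fisher exact test on the
2x2 table against a stated universe (default: the intersected gene
catalog), p-values by the standard point-probability summation
convention; note that for a perfectly overlapping pair the equally
improbable mirror table doubles the p relative to the observed table's
hypergeometric point mass. Sample odds ratios get a Haldane 0.5
correction (flagged) when a cell is zero. Direction concordance
between two DEG tables is an exact two-sided binomial test of the
same-direction count against 0.5, per stratum (e.g. tissue) and pooled
over strata; genes with zero fold-change in either table are excluded
and counted. Weighted Pearson correlation of fold-changes uses
weighted moments; its p-value uses the t approximation with effective
sample size (sum w)^2 / (sum w^2) — a documented choice, since no
exact finite-sample distribution exists for arbitrary weights.

## Mortality rates

The observation window (default ages 1.5–11.5 years) is divided into
6-month intervals. Within each interval and status, the annual
mortality rate is deaths / person-years: an individual alive through
the whole interval contributes 0.5 years, one dying or censored within
it contributes the time up to the event. An individual switching
status mid-interval has its exposure split exactly at the transition
age — the whole-interval alternative is ambiguous for switchers,
whereas splitting conserves total person-time exactly (asserted to
1e-9 in the tests). Rates are reported only for intervals holding at
least `min_individuals` (default 10) of the status, and two statuses
are compared by a paired t-test across their common retained
intervals, with a Shapiro–Wilk normality diagnostic on the paired
differences. Kaplan–Meier/Cox modelling and hazard smoothing are out
of scope.

## Synthetic data: what it emulates, and what it does not

`simulate_de_summaries` generates DE summary tables directly rather
than simulating counts and fitting a DE model — the pipeline's input
contract is the summary table, and direct generation keeps ground
truth exact and tests fast. Null genes carry Uniform(0,1] p-values and
Normal(0, 0.05) log2 fold-changes. Signal genes in planted (set,
tissue) cells carry Beta(a,1) p-values (default a = 0.1) and signed
fold-changes with mean magnitude 0.07 (~5% expression change — the
subtle-effect regime these methods target), drawn as gamma(4) with
that mean. Planted sets receive disjoint member pools; the per-(gene,
tissue) probability that the fold-change sign matches the planted
direction (`direction_consistency`) makes the consistency reward of
f_g testable. Expression totals are log-normal, split across tissues
by a symmetric Dirichlet whose concentration (default 0.1) yields a
realistic contingent of strongly tissue-concentrated genes (a few
percent of genes with >99% of expression in one tissue at alpha =
0.05, fewer at 0.1). Defaults are 15,000 genes x 16 tissues and 200
gene sets of 10–50 members.

The generator does not emulate species/sex/batch structure, the
multifactorial DE design, count-level noise, or correlated gene
backgrounds within a tissue. Passing null-calibration tests on this
generator therefore shows the resampling machinery is correct under
exchangeable backgrounds, not that real within-tissue correlation is
handled optimally — which is precisely why the empirical null exists:
it conditions on the observed background distribution rather than
assuming chi-square.

`simulate_coexpression` is a single-factor-per-module latent model;
`simulate_cohort` draws exponential lifetimes under piecewise-constant
status-specific hazards with optional deterministic-age switches and
administrative censoring.

## Validation conditions and problem sizes

The validation suite (and `scripts/acceptance.py`) runs at desk scale,
chosen so each property is sharply testable:

* Fisher-oracle agreement: 15,000-gene uniform background, 500 sets of
  size 5–50; agreement with the chi-square(2m) tail degrades for much
  smaller backgrounds because the empirical background distribution
  itself deviates from uniform.
* Null calibration: 10,000 genes x 4 tissues, 200 sets; KS uniformity
  of the pooled per-tissue and the cross-tissue set p-values, plus a
  binomial bound on how often draw-count escalation fires (probability
  1/1,001 per test under the null).
* Planted recovery: 50 replicates of 4,000 genes x 4 tissues with 8
  planted up-regulated sets (Beta(0.1,1), fully consistent) among 40.
* Consistency reward: 50 replicates of 2,000 genes x 8 tissues with
  diffuse expression (Dirichlet alpha = 5) and moderate signal
  (Beta(0.5,1)). Both choices are substantive: the cross-tissue reward
  only concerns genes expressed in several tissues, and at the default
  planted strength both the consistent and the random-sign set
  saturate the 1/100,001 empirical-p floor, which would make the
  paired comparison degenerate rather than informative.
* Connectivity: brute-force TOM oracle at 10 genes; exhaustive
  enumeration of all 2-subset pairs at 30 genes; 50 replicates of a
  planted two-module simulation (2 x 15 module genes + 30 noise genes,
  loading 0.9, 40 samples, beta = 26, 2,000 draws).
* Mortality: one cohort of 1,000 individuals (500 per status) with
  hazards 0.1 vs 0.2 / year.

## Known limitations

* The gene-level null for f_g treats tissues as independent given the
  weights; cross-tissue correlation of a gene's p-values is not
  modelled (the set-level resampling inherits whatever dependence the
  gene-level p-values carry).
* The escalation rule bounds the resolution of reported p-values at
  1/(max draws + 1); smaller p-values are censored at the floor.
* Biweight midcorrelation assumes at least a handful of samples;
  degenerate (zero-MAD) genes fall back to Pearson behavior.
* The paired t-test across age intervals treats interval rates as
  exchangeable paired observations; it inherits the usual small-sample
  normality caveats, which is why the Shapiro–Wilk diagnostic is
  reported alongside.
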