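# Methods

## Problem and model

The package selects candidate reference genes for qPCR normalization from a
genes × samples RNA-Seq count matrix spanning several genotypes and
phenological/treatment conditions. A usable reference gene must be (i) not
differentially expressed between any two conditions, (ii) abundant enough to
quantify reliably, and (iii) stable — low coefficient of variation across all
samples. The pipeline encodes each requirement as a separate, independently
testable stage.

Counts are modelled as negative binomial with the standard RNA-Seq
parameterization `var = μ + φ·μ²` (dispersion φ ≥ 0; φ = 0 is the Poisson
limit). Sequencing-depth differences are absorbed by per-sample size factors
(library size divided by the geometric mean of library sizes).

## Stage 1 — non-differential expression (NDE) filter

For every unordered pair of distinct condition labels, each gene is tested
with an exact conditional binomial test on group-summed counts: conditional
on a gene's total count `n` across both groups, the group-A sum is, under the
null, Binomial(n, p₀) with p₀ = group A's share of the summed size factors.
Overdispersion is handled by a quasi-likelihood variance inflation
`c = 1 + φ·m̄` (m̄ the size-factor-scaled per-sample mean): the observed
deviation of the group-A sum from its null expectation is shrunk by `√c`
before the exact test, so φ = 0 reduces exactly to the classical two-sided
binomial test (verified against full enumeration in the tests).

Dispersion handling: φ can be supplied (scalar or per gene); by default it is
estimated per gene by the within-group moment estimator
`φ̂ = max(0, (s² − m̄)/m̄²)` on scaled counts, pooled across the two groups
with (nᵍ − 1) weights. With ~10–12 samples per group these estimates are
noisy enough to fatten the null tail, so they are moderated toward the
across-gene median with a prior weight of 20 degrees of freedom (an
empirical-Bayes squeeze in the spirit of DE packages' dispersion shrinkage,
kept deliberately simple). Under a Poisson null this yields a raw rejection
rate of ~5–6% at the 5% level; under planted simulations at the default
design it gives >90% retention of stable genes and >90% exclusion of
4-fold-changed genes.

P-values are Benjamini–Hochberg adjusted across genes within each comparison.
A gene passes the stage when its adjusted p is ≥ α (default 0.05) in every
comparison and it has ≥ `min_reads_per_sample` (default 100) reads in every
sample. An optional CV ceiling (`max_cv`) exists but is disabled by default:
the resampling stage already thresholds CV (see Limitations).

## Stage 2 — per-gene statistics

Per gene: total (exact integer sum), mean = total / n_samples, variance and
SD with the sample (n − 1) denominator (population denominator available via
`ddof=0`; the choice matters little at n = 47 but is exposed because the
convention is ambiguous in spreadsheet-based workflows), and CV = SD/mean. A
gene with mean 0 is retained with CV flagged undefined. Five-number summaries
and quantiles use linear interpolation between order statistics — the most
common default and the same convention everywhere in the package. Pearson
correlations among μ, σ² and CV get two-sided p-values from
`t = r√(n−2)/√(1−r²)`; star codes (***, **, *, n.s.) always follow the
computed p-value. CV ranking sorts ascending by CV with ties broken by
descending mean and then gene id, making reports deterministic.

## Stage 3 — resampled order-statistic thresholds

The null question: how extreme a mean/CV pair could a gene show if its counts
were exchangeable draws from the pooled data? Each of `n_pseudo` (default
10,000) pseudo genes is n_samples counts drawn uniformly **with replacement**
from the pooled set of all matrix entries (the standard bootstrap reading;
it keeps pseudo genes i.i.d.), with mean and CV computed exactly as for real
genes. Thresholds are order statistics of the sorted pseudo values with rank
`k = round(p·N)` clamped to [1, N] — at N = 10,000 the 97.5% mean threshold
is the 9,750-th sorted mean and the 2.5% CV threshold the 250-th sorted CV.
Selection is strict: mean > μ-threshold AND CV < CV-threshold; boundary genes
are logged. All percentile pairs in a sweep — defaults (5%, 95%), (2.5%,
97.5%), (1%, 99%), (0.1%, 99.9%) — share one pseudo-gene set, which
guarantees nested, weakly shrinking selections across pairs.

## Stage 4 — geNorm stability

Ct values are transformed to relative quantities per gene,
`q = (1+E)^(Ct_min − Ct)`, so each gene's highest-expressing sample is its
calibrator (q = 1); E is the gene's amplification efficiency. Pairwise
variation `V_jk` is the sample SD over samples of `log2(q_j/q_k)`; stability
`M_j` is the mean of `V_jk` over all partners. One gene — the one with
maximal M, ties broken by gene id — is excluded per round until two remain;
those two have identical M by construction and are reported as an unordered
pair. Sample vs population SD is again exposed (`ddof`); sample SD is the
default. The pairwise-variation statistic V(n/n+1) of normalization factors
(geometric means of the n most stable genes) is provided for deciding how
many reference genes to use (conventional cutoff 0.15).

qPCR support: standard curves are ordinary least squares of Ct on log₁₀
quantity (≥ 3 distinct dilutions, slope must be negative), with
`E = 10^(−1/slope) − 1` and an inclusive 83–110% acceptance band; Ct
variability reports per-gene five-number summaries and CV of raw Ct; relative
expression reports group means ± SE scaled so each gene's lowest group mean
is 1 (a designated reference gene can be used instead — both readings of
"normalized to the lowest expression" are supported).

## Synthetic data

`generate_count_matrix(SimConfig())` emulates the target experiment: 47
samples over 14 genotypes and 4 conditions (three stages plus a treated
variant of the last), per-sample lognormal size factors renormalized to
geometric mean 1 (sd 0.2; set `libsize_sd=0` to test the unnormalized
regime), and 200 genes with base means log-uniform on 330–3,700 reads in
three classes: 20 stable (φ = 0.05, no condition effect), 30 DE (φ = 0.05,
±2 log₂-fold in one random condition) and 150 noisy (φ = 0.6, no condition
effect). The class sizes mirror a realistic funnel — a minority of truly
stable genes inside a larger non-DE background — at a scale comparable to a
242-gene NDE set. `generate_ct_table` inverts the standard-curve transform
(`Ct = ct_ref − log q / log(1+E)` plus Gaussian cycle noise) so the Ct
pathway is exactly invertible at zero noise.

What the generator does **not** emulate: GC/length biases, batch effects
beyond size factors, genotype-specific expression structure, or
mean-dependent dispersion trends. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated NB model, not
robustness to every artifact of real libraries.

## Numerical conventions and degenerate inputs

- One global seed; every stochastic operation derives a child seed by hashing
  `seed:operation` (always < 2³¹), so adding draws to one stage never shifts
  another's stream, and identical configurations give byte-identical reports.
- Decimal output always uses "." regardless of locale; CSV floats are written
  at 15 significant digits (round-trips exceed 12 significant digits).
- All-zero genes: dispersion 0 with a warning; CV undefined (NaN), retained
  in statistics, excluded from CV ranking with a warning.
- Missing Ct values: samples are dropped listwise for geNorm (it needs a
  complete matrix) and pairwise for per-gene Ct summaries; genes with < 2
  observed Ct values are excluded with a warning.
- Strict inequalities at selection thresholds; genes exactly on a boundary
  are logged rather than silently included.

## Design choices where the design was open

- The DE stand-in is an exact conditional binomial test rather than a
  reimplementation of a full GLM framework: it is exactly testable against an
  enumeration oracle, and external per-comparison results can replace it.
- All pairwise condition comparisons are run; with 4 conditions that is 6
  tests per gene.
- Problem sizes in tests and the acceptance checks (e.g. 2,000-gene null
  calibrations, 2,000-pseudo-gene sweeps in unit tests, 100-replicate
  stability recovery) were chosen as the smallest sizes at which the
  Monte-Carlo tolerances quoted in the tests are meaningful.

## Known limitations

- With the variation-index cap disabled (the default), high-dispersion genes
  can survive the NDE filter — their inflated dispersion makes the
  quasi-likelihood test conservative — and they fatten the pooled resampling
  distribution, raising the CV threshold (≈ 0.7 on default simulations vs
  ≈ 0.5 on homogeneous data). High-mean noisy genes can then enter the
  candidate set; the geNorm stage removes them whenever at least two stable
  candidates survive, but users with visibly heterogeneous NDE sets should
  consider setting `max_cv`.
- The moment/median-moderated dispersion is cruder than empirical-Bayes
  tagwise shrinkage; for production DE analysis, plug in external results.
- geNorm M values depend on the candidate panel: M is an average over
  partners, so a panel dominated by co-regulated genes can mask instability.
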