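# refgene-select

Statistical discovery of reference (housekeeping) genes for qPCR
normalization from bulk RNA-Seq count data.

qPCR expression measurements must be normalized against reference genes whose
own expression is stable across the tissues, developmental stages and
treatments under study. Classical choices (actin, ubiquitin, EF1-α, rRNA)
often turn out to be unstable in a new organism or condition set. This
package implements a pipeline that mines an existing RNA-Seq experiment for
candidate reference genes and validates them with geNorm stability analysis,
aimed at anyone with a genes × samples count matrix spanning multiple
genotypes/conditions who needs trustworthy qPCR normalizers.

## Method

Given a count matrix with per-sample design labels, the pipeline runs four
stages:

1. **NDE filter** — a gene is kept only if it is non-differentially expressed
   in *every* pairwise comparison of condition labels (exact conditional
   binomial test on group-summed counts with a quasi-likelihood
   overdispersion inflation `1 + φ·m̄`, Benjamini–Hochberg adjusted) and has
   at least 100 reads in every sample. Externally computed DE results (e.g.
   from edgeR) can be plugged in instead.
2. **Per-gene statistics** — for each gene, the mean μ and the coefficient of
   variation `CV = sd/μ` across all samples; a good reference gene couples a
   high μ (abundant, quantifiable) with a low CV (stable).
3. **Resampling thresholds** — how large a μ, and how small a CV, could arise
   by chance? 10,000 *pseudo genes* are built by drawing `n_samples` counts
   with replacement from the pooled matrix; the k-th order statistics of the
   sorted pseudo means and CVs (k = round(p·N), e.g. the 9,750-th mean at
   97.5% and the 250-th CV at 2.5%) become selection thresholds. Candidates
   must have μ strictly above and CV strictly below them.
4. **geNorm validation** — on qPCR-type relative quantities
   (`q = (1+E)^(Ct_min − Ct)` from threshold cycles and amplification
   efficiency E), each gene's stability is
   `M_j = mean_k SD_samples(log2 q_j/q_k)`; the gene with the highest M is
   excluded and M recomputed until the two most stable genes remain.

A negative-binomial synthetic-data generator (`refgene_select.simulate`)
reproduces the target study design — 47 samples, 14 genotypes, 4
phenological/treatment conditions, base means 330–3,700 reads — with planted
stable, differentially expressed and high-dispersion genes, so the whole
pipeline is testable without any download. qPCR helpers cover standard-curve
efficiency estimation (`E = 10^(−1/slope) − 1`, accepted band 83–110%), Ct
variability summaries and group-wise relative expression.

The three fit-shaped stages are also exposed as scikit-learn estimators
operating on samples × genes matrices: `NDEFilter` and `CVMeanSelector`
(feature selectors with `fit`/`get_support`/`transform`) and `GeNormRanker`
(`fit` → `final_pair_`, `m_values_`).

## Worked example

```bash
refgene-select run --simulate --seed 4 --out results/demo
```

```
stages: {'input_genes': 200, 'nde_genes': 72, 'selected_candidates': 6}; final pair: ('gene0007', 'gene0011')
```

Reading the funnel: of 200 simulated genes, 72 show no differential
expression in any of the six condition comparisons and clear 100 reads in
every sample; 6 of those jointly beat the resampled mean and CV thresholds at
the (2.5%, 97.5%) percentile pair; geNorm stepwise exclusion on the
candidates names `gene0007`/`gene0011` — both planted stable genes — as the
most stable pair. `results/demo/` holds every stage report
(`threshold_sweep.csv`, `gene_stats.csv`, `genorm_m_trace.csv`, …) plus a
`manifest.json` with seeds, stage counts and content hashes; rerunning with
the same seed reproduces the hashes byte-for-byte.

The same stages are available piecemeal (`simulate`, `nde`, `stats`,
`select`, `genorm`, `qpcr`) and as library calls:

```python
from refgene_select import (gene_stats, simulate_pseudo_genes,
                            percentile_thresholds, select_candidates)

stats = gene_stats(cm)                                  # cm: CountMatrix
pseudo = simulate_pseudo_genes(cm, n_pseudo=10_000, seed=1)
thr = percentile_thresholds(pseudo, cv_percentile=0.025, mu_percentile=0.975)
result = select_candidates(stats, thr)
print(result.n_selected, result.selected[:5])
```

## Documentation

See `docs/methods.md` for the statistical model, parameter defaults,
numerical conventions and known limitations.
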