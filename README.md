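# brainomics

Downstream multi-omics analyses for post-mortem brain case/control
cohorts, built as a tested, reusable library. It covers the statistical
stages that sit between a gene-level count matrix and biological
conclusions in a psychiatric transcriptomics study:

- **Covariate-aware differential expression** — per-gene negative-binomial
  GLMs with log link and size-factor offsets, testing the disorder factor
  by a 1-df likelihood-ratio chi-square of the full model
  `~ age + pH + PMI + PRUA + disorder` against the covariate-only reduced
  model, with independent filtering (baseMean ≥ 10) and Benjamini–Hochberg
  FDR. PRUA (percentage of reads uniquely aligned) is the alignment-quality
  covariate; it can also be regressed out of normalized expression.
- **Marker-gene cell-type composition indices** — a sample's index for a
  cell type is the median normalized expression of that type's marker
  genes; under proportionality, predicted proportion = observed index /
  purified-tissue index. Validated by *in-silico mixing*: purified count
  vectors are hypergeometrically down-sampled to weight-proportional read
  targets and summed, with size-matched random gene sets as the null and
  constrained least-squares deconvolution as a cross-check.
- **Expression-matched null resampling** — the median log2 fold change of a
  gene set against 1000 null sets matched on baseMean within 5%.
- **Consensus ChIP-peak / TSS proximity sweeps** — peaks of a reference set
  supported (≥ 1 bp overlap) in every replicate set; one-tailed rank-sum
  tests of near-vs-far genes at distance thresholds from 1 to 50 kb.
- **Integrated gene+metabolite pathway enrichment** — per omics layer, a
  one-tailed Wilcoxon test that pathway members have lower p-value ranks
  than the background, combined across layers with Fisher's method
  (−2Σln p ~ χ²(4)); pathways need > 5 measured genes and ≥ 1 measured
  metabolite.
- **Metabolomics** — per-metabolite rank-sum tests with FDR, top-k
  metabolite Ward clustering, and metabolite-ratio vs gene-expression
  Spearman correlations.

Because the studies this serves rely on restricted human tissue, the
package ships a first-class **synthetic cohort generator**
(`brainomics.simulate`) that plants known ground truth — per-sample
cell-type mixing weights, disorder effects, reduced expression near a
simulated transcription-factor peak set, PRUA-driven read thinning, and
metabolites coupled to gene sets at target correlations — so every stage
is tested end-to-end against recoverable truth.

## Worked example

`examples/03_celltype_mixing.py` builds purified neuron/astrocyte
libraries of 5,759,178 reads each, mixes them in silico and recovers the
weights:

```
80:20 mixing of 5,759,178-read libraries requests 4,607,342 + 1,151,836 reads

planted vs predicted neuron proportion:
  0.2 -> 0.212
  0.4 -> 0.406
  0.6 -> 0.602
  0.8 -> 0.803

marker MSE 0.0001 beats 100.0% of 500 size-matched random sets (empirical p = 0.0020)
```

The first line is the down-sampling arithmetic (read targets are
`round(weight × common_total)`); the predictions are index ratios, and the
null comparison shows the predictive power is specific to the marker
genes, not their number. The other scripts in `examples/` walk through
cohort simulation, differential expression (planted log2FC = 1.2 genes are
recovered at FDR < 0.05 with mean estimate 1.217), the peak-proximity
sweep (the near-vs-far rank-sum p grows monotonically from the 1 kb to the
50 kb threshold when the planted effect sits within 1 kb), and integrated
pathway enrichment (a planted pathway tops 15 decoys; Fisher combination
of (0.05, 0.05) = 0.01748).

A thin CLI mirrors the pipeline stages and is byte-reproducible under a
fixed seed:

```bash
brainomics all --config config.yml --seed 7 --outdir results/
```

with subcommands `simulate normalize de celltype peaks pathways metab all`.

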