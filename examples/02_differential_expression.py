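"""Covariate-adjusted NB likelihood-ratio differential expression.

Fits per-gene negative-binomial GLMs (~ age + pH + PMI + PRUA + disorder
vs the covariate-only reduced model) on a cohort with two planted effects,
then applies independent filtering (baseMean >= 10) and BH adjustment.
"""

from brainomics import diffexp, simulate

cfg = simulate.CohortConfig(
    n_genes=1500,
    n_per_group=20,
    de_effects={"SZ": {f"g{i:05d}": 1.2 for i in range(25)}},
    n_metabolites=0,
)
cohort = simulate.make_cohort(cfg, seed=2)

de = diffexp.nb_lrt(cohort.counts, cohort.samples, contrast=("SZ", "CTL"))
de = diffexp.filter_and_adjust(de, min_base_mean=10)

planted = [f"g{i:05d}" for i in range(25)]
sig = de[de["padj"] < 0.05]
print(f"genes at FDR<0.05: {len(sig)} (25 planted at log2FC=1.2)")
print(f"planted genes recovered: {sig.index.isin(planted).sum()}")
print(f"mean estimated log2FC of planted genes: {de.loc[planted, 'log2FC'].mean():.3f}")
print("\ntop 5 genes by adjusted p:")
cols = ["baseMean", "log2FC", "pvalue", "padj"]
print(de.nsmallest(5, "padj")[cols].round(4).to_string())

# A well-calibrated test recovers most planted genes near their true
# fold change while keeping null genes off the FDR<0.05 list.
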