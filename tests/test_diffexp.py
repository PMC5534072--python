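import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from brainomics import diffexp, simulate
from brainomics.diffexp import (
    DesignSpec,
    crossdisorder_concordance,
    estimate_dispersions,
    filter_and_adjust,
    nb_lrt,
)
from brainomics.io import CountMatrix, SampleTable

from conftest import make_sample_table


def _counts_from_matrix(Y, sample_ids):
    df = pd.DataFrame(Y, columns=sample_ids)
    df.index = [f"g{i:04d}" for i in range(len(df))]
    return CountMatrix(df)


class TestDispersions:
    def test_poisson_genes_estimated_near_zero(self, rng):
        Y = rng.poisson(200.0, size=(500, 48))
        cm = _counts_from_matrix(Y, [f"s{i}" for i in range(48)])
        disp = estimate_dispersions(cm, factors=pd.Series(1.0, index=cm.sample_ids))
        assert (disp <= 0.05).mean() >= 0.95

    def test_nb_dispersion_recovered(self, rng):
        alpha = 0.2
        mu = 300.0
        r = 1 / alpha
        Y = rng.negative_binomial(r, r / (r + mu), size=(500, 48))
        cm = _counts_from_matrix(Y, [f"s{i}" for i in range(48)])
        disp = estimate_dispersions(cm, factors=pd.Series(1.0, index=cm.sample_ids))
        assert abs(disp.mean() - alpha) < 0.05

    def test_constant_gene_alpha_zero(self):
        Y = np.vstack([np.full(6, 7), np.arange(1, 7)])
        cm = _counts_from_matrix(Y, [f"s{i}" for i in range(6)])
        disp = estimate_dispersions(
            cm, factors=pd.Series(1.0, index=cm.sample_ids), shrink=0.0
        )
        assert disp.iloc[0] == 0.0

    def test_all_zero_gene_flagged_nan(self):
        Y = np.vstack([np.zeros(6, int), np.arange(1, 7)])
        cm = _counts_from_matrix(Y, [f"s{i}" for i in range(6)])
        disp = estimate_dispersions(cm, factors=pd.Series(1.0, index=cm.sample_ids))
        assert np.isnan(disp.iloc[0])


@pytest.fixture(scope="module")
def fixture_data():
    rng = np.random.default_rng(3)
    st = make_sample_table(8, seed=3)
    mu = rng.uniform(50, 500, size=10)
    Y = rng.poisson(mu[:, None], size=(10, 16))
    return _counts_from_matrix(Y, st.sample_ids), st


class TestNBLRT:
    def test_poisson_limit_matches_statsmodels_deviance(self, fixture_data):
        """At alpha=0 the LRT statistic equals the Poisson GLM deviance
        difference between reduced and full models (independent fit)."""
        cm, st = fixture_data
        zeros = pd.Series(0.0, index=cm.gene_ids)
        ones = pd.Series(1.0, index=cm.sample_ids)
        de = nb_lrt(cm, st, dispersions=zeros, factors=ones)
        meta = st.table
        X_full = sm.add_constant(
            np.column_stack(
                [
                    meta[["age", "pH", "PMI", "PRUA"]].to_numpy(),
                    (meta["diagnosis"] == "SZ").astype(float),
                ]
            )
        )
        X_red = sm.add_constant(meta[["age", "pH", "PMI", "PRUA"]].to_numpy())
        for i, g in enumerate(cm.gene_ids):
            y = cm.values[i]
            full = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
            red = sm.GLM(y, X_red, family=sm.families.Poisson()).fit()
            stat_sm = red.deviance - full.deviance
            assert de.loc[g, "lrt_stat"] == pytest.approx(stat_sm, abs=1e-6)

    def test_nb_fit_matches_statsmodels(self, fixture_data):
        """Fixed-dispersion NB coefficients and log-likelihoods agree with
        statsmodels GLM as the independent optimizer."""
        cm, st = fixture_data
        alpha = 0.15
        disp = pd.Series(alpha, index=cm.gene_ids)
        ones = pd.Series(1.0, index=cm.sample_ids)
        de = nb_lrt(cm, st, dispersions=disp, factors=ones)
        meta = st.table
        X_full = sm.add_constant(
            np.column_stack(
                [
                    meta[["age", "pH", "PMI", "PRUA"]].to_numpy(),
                    (meta["diagnosis"] == "SZ").astype(float),
                ]
            )
        )
        for i, g in enumerate(cm.gene_ids):
            y = cm.values[i]
            full = sm.GLM(
                y, X_full, family=sm.families.NegativeBinomial(alpha=alpha)
            ).fit()
            lfc_sm = full.params[-1] / np.log(2)
            assert de.loc[g, "log2FC"] == pytest.approx(lfc_sm, abs=1e-4)

    def test_sample_order_invariance(self, fixture_data):
        cm, st = fixture_data
        perm = list(reversed(cm.sample_ids))
        cm2 = CountMatrix(cm.counts[perm])
        st2 = SampleTable(st.table.loc[perm])
        de1 = nb_lrt(cm, st)
        de2 = nb_lrt(cm2, st2)
        assert np.allclose(de1["pvalue"], de2["pvalue"], atol=1e-8)

    def test_contrast_flip_negates_lfc(self, fixture_data):
        cm, st = fixture_data
        de1 = nb_lrt(cm, st, contrast=("SZ", "CTL"))
        de2 = nb_lrt(cm, st, contrast=("CTL", "SZ"))
        assert np.allclose(de1["log2FC"], -de2["log2FC"], atol=1e-6)
        assert np.allclose(de1["pvalue"], de2["pvalue"], atol=1e-8)

    def test_lrt_statistic_non_negative(self, fixture_data):
        cm, st = fixture_data
        de = nb_lrt(cm, st)
        assert (de.loc[de["converged"], "lrt_stat"] >= 0).all()

    def test_singular_design_names_columns(self, fixture_data):
        cm, st = fixture_data
        with pytest.raises(ValueError, match="collinear"):
            nb_lrt(cm, st, design=DesignSpec(covariates=("age", "age")))

    def test_all_zero_gene_flagged(self, fixture_data):
        cm, st = fixture_data
        Y = cm.counts.copy()
        Y.iloc[0] = 0
        de = nb_lrt(CountMatrix(Y), st)
        assert not de["converged"].iloc[0]
        assert np.isnan(de["pvalue"].iloc[0])

    def test_including_prua_reduces_confounded_false_positives(self):
        """When alignment quality (PRUA) is confounded with diagnosis, the
        PRUA covariate must soak up the spurious signal."""
        wins = 0
        for s in range(8):
            cfg = simulate.CohortConfig(
                n_genes=500,
                n_per_group=10,
                marker_frac=0.03,
                n_metabolites=0,
                prua_mean_by_dx={"SZ": 0.70, "CTL": 0.90},
            )
            co = simulate.make_cohort(cfg, seed=300 + s)
            de_with = nb_lrt(co.counts, co.samples)
            de_without = nb_lrt(
                co.counts, co.samples, design=DesignSpec(covariates=("age", "pH", "PMI"))
            )
            fp_with = int((de_with.loc[de_with.converged, "pvalue"] < 0.05).sum())
            fp_without = int(
                (de_without.loc[de_without.converged, "pvalue"] < 0.05).sum()
            )
            wins += fp_with < fp_without
        assert wins >= 7


class TestFilterAdjust:
    def _table(self, base_means, pvals):
        return pd.DataFrame(
            {
                "baseMean": base_means,
                "log2FC": 0.0,
                "dispersion": 0.1,
                "lrt_stat": 1.0,
                "pvalue": pvals,
                "padj": np.nan,
                "converged": True,
            },
            index=[f"g{i}" for i in range(len(base_means))],
        )

    def test_low_expression_excluded_from_adjustment(self):
        de = self._table([5, 12, 12, 12, 12], [0.01, 0.02, 0.03, 0.04, 0.05])
        out = filter_and_adjust(de, min_base_mean=10)
        assert np.isnan(out["padj"].iloc[0])
        assert out["padj"].iloc[1:].notna().all()

    def test_surviving_padj_matches_bh_on_subset(self):
        from brainomics.stats import bh_adjust

        de = self._table([5, 12, 12, 12, 12], [0.01, 0.02, 0.03, 0.04, 0.05])
        out = filter_and_adjust(de, min_base_mean=10)
        expect = bh_adjust([0.02, 0.03, 0.04, 0.05])
        assert out["padj"].iloc[1:].to_numpy() == pytest.approx(expect)

    def test_zero_floor_adjusts_everything(self):
        de = self._table([5, 12], [0.5, 0.6])
        out = filter_and_adjust(de, min_base_mean=0)
        assert out["padj"].notna().all()

    def test_nonconvergent_excluded(self):
        de = self._table([20, 20], [0.01, 0.02])
        de.loc["g0", "converged"] = False
        out = filter_and_adjust(de)
        assert np.isnan(out["padj"].iloc[0])


class TestCrossDisorder:
    def _null_table(self, rng, n=2000):
        return pd.DataFrame(
            {
                "baseMean": rng.uniform(10, 1000, n),
                "log2FC": rng.normal(0, 0.3, n),
                "pvalue": rng.uniform(0, 1, n),
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_self_comparison_is_perfect(self, rng):
        de = self._null_table(rng)
        res = crossdisorder_concordance(de, de)
        assert res["rho"] == pytest.approx(1.0)
        assert res["n_sig_both"] == res["n_sig_a"] == res["n_sig_b"]

    def test_independent_tables_uncorrelated(self, rng):
        res = crossdisorder_concordance(
            self._null_table(rng, 10000), self._null_table(rng, 10000)
        )
        assert abs(res["rho"]) < 0.05

    def test_shared_planted_effect_gives_tiny_overlap_p(self):
        genes = {f"g{i:05d}": 1.5 for i in range(40)}
        cfg = simulate.CohortConfig(
            n_genes=800,
            n_per_group=12,
            marker_frac=0.03,
            n_metabolites=0,
            diagnoses=("CTL", "SZ", "BPD"),
            de_effects={"SZ": genes, "BPD": genes},
        )
        co = simulate.make_cohort(cfg, seed=77)
        de_sz = nb_lrt(co.counts, co.samples, contrast=("SZ", "CTL"))
        de_bp = nb_lrt(co.counts, co.samples, contrast=("BPD", "CTL"))
        res = crossdisorder_concordance(de_sz, de_bp)
        assert res["overlap_test"].p_value < 1e-6
        assert res["rho"] > 0

    def test_disjoint_gene_sets_rejected(self, rng):
        a = self._null_table(rng, 10)
        b = self._null_table(rng, 10)
        b.index = [f"x{i}" for i in range(10)]
        with pytest.raises(ValueError):
            crossdisorder_concordance(a, b)
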