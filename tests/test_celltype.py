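import numpy as np
import pandas as pd
import pytest

from brainomics import celltype as ct
from brainomics import simulate
from brainomics.io import CountMatrix
from brainomics.normalize import normalize_pipeline


class TestComputeIndex:
    def test_median_of_markers(self):
        df = pd.DataFrame({"s": [1.0, 5.0, 9.0, 100.0]}, index=["g1", "g2", "g3", "gx"])
        idx = ct.compute_index(df, {"neuron": ["g1", "g2", "g3"]})
        assert idx.loc["s", "neuron"] == 5.0

    def test_constant_matrix(self):
        df = pd.DataFrame(7.0, index=["g1", "g2"], columns=["s1", "s2"])
        idx = ct.compute_index(df, {"a": ["g1", "g2"]})
        assert (idx == 7.0).all().all()

    def test_locality_wrt_non_marker_genes(self):
        df = pd.DataFrame({"s": [1.0, 5.0, 9.0]}, index=["g1", "g2", "g3"])
        base = ct.compute_index(df, {"a": ["g1", "g2", "g3"]})
        df2 = pd.concat(
            [df, pd.DataFrame({"s": [1e6]}, index=["extra"])]
        )
        again = ct.compute_index(df2, {"a": ["g1", "g2", "g3"]})
        pd.testing.assert_frame_equal(base, again)

    def test_all_markers_missing_rejected(self):
        df = pd.DataFrame({"s": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="zzz"):
            ct.compute_index(df, {"zzz": ["nope"]})

    def test_partial_markers_warn(self):
        df = pd.DataFrame({"s": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="absent"):
            ct.compute_index(df, {"a": ["g1", "g2", "missing"]})


class TestDownsample:
    def test_identity_at_full_total(self, rng):
        v = np.array([5, 0, 12, 3])
        out = ct.downsample_counts(v, 20, rng)
        assert (out == v).all()

    def test_exact_total_and_bounds(self, rng):
        v = rng.integers(0, 1000, size=200)
        target = int(v.sum() * 0.37)
        out = ct.downsample_counts(v, target, rng)
        assert out.sum() == target
        assert (out <= v).all() and (out >= 0).all()

    def test_target_above_total_rejected(self, rng):
        with pytest.raises(ValueError):
            ct.downsample_counts(np.array([1, 2]), 10, rng)

    def test_hypergeometric_expectation(self, rng):
        v = np.array([100, 300, 600])
        target = 500
        draws = np.stack([ct.downsample_counts(v, target, rng) for _ in range(1000)])
        expect = v * target / v.sum()
        frac = v / v.sum()
        var = target * frac * (1 - frac) * (v.sum() - target) / (v.sum() - 1)
        se = np.sqrt(var / 1000)
        assert (np.abs(draws.mean(axis=0) - expect) <= 3 * se + 1e-9).all()


class TestMixInSilico:
    def test_printed_component_targets(self, rng):
        """80:20 mixing of equal 5,759,178-read libraries must request
        4,607,342 and 1,151,836 reads."""
        total = 5_759_178
        pure = {
            "neuron": np.array([total - 7, 7]),
            "astrocyte": np.array([3, total - 3]),
        }
        mixed, targets = ct.mix_in_silico(
            pure, {"neuron": 0.8, "astrocyte": 0.2}, rng
        )
        assert targets == {"neuron": 4_607_342, "astrocyte": 1_151_836}
        assert mixed.sum() == 4_607_342 + 1_151_836

    def test_degenerate_weights(self, rng):
        pure = {"a": np.array([10, 20]), "b": np.array([15, 15])}
        mixed, _ = ct.mix_in_silico(pure, {"a": 1.0, "b": 0.0}, rng)
        assert (mixed == pure["a"]).all()

    def test_bad_weights_rejected(self, rng):
        pure = {"a": np.array([10]), "b": np.array([10])}
        with pytest.raises(ValueError):
            ct.mix_in_silico(pure, {"a": 0.7, "b": 0.7}, rng)

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            ct.mix_in_silico(
                {"a": np.array([1, 2]), "b": np.array([1])}, {"a": 0.5, "b": 0.5}, rng
            )


class TestPredictProportion:
    def test_formula(self):
        assert ct.predict_proportion(40.0, 50.0)[0] == pytest.approx(0.8)
        assert ct.predict_proportion(50.0, 50.0)[0] == pytest.approx(1.0)

    def test_exact_on_proportional_indices(self):
        for w in np.linspace(0, 1, 11):
            est, clamped = ct.predict_proportion(w * 123.4, 123.4)
            assert est == pytest.approx(w, abs=1e-12)
            assert 0.0 <= clamped <= 1.0

    def test_nonpositive_purified_rejected(self):
        with pytest.raises(ValueError):
            ct.predict_proportion(1.0, 0.0)


@pytest.fixture(scope="module")
def mixing_benchmark():
    """Purified neuron/astrocyte libraries mixed at known weights."""
    panel = simulate.make_profiles(1000, ("neuron", "astrocyte"), 0.04, 50.0, seed=3)
    rng = np.random.default_rng(4)
    total = 1_000_000
    pure = {
        c: simulate.sample_pure_counts(panel, c, total, 0.05, seed=rng)
        for c in ("neuron", "astrocyte")
    }
    m = min(int(v.sum()) for v in pure.values())
    pure = {c: ct.downsample_counts(v, m, rng) for c, v in pure.items()}
    weights = (0.2, 0.4, 0.6, 0.8)
    cols = {}
    for w in weights:
        mixed, _ = ct.mix_in_silico(pure, {"neuron": w, "astrocyte": 1 - w}, rng)
        cols[f"mix{w}"] = mixed
    lin = pd.DataFrame(cols, index=panel.gene_ids).astype(float)
    pure_lin = pd.DataFrame(pure, index=panel.gene_ids).astype(float)
    true_w = pd.DataFrame(
        {"neuron": weights, "astrocyte": [1 - w for w in weights]},
        index=list(cols),
    )
    return panel, lin, pure_lin, true_w


class TestNullIndexMSE:
    def test_markers_beat_random_sets(self, mixing_benchmark):
        panel, lin, pure_lin, true_w = mixing_benchmark
        obs, nulls, p = ct.null_index_mse(
            lin, pure_lin, true_w, panel.marker_map, n_null=200, rng=1
        )
        assert p <= 0.01
        assert (nulls > obs).mean() >= 0.95

    def test_self_null_is_calibrated(self, mixing_benchmark):
        panel, lin, pure_lin, true_w = mixing_benchmark
        rng = np.random.default_rng(5)
        expressed = lin.index[(lin > 0).any(axis=1)]
        ok = 0
        for rep in range(10):
            fake = {
                c: list(rng.choice(expressed, size=len(g), replace=False))
                for c, g in panel.marker_map.items()
            }
            _, _, p = ct.null_index_mse(
                lin, pure_lin, true_w, fake, n_null=99, rng=rep
            )
            ok += p > 0.05
        assert ok >= 7

    def test_zero_nulls_rejected(self, mixing_benchmark):
        panel, lin, pure_lin, true_w = mixing_benchmark
        with pytest.raises(ValueError):
            ct.null_index_mse(lin, pure_lin, true_w, panel.marker_map, n_null=0)


class TestMatchedNullFoldChange:
    def _de(self, rng, n=1000):
        return pd.DataFrame(
            {
                "baseMean": rng.uniform(10, 1000, n),
                "log2FC": rng.normal(0, 0.5, n),
            },
            index=[f"g{i:04d}" for i in range(n)],
        )

    def test_candidates_within_tolerance(self, rng):
        de = self._de(rng)
        members = list(de.index[:20])
        pool, cands = ct.expression_matched_candidates(de, members, 0.05)
        pool_bm = de.loc[pool, "baseMean"].to_numpy()
        for g, idx in zip(members, cands):
            rel = np.abs(pool_bm[idx] - de.loc[g, "baseMean"]) / de.loc[g, "baseMean"]
            assert (rel <= 0.05 + 1e-12).all()

    def test_unmatched_member_raises_without_widening(self, rng):
        de = self._de(rng, 50)
        de.loc[de.index[0], "baseMean"] = 1e9
        with pytest.raises(ValueError, match="matched"):
            ct.expression_matched_candidates(
                de, [de.index[0]], 0.05, widen_on_failure=False
            )

    def test_planted_shift_detected(self, rng):
        de = self._de(rng)
        members = list(de.index[:30])
        de.loc[members, "log2FC"] -= 0.8
        obs, nulls, p = ct.matched_null_fold_change(de, members, n_null=500, rng=2)
        assert obs < 0
        assert p <= 0.01

    def test_null_set_not_significant(self, rng):
        de = self._de(rng)
        ok = 0
        for rep in range(10):
            members = list(rng.choice(de.index, size=25, replace=False))
            _, _, p = ct.matched_null_fold_change(de, members, n_null=199, rng=rep)
            ok += p > 0.05
        assert ok >= 7


class TestSpecificityCorrelation:
    def test_perfect_anticorrelation(self, rng):
        profiles = pd.DataFrame(
            {
                "neuron": rng.uniform(1, 100, 50),
                "astro": rng.uniform(1, 100, 50),
            },
            index=[f"g{i}" for i in range(50)],
        )
        spec = np.log2(
            (profiles["neuron"] + 1e-3) / (profiles["astro"] + 1e-3)
        )
        de = pd.DataFrame({"log2FC": -spec}, index=profiles.index)
        rho, p = ct.specificity_correlation(de, profiles, "neuron")
        assert rho == pytest.approx(-1.0)

    def test_planted_neuron_loss_detected(self):
        cfg = simulate.CohortConfig(
            n_genes=600,
            n_per_group=12,
            marker_frac=0.04,
            n_metabolites=0,
            neuron_shift={"SZ": -0.12},
        )
        co = simulate.make_cohort(cfg, seed=21)
        from brainomics.diffexp import nb_lrt

        de = nb_lrt(co.counts, co.samples)
        rho, p = ct.specificity_correlation(de, co.panel.mean_expression, "neuron")
        assert rho < 0
        assert p < 0.01


class TestLSDeconvolve:
    def test_noiseless_exact_recovery(self, rng):
        S = pd.DataFrame(
            rng.uniform(1, 100, size=(60, 2)),
            index=[f"g{i}" for i in range(60)],
            columns=["a", "b"],
        )
        w = np.array([0.6, 0.4])
        x = pd.DataFrame({"s": S.to_numpy() @ w}, index=S.index)
        est = ct.ls_deconvolve(x, S)
        assert est.loc["s"].to_numpy() == pytest.approx(w, abs=1e-6)

    def test_pure_profile(self, rng):
        S = pd.DataFrame(
            rng.uniform(1, 100, size=(60, 3)),
            index=[f"g{i}" for i in range(60)],
            columns=["a", "b", "c"],
        )
        x = pd.DataFrame({"s": S["b"]}, index=S.index)
        est = ct.ls_deconvolve(x, S)
        assert est.loc["s", "b"] == pytest.approx(1.0, abs=1e-6)

    def test_rank_deficient_rejected(self):
        S = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]}, index=["g1", "g2", "g3"]
        )
        x = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=S.index)
        with pytest.raises(ValueError, match="rank"):
            ct.ls_deconvolve(x, S)

    def test_concordance_with_index_ratio(self, mixing_benchmark):
        panel, lin, pure_lin, true_w = mixing_benchmark
        est_ls = ct.ls_deconvolve(lin, pure_lin)
        idx = ct.compute_index(lin, panel.marker_map)
        pure_idx = ct.compute_index(pure_lin, panel.marker_map)
        est_ratio = idx["neuron"] / pure_idx.loc["neuron", "neuron"]
        err_ls = np.abs(est_ls["neuron"] - true_w["neuron"])
        err_ratio = np.abs(est_ratio - true_w["neuron"])
        # both methods recover the planted weights
        assert err_ls.max() < 0.1 and err_ratio.max() < 0.1
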