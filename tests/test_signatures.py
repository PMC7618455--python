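"""Differential expression, specificity resampling, and signature variants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import fate_groups, make_adata
from resistrace import signatures as sig


def _log_adata(X):
    adata = make_adata(np.zeros(X.shape, dtype=int))
    adata.X = np.asarray(X, dtype=float)
    return adata


def _exact_ranksum_p(a, b):
    """Enumeration oracle: exact two-sided rank-sum P via all group splits."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        stat = ranks[list(combo)].sum()
        total += 1
        if abs(stat - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


class TestDifferentialExpression:
    def test_group_size_and_overlap_validation(self):
        adata = _log_adata(np.ones((6, 3)))
        cells = list(adata.obs_names)
        with pytest.raises(ValueError, match="at least 3"):
            sig.differential_expression(adata, cells[:2], cells[2:])
        with pytest.raises(ValueError, match="overlap"):
            sig.differential_expression(adata, cells[:3], cells[2:])

    def test_tiny_instance_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        X = np.stack(
            [rng.permutation(np.arange(10.0)) for _ in range(4)], axis=1
        )
        adata = _log_adata(X)
        cells = list(adata.obs_names)
        res = sig.differential_expression(adata, cells[:5], cells[5:])
        for j in range(4):
            exact = _exact_ranksum_p(X[:5, j], X[5:, j])
            assert res["pval"].iloc[j] == pytest.approx(exact, rel=0.10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        X = np.log1p(rng.poisson(5, size=(120, 2000)).astype(float))
        adata = _log_adata(X)
        cells = list(adata.obs_names)
        res = sig.differential_expression(adata, cells[:60], cells[60:])
        from scipy import stats

        assert stats.kstest(res["pval"], "uniform").pvalue > 0.01

    def test_planted_twofold_shift_recovered(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(20, size=(400, 50)).astype(float)
        base[:200, 0] = rng.poisson(40, size=200)  # 2-fold up in group A
        adata = _log_adata(np.log1p(base))
        cells = list(adata.obs_names)
        res = sig.differential_expression(adata, cells[:200], cells[200:])
        assert 0.7 <= res["log2fc"].iloc[0] <= 1.3
        assert res["padj"].iloc[0] < 0.05

    def test_constant_gene_gets_p_one(self):
        rng = np.random.default_rng(8)
        X = np.log1p(rng.poisson(5, size=(10, 3)).astype(float))
        X[:, 1] = 2.0
        adata = _log_adata(X)
        cells = list(adata.obs_names)
        res = sig.differential_expression(adata, cells[:5], cells[5:])
        assert res["pval"].iloc[1] == 1.0
        assert res["log2fc"].iloc[1] == 0.0

    def test_sign_convention_positive_means_up_in_group_a(self):
        X = np.log1p(np.array([[9.0], [9.0], [9.0], [1.0], [1.0], [1.0]]))
        adata = _log_adata(X)
        cells = list(adata.obs_names)
        res = sig.differential_expression(adata, cells[:3], cells[3:])
        assert res["log2fc"].iloc[0] > 0


@pytest.fixture(scope="module")
def groups(small_experiment):
    prn, res_cells, sen_cells = fate_groups(small_experiment, "treatment")
    crn, fit_cells, unf_cells = fate_groups(small_experiment, "control")
    return prn, res_cells, sen_cells, crn, fit_cells, unf_cells


class TestSpecificityTest:
    def test_treatment_only_effect_is_specific(self, small_experiment, groups):
        prn, res_cells, sen_cells, crn, fit_cells, unf_cells = groups
        res_sig = sig.differential_expression(prn, res_cells, sen_cells)
        spec = sig.specificity_test(
            prn, res_cells, sen_cells, crn, fit_cells, unf_cells,
            n_boot=500, n_perm=500, seed=0,
        )
        specific = set(spec.specific_genes(res_sig))
        truth_res = set(small_experiment.truth.resistance_genes)
        truth_fit = set(small_experiment.truth.fitness_genes)
        # resistance-program genes dominate; fitness-only genes stay out
        assert len(specific & truth_res) >= 5
        assert len(specific & truth_fit) <= max(1, len(specific) // 10)

    def test_fully_permuted_fates_yield_alpha_level_calls(self, groups):
        prn, res_cells, sen_cells, crn, fit_cells, unf_cells = groups
        rng = np.random.default_rng(1)
        pool_t = np.array(res_cells + sen_cells)
        pool_c = np.array(fit_cells + unf_cells)
        rates = []
        for rep in range(3):
            rng.shuffle(pool_t)
            rng.shuffle(pool_c)
            r, s = pool_t[: len(res_cells)], pool_t[len(res_cells):]
            f, u = pool_c[: len(fit_cells)], pool_c[len(fit_cells):]
            res_sig = sig.differential_expression(prn, list(r), list(s))
            spec = sig.specificity_test(
                prn, list(r), list(s), crn, list(f), list(u),
                n_boot=300, n_perm=300, seed=rep,
            )
            rates.append(len(spec.specific_genes(res_sig)) / prn.n_vars)
        assert np.mean(rates) <= 0.05

    def test_resampling_is_deterministic_under_seed(self, groups):
        prn, res_cells, sen_cells, crn, fit_cells, unf_cells = groups
        a = sig.specificity_test(prn, res_cells, sen_cells, crn, fit_cells,
                                 unf_cells, n_boot=200, n_perm=200, seed=5)
        b = sig.specificity_test(prn, res_cells, sen_cells, crn, fit_cells,
                                 unf_cells, n_boot=200, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zero_variance_gene_gets_p_one(self):
        rng = np.random.default_rng(2)
        X = np.log1p(rng.poisson(4, size=(40, 5)).astype(float))
        X[:, 3] = 1.5
        adata = _log_adata(X)
        cells = list(adata.obs_names)
        spec = sig.specificity_test(
            adata, cells[:10], cells[10:20], adata, cells[20:30], cells[30:],
            n_boot=100, n_perm=100, seed=0,
        )
        row = spec.table.iloc[3]
        assert row["delta_log2fc"] == 0.0
        assert row["boot_pval"] == 1.0 and row["perm_pval"] == 1.0


class TestSignatureVariants:
    def _inputs(self):
        genes = [f"g{i}" for i in range(6)]
        res = pd.DataFrame(
            {"log2fc": [1.0, 0.8, -0.5, 0.3, 0.9, 0.2],
             "pval": [0.01, 0.2, 0.01, 0.04, 0.001, 0.5],
             "padj": [0.02, 0.3, 0.02, 0.08, 0.004, 0.6]},
            index=pd.Index(genes, name="gene"),
        )
        fit = pd.DataFrame(
            {"log2fc": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]},
            index=pd.Index(genes, name="gene"),
        )
        spec = sig.SpecificityResult(
            pd.DataFrame(
                {"delta_log2fc": res["log2fc"],
                 "boot_pval": [0.01, 0.01, 0.9, 0.2, 0.01, 0.7],
                 "perm_pval": [0.01, 0.02, 0.9, 0.3, 0.01, 0.8]},
                index=pd.Index(genes, name="gene"),
            )
        )
        return res, fit, spec, genes

    def test_variant_nesting_and_concordance_restriction(self):
        res, fit, spec, genes = self._inputs()
        concordant = genes[:5]  # g5 not concordant
        variants = sig.build_signature_variants(res, fit, spec, concordant)
        assert set(variants["v2_wilcoxon"].index) <= set(variants["v1_full"].index)
        assert set(variants["v4_bootstrap"].index) <= set(variants["v3_contrast"].index)
        for v in variants.values():
            assert "g5" not in v.index

    def test_wilcoxon_filter_applies_to_variant_two_only(self):
        res, fit, spec, genes = self._inputs()
        variants = sig.build_signature_variants(res, fit, spec, genes)
        assert "g1" in variants["v1_full"].index  # pval 0.2
        assert "g1" not in variants["v2_wilcoxon"].index

    def test_zero_fitness_makes_contrast_equal_full(self):
        res, fit, spec, genes = self._inputs()
        variants = sig.build_signature_variants(res, fit, spec, genes)
        pd.testing.assert_series_equal(
            variants["v3_contrast"], variants["v1_full"], check_names=False
        )

    def test_empty_variant_errors(self):
        res, fit, spec, genes = self._inputs()
        with pytest.raises(ValueError, match="v1_full"):
            sig.build_signature_variants(res, fit, spec, [])
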