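"""Pre-resistance and pre-fitness gene signatures.

Differential expression between pre-resistant and pre-sensitive cells
(Wilcoxon rank-sum, run on singleton-lineage cells) yields the
pre-resistance signature; the same contrast in the vehicle arm (pre-fit
vs pre-unfit) yields the pre-fitness signature.  Bootstrap and
permutation tests on the log2FC contrast isolate genes up-regulated
specifically in pre-resistance, and the four query signature variants
are assembled for connectivity mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Collection, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _norm_matrix(adata: ad.AnnData, cells: Sequence[str]) -> np.ndarray:
    idx = adata.obs_names.get_indexer(pd.Index(cells))
    if (idx < 0).any():
        raise KeyError("group references cells absent from the matrix")
    return np.asarray(adata.X, dtype=float)[idx]


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float) -> np.ndarray:
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def differential_expression(
    adata: ad.AnnData,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE of group A vs group B.

    Operates on log-normalized expression; the rank-sum test uses the
    tie-corrected normal approximation.  log2FC compares group means of
    the unlogged (expm1) normalized expression with a pseudocount, so a
    positive value means higher in group A.  No fold-change or
    detection-fraction thresholds are applied; P-values are BH-adjusted
    over all tested genes.
    """
    if len(set(group_a) & set(group_b)):
        raise ValueError("groups overlap")
    if min(len(group_a), len(group_b)) < 3:
        raise ValueError("each group needs at least 3 cells")
    A = _norm_matrix(adata, group_a)
    B = _norm_matrix(adata, group_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # exact null distribution for tiny tie-free groups, tie-corrected
        # normal approximation otherwise
        res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    # constant genes: all ranks tie, no evidence either way
    constant = (A.std(axis=0) == 0) & (B.std(axis=0) == 0) & (A[0] == B[0]).ravel()
    p = np.where(constant, 1.0, p)
    Ea, Eb = np.expm1(A), np.expm1(B)
    lfc = _log2fc(Ea.mean(axis=0), Eb.mean(axis=0), pseudocount)
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "log2fc": lfc,
            "pval": p,
            "padj": multipletests(p, method="fdr_bh")[1],
            "pct_a": (A > 0).mean(axis=0),
            "pct_b": (B > 0).mean(axis=0),
        }
    ).set_index("gene")


def _group_mean_expm1(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.expm1(X[idx]).mean(axis=0)


def _bootstrap_means(
    E: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap group means over cells: (n_boot, n_genes)."""
    n = E.shape[0]
    W = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(np.float32)
    return (W @ E) / n


def _permuted_means(
    E_all: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Means of random size-n_a / complement splits: two (n_perm, genes) arrays."""
    n = E_all.shape[0]
    colsum = E_all.sum(axis=0, keepdims=True)
    S = np.zeros((n_perm, n), dtype=np.float32)
    for k in range(n_perm):
        S[k, rng.choice(n, size=n_a, replace=False)] = 1.0
    sum_a = S @ E_all
    mean_a = sum_a / n_a
    mean_b = (colsum - sum_a) / (n - n_a)
    return mean_a, mean_b


@dataclass
class SpecificityResult:
    table: pd.DataFrame  # delta_log2fc, boot_pval, perm_pval per gene

    def specific_genes(
        self, resistance_sig: pd.DataFrame, alpha: float = 0.05
    ) -> list[str]:
        """Genes up-regulated specifically in pre-resistance.

        Specific iff the resistance-signature BH-adjusted P < alpha, both
        resampling P-values < alpha, and the contrast log2FC is positive.
        """
        t = self.table.join(resistance_sig[["padj"]], how="inner")
        keep = (
            (t["padj"] < alpha)
            & (t["boot_pval"] < alpha)
            & (t["perm_pval"] < alpha)
            & (t["delta_log2fc"] > 0)
        )
        return t.index[keep].tolist()


def specificity_test(
    treat_adata: ad.AnnData,
    resistant_cells: Sequence[str],
    sensitive_cells: Sequence[str],
    control_adata: ad.AnnData,
    fit_cells: Sequence[str],
    unfit_cells: Sequence[str],
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> SpecificityResult:
    """Bootstrap/permutation assessment of the resistance-vs-fitness contrast.

    The observed statistic per gene is
    delta = log2FC(resistant vs sensitive) - log2FC(fit vs unfit).

    Bootstrap P: cells are resampled with replacement within each of the
    four groups and delta recomputed; P is the (+1-corrected) fraction of
    bootstrap deltas <= 0 — one-sided, for genes up in pre-resistance.
    Permutation P: fate labels are shuffled within each arm and delta
    recomputed; P is the (+1-corrected) fraction of permuted |delta|
    reaching the observed |delta| (two-sided).
    """
    if min(n_boot, n_perm) < 100:
        warnings.warn("fewer than 100 resamples gives coarse P resolution")
    if not treat_adata.var_names.equals(control_adata.var_names):
        shared = treat_adata.var_names.intersection(control_adata.var_names)
        if shared.empty:
            raise ValueError("no shared genes between the two arms")
        treat_adata = treat_adata[:, shared]
        control_adata = control_adata[:, shared]
    rng = np.random.default_rng(seed)

    groups = []
    for adata, cells in (
        (treat_adata, resistant_cells),
        (treat_adata, sensitive_cells),
        (control_adata, fit_cells),
        (control_adata, unfit_cells),
    ):
        groups.append(np.expm1(_norm_matrix(adata, cells)).astype(np.float32))
    E_res, E_sen, E_fit, E_unf = groups

    def delta(m_res, m_sen, m_fit, m_unf):
        return _log2fc(m_res, m_sen, pseudocount) - _log2fc(m_fit, m_unf, pseudocount)

    obs = delta(*(E.mean(axis=0) for E in groups))

    boot = delta(*(_bootstrap_means(E, n_boot, rng) for E in groups))
    boot_p = (np.sum(boot <= 0.0, axis=0) + 1) / (n_boot + 1)

    mr, ms = _permuted_means(
        np.vstack([E_res, E_sen]), E_res.shape[0], n_perm, rng
    )
    mf, mu = _permuted_means(
        np.vstack([E_fit, E_unf]), E_fit.shape[0], n_perm, rng
    )
    perm = delta(mr, ms, mf, mu)
    perm_p = (np.sum(np.abs(perm) >= np.abs(obs)[None, :], axis=0) + 1) / (n_perm + 1)

    constant = (
        (E_res.std(axis=0) == 0)
        & (E_sen.std(axis=0) == 0)
        & (E_fit.std(axis=0) == 0)
        & (E_unf.std(axis=0) == 0)
        & (np.abs(obs) < 1e-12)
    )
    boot_p = np.where(constant, 1.0, boot_p)
    perm_p = np.where(constant, 1.0, perm_p)

    table = pd.DataFrame(
        {
            "gene": treat_adata.var_names,
            "delta_log2fc": obs,
            "boot_pval": boot_p,
            "perm_pval": perm_p,
        }
    ).set_index("gene")
    return SpecificityResult(table)


def build_signature_variants(
    resistance_sig: pd.DataFrame,
    fitness_sig: pd.DataFrame,
    specificity: SpecificityResult,
    concordant_genes: Collection[str],
    pval_cut: float = 0.05,
) -> dict[str, pd.Series]:
    """Assemble the four query signature variants.

    1. pre-resistance log2FC;
    2. pre-resistance log2FC restricted to Wilcoxon P < 0.05;
    3. contrast log2FC (pre-resistance minus pre-fitness);
    4. contrast log2FC restricted to bootstrap P < 0.05 —
    all intersected with the sister-concordant gene set.
    """
    conc = pd.Index(sorted(set(concordant_genes)))
    res = resistance_sig.loc[resistance_sig.index.intersection(conc)]
    shared = res.index.intersection(fitness_sig.index)
    contrast = (
        res.loc[shared, "log2fc"] - fitness_sig.loc[shared, "log2fc"]
    )
    spec = specificity.table.loc[specificity.table.index.intersection(shared)]
    variants = {
        "v1_full": res["log2fc"],
        "v2_wilcoxon": res.loc[res["pval"] < pval_cut, "log2fc"],
        "v3_contrast": contrast,
        "v4_bootstrap": contrast.loc[
            spec.index[spec["boot_pval"] < pval_cut].intersection(contrast.index)
        ],
    }
    for name, v in variants.items():
        if v.empty:
            raise ValueError(f"signature variant {name} is empty after filtering")
    return variants
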