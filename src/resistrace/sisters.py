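"""Sister-pair transcriptomic similarity and sister-concordant genes.

Sister cells — the two daughters of one barcoded cell — are compared
against random cell pairs: Euclidean distances over the top variable
genes quantify overall similarity, and a per-gene Welch t-test on
within-pair absolute log2 fold changes identifies the sister-concordant
genes, i.e. genes whose expression is heritable across one division.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _matrix(adata: ad.AnnData | np.ndarray) -> np.ndarray:
    if isinstance(adata, ad.AnnData):
        return np.asarray(adata.X, dtype=float)
    return np.asarray(adata, dtype=float)


def _cell_index(adata: ad.AnnData, cells: pd.Series) -> np.ndarray:
    idx = adata.obs_names.get_indexer(cells)
    if (idx < 0).any():
        missing = cells[idx < 0].tolist()[:5]
        raise KeyError(f"pair references cells absent from the matrix: {missing}")
    return idx


def _decode_pair_codes(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map codes in [0, n*(n-1)/2) to unordered index pairs (i < j)."""
    # i is the largest integer with i*(2n-i-1)/2 <= code
    i = np.floor((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * codes)) / 2).astype(
        np.int64
    )
    offset = codes - i * (2 * n - i - 1) // 2
    j = i + 1 + offset
    return i, j


def pair_distances(
    adata: ad.AnnData,
    pairs: pd.DataFrame,
    n_random: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Euclidean distances for sister pairs and sampled random pairs.

    ``pairs`` must have ``cell_a``/``cell_b`` columns referencing cells of
    ``adata`` (typically already restricted to the top variable genes).
    ``n_random`` non-sister pairs are sampled uniformly without
    replacement; if it meets or exceeds the number available, all
    non-sister pairs are used.  Returns a PairDistanceTable with columns
    (cell_a, cell_b, distance, kind).
    """
    X = _matrix(adata)
    n = X.shape[0]
    ia = _cell_index(adata, pairs["cell_a"])
    ib = _cell_index(adata, pairs["cell_b"])
    sister_codes = set()
    for a, b in zip(ia, ib):
        i, j = (a, b) if a < b else (b, a)
        sister_codes.add(i * (2 * n - i - 1) // 2 + (j - i - 1))

    total_pairs = n * (n - 1) // 2
    n_available = total_pairs - len(sister_codes)
    rng = np.random.default_rng(seed)
    if n_random >= n_available:
        codes = np.array(
            [c for c in range(total_pairs) if c not in sister_codes], dtype=np.int64
        )
    else:
        chosen: set[int] = set()
        while len(chosen) < n_random:
            draw = rng.integers(0, total_pairs, size=2 * (n_random - len(chosen)))
            for c in draw:
                c = int(c)
                if c not in sister_codes and c not in chosen:
                    chosen.add(c)
                    if len(chosen) == n_random:
                        break
        codes = np.fromiter(chosen, dtype=np.int64, count=len(chosen))
        codes.sort()
    ri, rj = _decode_pair_codes(codes, n)

    sister_d = np.linalg.norm(X[ia] - X[ib], axis=1)
    random_d = np.linalg.norm(X[ri] - X[rj], axis=1)
    sister_df = pd.DataFrame(
        {
            "cell_a": pairs["cell_a"].to_numpy(),
            "cell_b": pairs["cell_b"].to_numpy(),
            "distance": sister_d,
            "kind": "sister",
        }
    )
    random_df = pd.DataFrame(
        {
            "cell_a": adata.obs_names[ri],
            "cell_b": adata.obs_names[rj],
            "distance": random_d,
            "kind": "random",
        }
    )
    return pd.concat([sister_df, random_df], ignore_index=True)


def filter_low_expression_genes(
    adata: ad.AnnData, quantile: float = 0.10
) -> list[str]:
    """Genes whose total normalized expression reaches the given quantile.

    The cutoff is the requested quantile (linear interpolation) of the
    per-gene totals of this dataset; genes strictly below it are removed,
    ties at the cutoff are kept.  ``quantile=0`` is the no-op limit.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    totals = np.asarray(_matrix(adata).sum(axis=0))
    cutoff = np.quantile(totals, quantile)
    return [g for g, t in zip(adata.var_names, totals) if t >= cutoff]


def filter_distant_sisters(
    distances: pd.DataFrame, quantile: float = 0.90
) -> pd.DataFrame:
    """Drop sister pairs more distant than the given sister-distance quantile.

    The cutoff is recomputed from the observed sister-distance
    distribution; pairs at or below it are retained.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    sisters = distances[distances["kind"] == "sister"] if "kind" in distances else distances
    cutoff = np.quantile(sisters["distance"].to_numpy(), quantile)
    return sisters[sisters["distance"] <= cutoff].copy()


def _pair_log2fc(
    X: np.ndarray, ia: np.ndarray, ib: np.ndarray, pseudocount: float
) -> np.ndarray:
    """Per-pair per-gene |log2 FC| on unlogged normalized expression."""
    Ea = np.expm1(X[ia]) + pseudocount
    Eb = np.expm1(X[ib]) + pseudocount
    return np.abs(np.log2(Ea / Eb))


def sister_concordant_genes(
    adata: ad.AnnData,
    sister_pairs: pd.DataFrame,
    random_pairs: pd.DataFrame,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene test of whether sisters are more alike than random pairs.

    Within-pair |log2FC| distributions (on expm1-scale normalized
    expression with a pseudocount) are compared between sister and random
    pairs by a two-tailed Welch t-test, with Benjamini-Hochberg
    adjustment across genes.  A gene is concordant iff adjusted P < alpha
    and its mean sister |log2FC| is below the random mean.  Genes with no
    variance in either group get t = 0, P = 1.
    """
    if len(sister_pairs) < 2 or len(random_pairs) < 2:
        raise ValueError("need at least two sister and two random pairs")
    X = _matrix(adata)
    S = _pair_log2fc(
        X,
        _cell_index(adata, sister_pairs["cell_a"]),
        _cell_index(adata, sister_pairs["cell_b"]),
        pseudocount,
    )
    R = _pair_log2fc(
        X,
        _cell_index(adata, random_pairs["cell_a"]),
        _cell_index(adata, random_pairs["cell_b"]),
        pseudocount,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(S, R, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    mean_s, mean_r = S.mean(axis=0), R.mean(axis=0)
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "sister_mean_abs_log2fc": mean_s,
            "random_mean_abs_log2fc": mean_r,
            "t": t,
            "pval": p,
            "padj": adj,
            "concordant": (adj < alpha) & (mean_s < mean_r),
        }
    ).set_index("gene")
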