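"""Connectivity-map scoring of query signatures against a drug library.

The query signature is split into up- and down-regulated gene sets and
each is scored against a drug's ranked differential-expression profile
with a weighted Kolmogorov-Smirnov enrichment statistic.  When the two
enrichment scores have opposite signs the connectivity score is their
half-difference, otherwise 0.  A negative score means the drug reverses
the query signature; candidate pre-sensitizers must score negative with
permutation P < 0.05 in all four signature variants.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def enrichment_score(
    ranked_stats: np.ndarray, hit_positions: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted KS enrichment of a hit set in a ranked profile.

    ``ranked_stats`` are the profile values sorted in descending order;
    ``hit_positions`` index into that ranking.  Hits advance the running
    sum by |stat|^weight (normalized), misses retreat by 1/(N - n_hits);
    the score is the signed extremum of the running sum.
    """
    N = len(ranked_stats)
    k = len(hit_positions)
    if k == 0 or k >= N:
        return 0.0
    pos = np.sort(np.asarray(hit_positions))
    w = np.abs(ranked_stats[pos]) ** weight
    total = w.sum()
    if total == 0:
        return 0.0
    cum_hit = np.cumsum(w) / total
    miss_step = 1.0 / (N - k)
    j = np.arange(k)
    # running-sum extremes occur just after each hit and just before the next
    after = cum_hit - (pos - j) * miss_step
    before = np.concatenate(([0.0], cum_hit[:-1])) - (pos - j) * miss_step
    candidates = np.concatenate((after, before, [0.0, cum_hit[-1] - (N - k) * miss_step]))
    return float(candidates[np.argmax(np.abs(candidates))])


def _combine(es_up: float, es_down: float, k_up: int, k_down: int) -> float:
    # one-sided queries (e.g. an up-only gene list) are scored by the
    # single set's enrichment; two-sided queries require opposite signs
    if k_down == 0:
        return es_up
    if k_up == 0:
        return -es_down
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


def _batch_es(
    ranked_abs_w: np.ndarray, positions: np.ndarray, n_total: int
) -> np.ndarray:
    """Vectorized enrichment scores for many hit-position sets.

    ``positions`` is (n_sets, k), each row ascending.  Same running-sum
    extremum as :func:`enrichment_score`.
    """
    n_sets, k = positions.shape
    w = ranked_abs_w[positions]
    total = w.sum(axis=1, keepdims=True)
    safe = np.where(total == 0, 1.0, total)
    cum_hit = np.cumsum(w, axis=1) / safe
    miss_step = 1.0 / (n_total - k)
    j = np.arange(k)[None, :]
    drop = (positions - j) * miss_step
    after = cum_hit - drop
    before = np.concatenate(
        (np.zeros((n_sets, 1)), cum_hit[:, :-1]), axis=1
    ) - drop
    cand = np.concatenate((after, before), axis=1)
    es = np.take_along_axis(
        cand, np.argmax(np.abs(cand), axis=1)[:, None], axis=1
    ).ravel()
    return np.where(total.ravel() == 0, 0.0, es)


def connectivity_score(
    query: pd.Series | Mapping[str, float],
    profile: pd.Series | Mapping[str, float],
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 10,
    weight: float = 1.0,
) -> tuple[float, float]:
    """CMap-style connectivity of a query signature to one drug profile.

    The query's up (log2FC > 0) and down (log2FC < 0) gene sets are
    enriched against the drug's descending value ranking; the score is
    (ES_up - ES_down)/2 when the two have opposite signs, else 0.  The
    P-value permutes the gene labels of the drug profile (equivalently,
    assigns the query sets to random rank positions) with a +1/(n+1)
    correction, two-sided on |score|.
    """
    query = pd.Series(query, dtype=float)
    profile = pd.Series(profile, dtype=float)
    shared = query.index.intersection(profile.index)
    dropped = len(query) - len(shared)
    if dropped:
        logger.info("dropped %d query genes absent from the drug profile", dropped)
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} query genes overlap the drug profile "
            f"(min_overlap={min_overlap})"
        )
    order = profile.sort_values(ascending=False, kind="mergesort")
    rank_of = pd.Series(np.arange(len(order)), index=order.index)
    ranked_stats = order.to_numpy()
    up = rank_of[shared[query[shared] > 0]].to_numpy()
    down = rank_of[shared[query[shared] < 0]].to_numpy()

    es_up = enrichment_score(ranked_stats, up, weight)
    es_down = enrichment_score(ranked_stats, down, weight)
    score = _combine(es_up, es_down, len(up), len(down))

    if n_perm <= 0:
        return score, np.nan
    rng = np.random.default_rng(seed)
    N = len(ranked_stats)
    k_up, k_down = len(up), len(down)
    ranked_abs_w = np.abs(ranked_stats) ** weight
    perm = np.argsort(rng.random((n_perm, N)), axis=1)
    null_scores = np.zeros(n_perm)
    es_u = (
        _batch_es(ranked_abs_w, np.sort(perm[:, :k_up], axis=1), N)
        if k_up
        else np.zeros(n_perm)
    )
    es_d = (
        _batch_es(ranked_abs_w, np.sort(perm[:, k_up : k_up + k_down], axis=1), N)
        if k_down
        else np.zeros(n_perm)
    )
    if k_down == 0:
        null_scores = es_u
    elif k_up == 0:
        null_scores = -es_d
    else:
        opposite = es_u * es_d < 0
        null_scores[opposite] = (es_u[opposite] - es_d[opposite]) / 2.0
    p = (np.sum(np.abs(null_scores) >= abs(score)) + 1) / (n_perm + 1)
    return score, float(p)


def score_library(
    variants: Mapping[str, pd.Series],
    library: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 10,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Connectivity of every signature variant against every library drug.

    ``library`` is a drug x gene matrix of differential-expression
    weights.  Returns a ConnectivityTable (drug, variant, score, pval).
    """
    if library.isna().all(axis=1).any():
        raise ValueError("library contains all-missing drug rows")
    rows = []
    rng = np.random.default_rng(seed)
    for drug, profile in library.iterrows():
        profile = profile.dropna()
        for vname, query in variants.items():
            s, p = connectivity_score(
                query,
                profile,
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
                min_overlap=min_overlap,
                weight=weight,
            )
            rows.append((drug, vname, s, p))
    return pd.DataFrame(rows, columns=["drug", "variant", "score", "pval"])


def rank_and_filter(
    table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank drugs by mean connectivity and apply the all-variants filter.

    A drug passes iff its score is negative with P < alpha in every
    signature variant.  Returns per-drug rows sorted ascending by mean
    score (strongest signature reversal first) with a ``passed`` flag.
    """
    def _per_drug(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "mean_score": g["score"].mean(),
                "n_variants": len(g),
                "passed": bool(((g["score"] < 0) & (g["pval"] < alpha)).all()),
            }
        )

    out = (
        table.groupby("drug", sort=False)
        .apply(_per_drug, include_groups=False)
        .sort_values("mean_score")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
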