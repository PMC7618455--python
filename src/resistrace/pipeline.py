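"""End-to-end orchestration of the synthetic analysis pipeline.

Runs simulate -> read corruption -> barcode recovery -> fate partition ->
normalization -> sister concordance -> signatures -> connectivity on one
synthetic experiment, returning every intermediate product.  Serves as
the reference composition of the library modules (the CLI subcommands
mirror these steps one stage at a time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from . import barcodes as bc
from . import connectivity as conn
from . import lineage
from . import preprocess as pp
from . import signatures as sig
from . import simulate as sim
from . import sisters as sis


@dataclass
class PipelineResult:
    experiment: sim.SimulatedExperiment
    cell_labels: dict[str, dict[str, str]]  # arm -> cell -> recovered label
    fates: dict[str, pd.DataFrame]
    concordance: pd.DataFrame
    distances: pd.DataFrame
    resistance_signature: pd.DataFrame
    fitness_signature: pd.DataFrame
    specificity: sig.SpecificityResult
    variants: dict[str, pd.Series]
    connectivity: pd.DataFrame | None
    drug_ranking: pd.DataFrame | None


def _recover_labels(
    adata: ad.AnnData,
    reads_per_cell: int,
    error_rate: float,
    seed: int,
    max_shared: int | None,
) -> dict[str, str]:
    truth = dict(zip(adata.obs_names, adata.obs["label"]))
    reads = sim.corrupt_reads(truth, reads_per_cell, error_rate, seed=seed)
    cells, _ = bc.extract_cell_labels(
        list(zip(reads["cell_id"], reads["read"])), max_shared=max_shared
    )
    return cells


def run_end_to_end(
    config: sim.SimulationConfig,
    reads_per_cell: int = 10,
    n_random_pairs: int = 5000,
    n_top_genes: int = 1000,
    n_boot: int = 500,
    n_perm: int = 500,
    drug_library: pd.DataFrame | None = None,
    n_library_drugs: int = 50,
    n_perm_connectivity: int = 200,
) -> PipelineResult:
    """Run the full analysis on one simulated experiment.

    When no ``drug_library`` is supplied, a synthetic library of
    ``n_library_drugs`` random profiles plus one exact inverse of the
    full-signature variant (drug id ``planted_inverse``) is generated, so
    the connectivity stage always has a known positive control.
    """
    exp = sim.simulate_experiment(config)
    rng = np.random.default_rng(config.seed + 1)

    cell_labels: dict[str, dict[str, str]] = {}
    post_labels: dict[str, set[str]] = {}
    for arm, (pre, post) in exp.arms.items():
        cell_labels[arm] = _recover_labels(
            pre, reads_per_cell, config.barcode_error_rate,
            seed=int(rng.integers(2**31)), max_shared=4,
        )
        post_map = _recover_labels(
            post, reads_per_cell, config.barcode_error_rate,
            seed=int(rng.integers(2**31)), max_shared=None,
        )
        post_labels[arm] = set(post_map.values())

    fates = {
        arm: lineage.assign_fates(cell_labels[arm], post_labels[arm], arm=arm)
        for arm in exp.arms
    }

    # sister concordance on the treatment-arm pre sample
    pre_norm = pp.normalize_log(pp.filter_genes(exp.pre, min_cells=3))
    labeled = {
        c: l for c, l in cell_labels["treatment"].items()
        if c in set(pre_norm.obs_names)
    }
    pairs = lineage.sister_pairs(labeled)
    keep = sis.filter_low_expression_genes(pre_norm, quantile=0.10)
    pre_norm = pre_norm[:, keep].copy()
    top = pp.top_variable_genes(pre_norm, min(n_top_genes, pre_norm.n_vars))
    distances = sis.pair_distances(
        pre_norm[:, top].copy(), pairs, n_random=n_random_pairs,
        seed=int(rng.integers(2**31)),
    )
    retained = sis.filter_distant_sisters(distances, quantile=0.90)
    retained_pairs = pairs.merge(retained[["cell_a", "cell_b"]])
    concordance = sis.sister_concordant_genes(
        pre_norm, retained_pairs, distances[distances["kind"] == "random"]
    )
    concordant_genes = concordance.index[concordance["concordant"]].tolist()

    # signatures on singleton-lineage cells of each arm
    def arm_groups(arm: str):
        pre, _ = exp.arms[arm]
        norm = pp.normalize_log(pp.filter_genes(pre, min_cells=3))
        cells = {
            c: l for c, l in cell_labels[arm].items() if c in set(norm.obs_names)
        }
        singles = lineage.singleton_cells(cells)
        f = fates[arm]
        f = f[f["cell_id"].isin(singles)]
        surviving, lost = lineage.ARM_FATES[arm]
        return (
            norm,
            f.loc[f["fate"] == surviving, "cell_id"].tolist(),
            f.loc[f["fate"] == lost, "cell_id"].tolist(),
        )

    treat_norm, res_cells, sen_cells = arm_groups("treatment")
    ctrl_norm, fit_cells, unf_cells = arm_groups("control")
    resistance_sig = sig.differential_expression(treat_norm, res_cells, sen_cells)
    fitness_sig = sig.differential_expression(ctrl_norm, fit_cells, unf_cells)
    specificity = sig.specificity_test(
        treat_norm, res_cells, sen_cells, ctrl_norm, fit_cells, unf_cells,
        n_boot=n_boot, n_perm=n_perm, seed=int(rng.integers(2**31)),
    )
    variants = sig.build_signature_variants(
        resistance_sig, fitness_sig, specificity, concordant_genes
    )

    connectivity_table = drug_ranking = None
    if drug_library is None and n_library_drugs > 0:
        drug_library = synthetic_drug_library(
            variants["v1_full"], n_library_drugs, seed=int(rng.integers(2**31))
        )
    if drug_library is not None:
        connectivity_table = conn.score_library(
            variants, drug_library, n_perm=n_perm_connectivity,
            seed=int(rng.integers(2**31)),
        )
        drug_ranking = conn.rank_and_filter(connectivity_table)

    return PipelineResult(
        experiment=exp,
        cell_labels=cell_labels,
        fates=fates,
        concordance=concordance,
        distances=distances,
        resistance_signature=resistance_sig,
        fitness_signature=fitness_sig,
        specificity=specificity,
        variants=variants,
        connectivity=connectivity_table,
        drug_ranking=drug_ranking,
    )


def synthetic_drug_library(
    query: pd.Series,
    n_drugs: int,
    seed: int = 0,
    n_genes: int = 978,
    planted_id: str = "planted_inverse",
) -> pd.DataFrame:
    """Random drug x gene profiles plus one exact inverse of ``query``.

    The library gene universe contains every query gene (padded with
    extra genes up to ``n_genes``); the planted drug carries the negated
    query weights with near-zero values elsewhere, so it should reverse
    the query signature more strongly than any random profile.
    """
    rng = np.random.default_rng(seed)
    genes = list(query.index)
    genes += [f"lib_gene{i}" for i in range(max(0, n_genes - len(genes)))]
    profiles = pd.DataFrame(
        rng.normal(size=(n_drugs, len(genes))),
        index=[f"drug{i:03d}" for i in range(n_drugs)],
        columns=genes,
    )
    planted = pd.Series(rng.normal(0.0, 0.01, len(genes)), index=genes)
    scale = np.abs(query).mean() or 1.0
    planted[query.index] = -query / scale * 3.0
    profiles.loc[planted_id] = planted
    return profiles
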