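"""Synthetic lineage-tracing experiments with known ground truth.

The generative model mirrors the experimental design: uniquely barcoded,
synchronized cells divide exactly once; the two daughters are split at
random between a profiled (pre-treatment) half and a treated half; drug
treatment kills a target fraction of treated cells as a function of a
latent, lineage-level resistance program; surviving lineages are
re-detected in the post-treatment sample.  A vehicle-control arm is
generated the same way with survival driven by a latent growth-fitness
program instead.

Expression model (per gene g, cell c of lineage l):

    log mu_gc = b_g + sigma_bio * ( sqrt(h_g) * L_gl + sqrt(1 - h_g) * e_gc )
                + ln(2) * resistance_effect * r_l   [resistance genes]
                + ln(2) * fitness_effect   * f_l    [fitness genes]

with b_g a log-normal gene baseline, L_gl a lineage-shared factor, e_gc
per-cell noise (all standard normal), and h_g the heritability — the
share of biological log-variance shared between sisters.  Counts are
negative-binomial around depth-scaled softmax means.  Treated-cell
survival is Bernoulli with a logistic link in the latent score; the
intercept is solved numerically so the expected death rate equals
``kill_fraction``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .barcodes import DEFAULT_TEMPLATE, FULL_TEMPLATE, BarcodeTemplate

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "generate_barcode_library",
    "simulate_experiment",
    "corrupt_reads",
    "simulate_dose_response",
]

_BASES = np.array(list("ACGT"))


def generate_barcode_library(n_lineages: int, seed: int) -> dict[int, str]:
    """Draw ``n_lineages`` distinct 20-mer lineage labels over {A,C,G,T}.

    Collisions are resampled; more than 4^20 lineages cannot be uniquely
    labeled and raise.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    if n_lineages > 4**20:
        raise ValueError("cannot draw more than 4^20 unique 20-mers")
    rng = np.random.default_rng(seed)
    labels: dict[str, None] = {}
    while len(labels) < n_lineages:
        draw = rng.integers(0, 4, size=(n_lineages - len(labels), 20))
        for row in draw:
            labels.setdefault("".join(_BASES[row]), None)
    return dict(enumerate(labels))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    n_lineages: int = 2000
    n_genes: int = 2000
    heritability: float | np.ndarray = 0.6
    n_resistance_genes: int = 0
    resistance_effect: float = 0.0  # log2 shift per unit resistance score
    n_fitness_genes: int = 0
    fitness_effect: float | None = None  # defaults to resistance_effect
    kill_fraction: float = 0.70
    control_kill_fraction: float = 0.5
    survival_slope: float = 2.0
    mean_depth: float = 20000.0
    dispersion: float = 10.0  # negative-binomial size (larger = less overdispersed)
    biological_sd: float = 0.5  # natural-log scale
    baseline_sd: float = 1.0
    library_sd: float = 0.2
    barcode_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1 or self.n_genes < 1:
            raise ValueError("n_lineages and n_genes must be positive")
        h = np.asarray(self.heritability, dtype=float)
        if h.ndim not in (0, 1) or (h.ndim == 1 and h.size != self.n_genes):
            raise ValueError("heritability must be a scalar or length-n_genes vector")
        if np.any(h < 0) or np.any(h > 1):
            raise ValueError("heritability must lie in [0, 1]")
        for name in ("kill_fraction", "control_kill_fraction", "barcode_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_resistance_genes < 0 or self.n_fitness_genes < 0:
            raise ValueError("gene-program sizes must be non-negative")
        if self.n_resistance_genes + self.n_fitness_genes > self.n_genes:
            raise ValueError("resistance + fitness genes exceed n_genes")
        if self.resistance_effect < 0:
            raise ValueError("resistance_effect must be non-negative")
        if min(self.mean_depth, self.dispersion) <= 0:
            raise ValueError("mean_depth and dispersion must be positive")
        if self.fitness_effect is None:
            self.fitness_effect = self.resistance_effect


@dataclass
class GroundTruth:
    """Latent state of a simulated experiment, for validation only."""

    resistance_genes: list[str]
    fitness_genes: list[str]
    lineages: pd.DataFrame  # arm, lineage, label, resistance/fitness score, survived
    true_labels: dict[str, str]  # cell_id -> 20-mer, both arms' pre cells

    def labels_for_arm(self, arm: str) -> pd.DataFrame:
        return self.lineages[self.lineages["arm"] == arm]


@dataclass
class SimulatedExperiment:
    pre: ad.AnnData
    post: ad.AnnData
    control_pre: ad.AnnData
    control_post: ad.AnnData
    truth: GroundTruth
    config: SimulationConfig

    @property
    def arms(self) -> dict[str, tuple[ad.AnnData, ad.AnnData]]:
        return {
            "treatment": (self.pre, self.post),
            "control": (self.control_pre, self.control_post),
        }


def _solve_survival_intercept(
    scores: np.ndarray, slope: float, kill_fraction: float
) -> float:
    """Intercept a with mean(sigmoid(a + slope*score)) == 1 - kill_fraction."""
    target = 1.0 - kill_fraction
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(mid + slope * scores)))
        if p.mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    """Gamma-Poisson draw: mean mu, variance mu + mu^2/size."""
    lam = rng.gamma(shape=size, scale=mu / size)
    return rng.poisson(lam).astype(np.int32)


def _simulate_counts(
    rng: np.random.Generator,
    log_mu: np.ndarray,
    mean_depth: float,
    dispersion: float,
    library_sd: float,
) -> np.ndarray:
    props = np.exp(log_mu - log_mu.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    lib = np.exp(rng.normal(0.0, library_sd, size=(props.shape[0], 1)))
    return _nb_counts(rng, mean_depth * lib * props, dispersion)


def _make_adata(
    counts: np.ndarray,
    cell_ids: list[str],
    sample: str,
    labels: list[str],
    lineages: np.ndarray,
    gene_names: list[str],
) -> ad.AnnData:
    obs = pd.DataFrame(
        {"sample": sample, "label": labels, "lineage": lineages},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=gene_names))
    adata.layers["counts"] = counts.copy()
    return adata


def _simulate_arm(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    arm: str,
    labels: Mapping[int, str],
    baseline: np.ndarray,
    sqrt_h: np.ndarray,
    sqrt_1mh: np.ndarray,
    res_idx: np.ndarray,
    fit_idx: np.ndarray,
    gene_names: list[str],
    kill_fraction: float,
) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame, dict[str, str]]:
    n_lin, n_genes = cfg.n_lineages, cfg.n_genes
    r = rng.standard_normal(n_lin)  # resistance score
    f = rng.standard_normal(n_lin)  # growth-fitness score
    lineage_factor = rng.standard_normal((n_lin, n_genes))

    shift = np.zeros((n_lin, n_genes))
    shift[:, res_idx] += np.log(2) * cfg.resistance_effect * r[:, None]
    shift[:, fit_idx] += np.log(2) * cfg.fitness_effect * f[:, None]
    lineage_mean = (
        baseline[None, :] + cfg.biological_sd * sqrt_h * lineage_factor + shift
    )

    # one division -> two daughters; independent coin flips split them
    to_pre = rng.random((n_lin, 2)) < 0.5
    score = r if arm == "treatment" else f
    intercept = _solve_survival_intercept(score, cfg.survival_slope, kill_fraction)
    with np.errstate(over="ignore"):
        p_survive = 1.0 / (1.0 + np.exp(-(intercept + cfg.survival_slope * score)))
    survived_cell = (rng.random((n_lin, 2)) < p_survive[:, None]) & ~to_pre

    def _cells(mask: np.ndarray, tag: str) -> tuple[ad.AnnData, np.ndarray]:
        lin_ids, _ = np.nonzero(mask)
        noise = rng.standard_normal((lin_ids.size, n_genes))
        log_mu = lineage_mean[lin_ids] + cfg.biological_sd * sqrt_1mh * noise
        counts = _simulate_counts(
            rng, log_mu, cfg.mean_depth, cfg.dispersion, cfg.library_sd
        )
        prefix = "T" if arm == "treatment" else "C"
        cell_ids = [f"{prefix}_{tag}_{i:05d}" for i in range(lin_ids.size)]
        adata = _make_adata(
            counts,
            cell_ids,
            f"{'treat' if arm == 'treatment' else 'ctrl'}_{tag}",
            [labels[l] for l in lin_ids],
            lin_ids,
            gene_names,
        )
        return adata, lin_ids

    pre_adata, _ = _cells(to_pre, "pre")
    post_adata, _ = _cells(survived_cell, "post")

    lineage_survived = survived_cell.any(axis=1)
    lin_table = pd.DataFrame(
        {
            "arm": arm,
            "lineage": np.arange(n_lin),
            "label": [labels[l] for l in range(n_lin)],
            "resistance_score": r,
            "fitness_score": f,
            "n_pre_cells": to_pre.sum(axis=1),
            "n_treated_cells": (~to_pre).sum(axis=1),
            "n_surviving_cells": survived_cell.sum(axis=1),
            "survived": lineage_survived,
        }
    )
    true_labels = dict(zip(pre_adata.obs_names, pre_adata.obs["label"]))
    return pre_adata, post_adata, lin_table, true_labels


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Simulate paired treatment and vehicle-control arms.

    Each arm draws its own lineages from a shared barcode library (so
    labels never collide across arms by construction, matching the
    per-arm uniqueness the design assumes).  Returns the four count
    matrices (pre/post x treatment/control) and the ground truth.
    """
    cfg = config
    if cfg.kill_fraction in (0.0, 1.0):
        warnings.warn(
            f"kill_fraction={cfg.kill_fraction} yields a degenerate fate partition"
        )
    rng = np.random.default_rng(cfg.seed)
    library = generate_barcode_library(2 * cfg.n_lineages, rng.integers(2**31))
    treat_labels = {i: library[i] for i in range(cfg.n_lineages)}
    ctrl_labels = {i: library[cfg.n_lineages + i] for i in range(cfg.n_lineages)}

    gene_names = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_genes)
    h = np.broadcast_to(np.asarray(cfg.heritability, float), (cfg.n_genes,))
    sqrt_h, sqrt_1mh = np.sqrt(h), np.sqrt(1.0 - h)

    program = rng.permutation(cfg.n_genes)
    res_idx = np.sort(program[: cfg.n_resistance_genes])
    fit_idx = np.sort(
        program[cfg.n_resistance_genes : cfg.n_resistance_genes + cfg.n_fitness_genes]
    )

    pre, post, treat_lin, treat_map = _simulate_arm(
        rng, cfg, "treatment", treat_labels, baseline, sqrt_h, sqrt_1mh,
        res_idx, fit_idx, gene_names, cfg.kill_fraction,
    )
    cpre, cpost, ctrl_lin, ctrl_map = _simulate_arm(
        rng, cfg, "control", ctrl_labels, baseline, sqrt_h, sqrt_1mh,
        res_idx, fit_idx, gene_names, cfg.control_kill_fraction,
    )

    truth = GroundTruth(
        resistance_genes=[gene_names[i] for i in res_idx],
        fitness_genes=[gene_names[i] for i in fit_idx],
        lineages=pd.concat([treat_lin, ctrl_lin], ignore_index=True),
        true_labels={**treat_map, **ctrl_map},
    )
    return SimulatedExperiment(pre, post, cpre, cpost, truth, cfg)


def corrupt_reads(
    cell_labels: Mapping[str, str],
    reads_per_cell: int,
    barcode_error_rate: float,
    seed: int,
    template: BarcodeTemplate = FULL_TEMPLATE,
    corrupt_anchors: bool = False,
) -> pd.DataFrame:
    """Emit noisy template reads for each cell's true label.

    Each read is the full construct with the cell's informative bases;
    every informative base is substituted independently with probability
    ``barcode_error_rate`` (anchor/flank bases too when
    ``corrupt_anchors``).  Returns a DataFrame (cell_id, read).
    """
    if not 0.0 <= barcode_error_rate <= 0.25:
        raise ValueError("barcode_error_rate must lie in [0, 0.25]")
    rng = np.random.default_rng(seed)
    base_to_int = {b: i for i, b in enumerate("ACGT")}
    cells = list(cell_labels)
    seqs = np.array(
        [
            [base_to_int[b] for b in template.instantiate(cell_labels[c])]
            for c in cells
        ],
        dtype=np.int8,
    )
    n_cells, seq_len = seqs.shape
    reads = np.repeat(seqs, reads_per_cell, axis=0)
    hit = rng.random(reads.shape) < barcode_error_rate
    if not corrupt_anchors:
        mask = np.zeros(seq_len, dtype=bool)
        mask[list(template.informative_positions)] = True
        hit &= mask[None, :]
    # substitute with one of the three other bases, uniformly
    reads[hit] = (reads[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    base_arr = np.array(list("ACGT"))
    read_strs = ["".join(row) for row in base_arr[reads]]
    cell_ids = np.repeat(cells, reads_per_cell)
    return pd.DataFrame({"cell_id": cell_ids, "read": read_strs})


def _four_pl(d: np.ndarray, ymin: float, ymax: float, ec50: float, hill: float):
    d = np.asarray(d, dtype=float)
    out = np.full(d.shape, ymin, dtype=float)
    nz = d > 0
    out[nz] = ymin + (ymax - ymin) / (1.0 + (ec50 / d[nz]) ** hill)
    return out


def simulate_dose_response(
    model: Literal["bliss-null", "hsa-null", "additive-shift"],
    doses1: Sequence[float],
    doses2: Sequence[float],
    mono1: Mapping[str, float] | None = None,
    mono2: Mapping[str, float] | None = None,
    synergy_delta: float = 0.0,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    neg_control: float = 100.0,
    pos_control: float = 0.0,
) -> "pd.DataFrame":
    """Oracle dose-response surfaces on a known null model.

    Monotherapies follow 4-parameter logistic curves (percent inhibition);
    combination cells follow the named null plus ``synergy_delta``
    percentage points plus Gaussian noise on the readings.  Under
    ``additive-shift`` the two drugs share drug 1's curve shape and
    differ only in potency, which makes the surface exactly
    Loewe-additive.  Returns a long-format DataFrame
    (dose1, dose2, replicate, reading) with readings on the viability
    scale anchored at the given plate controls; attach it to
    :class:`resistrace.synergy.DoseResponse` for scoring.
    """
    doses1 = np.asarray(sorted(doses1), dtype=float)
    doses2 = np.asarray(sorted(doses2), dtype=float)
    for d in (doses1, doses2):
        if d[0] != 0.0 or (d > 0).sum() < 2:
            raise ValueError("each dose grid needs a zero dose plus >=2 doses")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    mono1 = dict(ymin=0.0, ymax=80.0, ec50=1.0, hill=1.5) | dict(mono1 or {})
    mono2 = dict(ymin=0.0, ymax=60.0, ec50=5.0, hill=1.2) | dict(mono2 or {})

    y1 = _four_pl(doses1, **mono1)
    y2 = _four_pl(doses2, **mono2)
    grid1, grid2 = np.meshgrid(doses1, doses2, indexing="ij")
    if model == "bliss-null":
        f1, f2 = y1[:, None] / 100.0, y2[None, :] / 100.0
        truth = 100.0 * (f1 + f2 - f1 * f2)
    elif model == "hsa-null":
        truth = np.maximum(y1[:, None], y2[None, :])
    elif model == "additive-shift":
        rho = mono1["ec50"] / mono2["ec50"]  # relative potency of drug 2
        truth = _four_pl(grid1 + rho * grid2, **mono1)
    else:
        raise ValueError(f"unknown null model: {model}")
    combo = (grid1 > 0) & (grid2 > 0)
    truth = truth + synergy_delta * combo

    rng = np.random.default_rng(seed)
    rows = []
    for i, d1 in enumerate(doses1):
        for j, d2 in enumerate(doses2):
            reading = neg_control - truth[i, j] / 100.0 * (neg_control - pos_control)
            for rep in range(replicates):
                rows.append(
                    (d1, d2, rep, reading + rng.normal(0.0, noise_sd))
                )
    return pd.DataFrame(rows, columns=["dose1", "dose2", "replicate", "reading"])
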