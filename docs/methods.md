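# Methods

This note documents the models, statistics, and numerical choices behind
each pipeline stage, the generative model used for validation, and what
the synthetic results do and do not demonstrate.

## Barcode recovery

Lineage labels are 20 random bases embedded in a fixed construct whose
anchor dinucleotides (CA, TG, AC, GA, GT, CT) bracket five 4-base
informative blocks.  Extraction matches the anchor sub-pattern exactly
(first match, both orientations by default) and concatenates the
informative positions.  Anchors are not fuzzy-matched: a read whose
anchor bases are corrupted is dropped rather than guessed at, because
the downstream directional correction already absorbs single-base errors
in the informative positions, and fuzzy anchors would admit spurious
template matches at a rate that grows with read length.

Error correction follows the directional network method used for UMI
deduplication: a directed edge a→b exists when Hamming(a, b) = 1 and
count(a) ≥ 2·count(b) − 1; nodes are visited in decreasing count order
(ties broken lexicographically) and each unassigned node seeds a cluster
that absorbs everything reachable along directed edges.  This is the
"directional" clustering semantics (chains a→b→c collapse to the
highest-count root) and is the single supported variant.  Counts feeding
the rule are per-sample read totals per label; the per-cell consensus
label is the corrected label with the highest read count in that cell,
with ties left unlabeled — the conservative choice, since a two-way tie
most often means a doublet or a chimeric read.  Labels carried by more
than four cells in a pre-treatment sample are removed outright (all
carrier cells), as such promiscuous labels cannot identify a lineage.

## Fate partition

A pre-treatment cell is pre-resistant (pre-fit in the vehicle arm) iff
its corrected label appears among post-treatment labels; detection is a
set-membership test with no abundance threshold, since re-detection of a
lineage, not its expansion, is the evidence of survival.  Differential
analyses use only singleton-lineage cells — cells whose sister was not
also profiled — to avoid pairs of half-weight pseudo-replicates.
Sister pairs for the concordance analysis come only from labels carried
by exactly two cells.

## QC, normalization, variable genes

Default per-cell QC intervals: UMI [20000, 200000] and detected genes
[2500, 12000] for pre-treatment samples, [10000, 100000] and
[2000, 10000] for post-treatment; both interval bounds inclusive.  The
mitochondrial bound (fraction < 0.15, genes matched by the configurable
symbol prefix "MT-") is strict.  Genes expressed in fewer than three
cells are removed.  Normalization is depth scaling to 10⁴ followed by
log1p; zero counts map to zero.

Variable genes are ranked by a variance-stabilized statistic: per-gene
count variance is regressed on the mean by lowess in log10 space
(span 0.3), counts are standardized by the trend-expected standard
deviation, clipped at √N, and the variance of the clipped values is the
ranking statistic.  The clip bounds the influence of single outlier
cells.  With very few genes an isolated high-mean gene has high leverage
on the lowess trend and can absorb its own excess variance; the selector
is intended for matrices with hundreds of genes or more, where the trend
is dominated by the bulk.

## Sister concordance

Similarity uses Euclidean distance over the top 1000 variable genes of
the normalized matrix.  Random pairs are sampled uniformly without
replacement from the non-sister pairs (default 100 000; exhaustive
enumeration when fewer exist).  Two data-driven quantile filters are
recomputed per dataset, never hard-coded: genes below the 10% quantile
of total normalized expression are removed (ties at the cutoff kept,
linear-interpolation quantile), and sister pairs above the 90% quantile
of the sister-distance distribution are discarded as likely
mis-assignments.

Per gene, the within-pair effect is |log₂((eₐ + 1)/(e_b + 1))| on
expm1-scale normalized expression.  The absolute value is used because
pairs are unordered, so a signed fold change is ill-defined; the
pseudocount of 1 (configurable) avoids infinities at zeros.  Sister and
random distributions are compared by a two-tailed Welch t-test
(unequal variances, since the two pools differ in size and spread), with
Benjamini–Hochberg adjustment across genes; a gene is concordant iff
adjusted P < 0.05 and the sister mean is the smaller one.  Genes with no
variance in either pool receive t = 0, P = 1 rather than being dropped.

## Signatures and specificity

Differential expression is a two-sided Wilcoxon rank-sum test on
normalized values with no fold-change or detection thresholds; SciPy's
implementation selects the exact null distribution for tiny tie-free
groups and the tie-corrected normal approximation otherwise.  log₂FC
compares group means of expm1-scale expression with pseudocount 1,
matching the concordance statistic for internal consistency; positive
means higher in pre-resistant (or pre-fit).

The specificity statistic per gene is Δ = log₂FC(resistant vs
sensitive) − log₂FC(fit vs unfit).  Two resampling schemes assess it:

- **bootstrap** — cells resampled with replacement within each of the
  four groups; P = (+1-corrected) fraction of bootstrap Δ ≤ 0,
  one-sided, appropriate for genes reported as specifically
  *up*-regulated;
- **permutation** — fate labels shuffled within each arm; P =
  (+1-corrected) fraction of permuted |Δ| ≥ observed |Δ|, two-sided.

Both default to 1000 resamples and are seeded.  A gene is *specific*
iff its DE adjusted P < 0.05, both resampling P < 0.05, and Δ > 0.
These constructions are this package's documented defaults; other
resampling units (e.g. residual bootstrap) are deliberate non-goals.

Four query signature variants are assembled, all restricted to
sister-concordant genes: (1) full pre-resistance log₂FC; (2) restricted
to Wilcoxon P < 0.05; (3) the contrast Δ; (4) the contrast restricted
to bootstrap P < 0.05.  Variants 2 and 4 are subsets of 1 and 3 by
construction.

## Connectivity scoring

The query is split into up (log₂FC > 0) and down (log₂FC < 0) sets and
each is scored against a drug's descending-value gene ranking with a
weighted Kolmogorov–Smirnov enrichment statistic (hit increments
∝ |stat|^w, default w = 1; misses step down uniformly; score is the
signed extremum of the running sum).  For two-sided queries the
connectivity score is (ES_up − ES_down)/2 when the two enrichments have
opposite signs and 0 otherwise.  For one-sided queries — variant 4
contains only up-regulated genes — that combination rule would return 0
identically, so the score falls back to the single set's enrichment
alone.  P-values permute the gene labels of the drug profile (the query
sets land on random rank positions), two-sided on |score| with a
+1/(n+1) correction.  Query genes absent from a drug profile are
dropped per pair with a logged count; fewer than 10 overlapping genes is
an error.  A candidate pre-sensitizer must score negative with P < 0.05
in all four variants; drugs are reported in ascending mean-score order.

## Synergy scoring

Raw readings are anchored linearly to the plate controls:
inhibition% = 100·(neg − reading)/(neg − pos).  This two-control
anchoring is the standard normalization for luminescent viability
readouts; values outside [0, 100] are flagged but not clipped.
Reference models, all in percentage points over the nonzero–nonzero
dose cells:

- **HSA**: observed − max(monotherapy₁, monotherapy₂);
- **Bliss**: observed − (y₁ + y₂ − y₁y₂) on fractions;
- **Loewe**: monotherapies fitted by 4-parameter logistic curves;
  the expected response solves d₁/D₁(y) + d₂/D₂(y) = 1 by bisection
  (tolerance 1e−6 on the response scale); non-bracketing cells fall
  back to the nearer asymptote and are flagged;
- **ZIP**: the Bliss-form expectation is computed from the fitted
  monotherapy curves, and the observed surface is smoothed by refitting
  each row and column as a potency-shift logistic anchored at the
  partner drug's fitted effect and saturating at 100%; the delta is the
  average of the two conditional fits minus the expectation.

4PL fits use constrained least squares with endpoint/median-dose
initialization; a decreasing curve is represented by ymax < ymin rather
than a negative slope, and Bliss treats these models on the fraction
scale after clipping fitted values to [0, 1].  Noise-free null surfaces
of each model score |mean| < 1 point under their own model.

Bootstrap significance resamples replicate readings within each dose
cell (the replicate is the resampling unit; the cited scoring tool's
unit is unstated, so this choice is documented rather than claimed).
P is twice the +1-corrected fraction of bootstrap means on the opposite
side of zero, capped at 1; an exactly-zero observed mean returns P = 1.
The default 10 iterations mirrors common practice but bounds P below at
2/11, so the CLI recommends ≥ 1000.  A combination is called
synergistic iff the mean score is ≥ 5 (inclusive).

## The generative model

The simulator emulates the experimental design so every stage can be
validated against known ground truth:

- each of n_lineages cells divides once; the two daughters enter the
  profiled vs treated half by independent fair coin flips, so singleton
  and two-sister pre-treatment lineages arise naturally;
- per gene g and cell c of lineage l, the log mean is
  b_g + σ_bio·(√h_g·L_gl + √(1−h_g)·ε_gc) plus ln2·effect·score on
  program genes, with b_g ~ N(0, 1), L and ε standard normal, and h_g
  the heritability (scalar or per-gene vector) — the share of
  biological log-variance shared between sisters;
- counts are negative-binomial (gamma–Poisson, size 10) around
  depth-scaled softmax means with log-normal library sizes (sd 0.2);
- treated-cell survival is Bernoulli with a logistic link in the
  lineage's latent score (slope 2.0); the intercept is solved by
  bisection so the expected death rate equals kill_fraction (default
  0.70).  The treatment arm's survival depends on the resistance score,
  the control arm's on an independent growth-fitness score (control
  kill 0.5 by default, representing sampling/growth loss in the vehicle
  arm);  both scores shift expression in both arms, only survival links
  differ;
- survivors are re-profiled with fresh cell-level noise (regrowth
  re-detects lineages without modeling clone expansion);
- reads are the full construct with each informative base substituted
  independently at the configured error rate (default 0.01).

Defaults σ_bio = 0.5 (natural log), baseline sd 1.0, mean depth 20000
were chosen once as typical of moderately deep droplet scRNA-seq and a
heterogeneous cell line; they are config fields, not tuning knobs.

**What the simulation does not capture**: ambient RNA, doublets,
cell-cycle structure, clone expansion bias, mutation acquisition, and
batch effects are all absent, and heritability is imposed as a single
shared factor rather than arising from chromatin state.  Passing the
validation suite therefore demonstrates that the statistics are
correctly implemented and calibrated under the stated model — not that
the biological conclusions transfer to any particular dataset.

## Problem sizes used in validation

The test suite and acceptance script run the pipeline at reduced but
statistically meaningful scale, chosen as the smallest sizes at which
the calibration targets are stable: 2000 lineages for barcode recovery
and kill calibration, 600–800 lineages for distance statistics,
2000 lineages / 1000 genes for concordance power at ~500 sister pairs,
and 1500 lineages / 2000 genes / 200-gene programs for signature
recovery.  End-to-end runs complete in seconds to tens of seconds per
seed on one CPU.

## Known limitations

- The directional correction assumes substitution errors only; indels
  shift the anchor frame and such reads are dropped at extraction.
- The Loewe and ZIP models require ≥ 3 nonzero monotherapy doses for
  curve fitting and degrade on very flat monotherapies (fallbacks are
  flagged, not silent).
- The connectivity P-value permutes gene labels of the drug profile;
  it does not model inter-gene correlation in the drug library.
- With n_boot = 10 the synergy bootstrap P has resolution 2/11 and is
  best read as a screen, not an inferential P-value.
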