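"""Lineage-label extraction and error correction.

Expressed lineage barcodes are 20 random bases embedded in a fixed
construct whose anchor dinucleotides (CA, TG, AC, GA, GT, CT) separate
five blocks of four informative bases.  This module finds the anchor
pattern in raw read sequences, collapses sequencing errors with the
directional network method used for UMI deduplication, assigns a
consensus label to each cell, and removes promiscuous labels shared by
too many cells.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: anchor sub-pattern: five N4 blocks separated by fixed dinucleotides
SUB_PATTERN = "CANNNNTGNNNNACNNNNGANNNNGTNNNNCT"

#: full barcode construct as integrated in the reference (flanks + sub-pattern)
FULL_CONSTRUCT = (
    "CTGGGGCACAAGCTTAATTAAGAATTCANNNNTGNNNNACNNNNGANNNNGTNNNNCT"
    "AGGGCCTAGAGGGCCCGTTTAAAC"
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodeTemplate:
    """Anchor template for locating the informative bases in a read.

    ``pattern`` is a string over {A,C,G,T,N} where N marks an informative
    position.  The default is the anchor sub-pattern of the lineage
    construct; `informative_positions` is derived and always has
    length 20 for the default.
    """

    pattern: str = SUB_PATTERN
    informative_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        pos = tuple(i for i, b in enumerate(self.pattern) if b == "N")
        object.__setattr__(self, "informative_positions", pos)
        if not pos:
            raise ValueError("template pattern contains no informative (N) positions")

    @property
    def label_length(self) -> int:
        return len(self.informative_positions)

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern.replace("N", "[ACGT]"))

    def instantiate(self, label: str) -> str:
        """Fill the N positions of the pattern with ``label``."""
        if len(label) != self.label_length:
            raise ValueError(
                f"label length {len(label)} != template capacity {self.label_length}"
            )
        seq = list(self.pattern)
        for base, i in zip(label, self.informative_positions):
            seq[i] = base
        return "".join(seq)


DEFAULT_TEMPLATE = BarcodeTemplate()
#: template spanning the whole integrated construct (flanks included)
FULL_TEMPLATE = BarcodeTemplate(FULL_CONSTRUCT)

_VALID_READ = re.compile(r"^[ACGTN]*$")


def extract_label(
    read: str,
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    search_revcomp: bool = True,
) -> str | None:
    """Extract the informative bases at the first exact anchor match.

    Returns the concatenated N-block bases (the lineage label), or None
    when the anchors are absent in both orientations.  Reads containing
    characters outside {A,C,G,T,N} are rejected with a warning.
    """
    if not _VALID_READ.match(read):
        warnings.warn(f"read contains non-ACGTN characters, rejected: {read[:40]}...")
        return None
    rx = template.regex
    m = rx.search(read)
    if m is None and search_revcomp:
        m = rx.search(reverse_complement(read))
    if m is None:
        return None
    window = m.group(0)
    return "".join(window[i] for i in template.informative_positions)


def count_labels(
    reads: Iterable[tuple[str, str]],
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    search_revcomp: bool = True,
) -> pd.DataFrame:
    """Tabulate raw labels per cell from (cell_id, sequence) reads.

    Returns a LabelCountTable: DataFrame with columns
    ``cell_id, label, count`` (one row per observed cell/label pair).
    Reads without an anchor match are dropped.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for cell_id, seq in reads:
        label = extract_label(seq, template, search_revcomp=search_revcomp)
        if label is not None:
            counts[(cell_id, label)] += 1
    if not counts:
        return pd.DataFrame(columns=["cell_id", "label", "count"])
    rows = [(c, l, n) for (c, l), n in counts.items()]
    return pd.DataFrame(rows, columns=["cell_id", "label", "count"])


def _hamming1_pairs(labels: list[str]) -> set[tuple[str, str]]:
    """All unordered pairs of labels at Hamming distance exactly 1.

    Uses per-position masking so runtime is O(n * L) expected rather
    than O(n^2 * L).
    """
    pairs: set[tuple[str, str]] = set()
    length = len(labels[0])
    for pos in range(length):
        buckets: dict[str, list[str]] = defaultdict(list)
        for lab in labels:
            buckets[lab[:pos] + lab[pos + 1 :]].append(lab)
        for mates in buckets.values():
            if len(mates) > 1:
                for i in range(len(mates)):
                    for j in range(i + 1, len(mates)):
                        a, b = mates[i], mates[j]
                        if a != b:
                            pairs.add((a, b) if a < b else (b, a))
    return pairs


def correct_directional(label_counts: Mapping[str, int]) -> dict[str, str]:
    """Collapse sequencing errors with the directional network method.

    A directed edge a -> b exists iff Hamming(a, b) == 1 and
    count(a) >= 2 * count(b) - 1.  Nodes are visited in decreasing count
    order (ties broken lexicographically); each unassigned node seeds a
    cluster and absorbs every unassigned node reachable along directed
    edges.  Returns the raw -> corrected label mapping (idempotent: the
    corrected labels map to themselves).
    """
    if not label_counts:
        raise ValueError("empty label count map")
    labels = list(label_counts)
    lengths = {len(l) for l in labels}
    if len(lengths) != 1:
        raise ValueError(f"labels of unequal length: {sorted(lengths)}")
    if any(n <= 0 for n in label_counts.values()):
        raise ValueError("label counts must be positive")

    adjacency: dict[str, list[str]] = defaultdict(list)
    for a, b in _hamming1_pairs(labels):
        ca, cb = label_counts[a], label_counts[b]
        if ca >= 2 * cb - 1:
            adjacency[a].append(b)
        if cb >= 2 * ca - 1:
            adjacency[b].append(a)

    order = sorted(labels, key=lambda l: (-label_counts[l], l))
    mapping: dict[str, str] = {}
    for root in order:
        if root in mapping:
            continue
        mapping[root] = root
        stack = [root]
        while stack:
            node = stack.pop()
            for nbr in sorted(adjacency.get(node, ())):
                if nbr not in mapping:
                    mapping[nbr] = root
                    stack.append(nbr)
    return mapping


def apply_correction(table: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Replace raw labels by their corrected representative and re-aggregate."""
    out = table.copy()
    out["label"] = out["label"].map(mapping)
    if out["label"].isna().any():
        raise ValueError("correction mapping does not cover all labels in the table")
    return (
        out.groupby(["cell_id", "label"], as_index=False, sort=False)["count"].sum()
    )


def assign_cell_labels(
    table: pd.DataFrame, min_reads: int = 1
) -> dict[str, str]:
    """Per-cell consensus: the label with the highest read count.

    Requires the winning count to be >= ``min_reads``; cells whose top
    two labels tie are left unlabeled (absent from the result), as are
    cells with no matching reads.
    """
    assignments: dict[str, str] = {}
    for cell_id, grp in table.groupby("cell_id", sort=False):
        best = grp["count"].max()
        if best < min_reads:
            continue
        winners = sorted(grp.loc[grp["count"] == best, "label"])
        if len(winners) == 1:
            assignments[cell_id] = winners[0]
    return assignments


def filter_shared_labels(
    cell_labels: Mapping[str, str], max_cells: int = 4
) -> tuple[dict[str, str], dict[str, int]]:
    """Drop cells whose label is carried by more than ``max_cells`` cells.

    Labels observed in exactly ``max_cells`` cells are retained.  Returns
    the filtered map and a report {label: n_cells_removed}.
    """
    tally: dict[str, int] = defaultdict(int)
    for lab in cell_labels.values():
        tally[lab] += 1
    removed = {lab: n for lab, n in tally.items() if n > max_cells}
    kept = {c: l for c, l in cell_labels.items() if l not in removed}
    return kept, removed


def extract_cell_labels(
    reads: Iterable[tuple[str, str]],
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    min_reads: int = 1,
    max_shared: int | None = 4,
    search_revcomp: bool = True,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Full read -> cell-label pipeline: extract, correct, assign, filter.

    Returns (cell -> label map, corrected LabelCountTable).  Set
    ``max_shared=None`` to skip the promiscuous-label filter (e.g. for
    post-treatment samples where only label presence matters).
    """
    raw = count_labels(reads, template, search_revcomp=search_revcomp)
    if raw.empty:
        return {}, raw
    totals = raw.groupby("label")["count"].sum().to_dict()
    mapping = correct_directional(totals)
    corrected = apply_correction(raw, mapping)
    cells = assign_cell_labels(corrected, min_reads=min_reads)
    if max_shared is not None:
        cells, _ = filter_shared_labels(cells, max_cells=max_shared)
    return cells, corrected
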