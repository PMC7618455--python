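"""Fate partitioning and sister-pair enumeration from lineage labels.

A pre-treatment cell whose label is re-detected among post-treatment
survivors is pre-resistant (pre-fit in the vehicle-control arm);
otherwise it is pre-sensitive (pre-unfit).  Cells sharing a label within
one treatment group are sisters — daughters of the same barcoded cell.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from itertools import combinations
from typing import Collection, Mapping

import pandas as pd

ARM_FATES = {
    "treatment": ("pre_resistant", "pre_sensitive"),
    "control": ("pre_fit", "pre_unfit"),
}


def assign_fates(
    pre_labels: Mapping[str, str],
    post_labels: Collection[str],
    arm: str = "treatment",
) -> pd.DataFrame:
    """Label-match pre-treatment cells against post-treatment survivors.

    Returns a FatePartition table (cell_id, label, fate).  Labels present
    only post-treatment are ignored; presence is a pure set-membership
    test with no abundance threshold.
    """
    if arm not in ARM_FATES:
        raise ValueError(f"arm must be one of {sorted(ARM_FATES)}")
    if not pre_labels:
        raise ValueError("empty pre-treatment cell->label map")
    surviving, lost = ARM_FATES[arm]
    post_set = set(post_labels)
    rows = [
        (cell, lab, surviving if lab in post_set else lost)
        for cell, lab in pre_labels.items()
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "label", "fate"])
    return df


def fate_lineage_counts(partition: pd.DataFrame) -> dict[str, int]:
    """Number of distinct lineages per fate class."""
    return partition.groupby("fate")["label"].nunique().to_dict()


def singleton_cells(pre_labels: Mapping[str, str]) -> set[str]:
    """Cells whose label occurs exactly once in the pre-treatment sample.

    These are the cells lacking a profiled sister; differential analyses
    are run on them to avoid the half-lineage double counting that arises
    when both sisters land in the profiled half.
    """
    tally = Counter(pre_labels.values())
    return {cell for cell, lab in pre_labels.items() if tally[lab] == 1}


def sister_pairs(
    pre_labels: Mapping[str, str] | pd.DataFrame,
    two_sisters_only: bool = True,
) -> pd.DataFrame:
    """Enumerate unordered pairs of cells sharing a lineage label.

    Accepts a cell->label map or a pooled DataFrame with ``cell_id`` and
    ``label`` columns (several pre-treatment samples pooled within a
    treatment group).  With ``two_sisters_only`` (the concordance-analysis
    setting) only labels carried by exactly two cells yield a pair;
    otherwise all within-label pairs are emitted.
    """
    if isinstance(pre_labels, pd.DataFrame):
        items = list(zip(pre_labels["cell_id"], pre_labels["label"]))
    else:
        items = list(pre_labels.items())
    by_label: dict[str, list[str]] = defaultdict(list)
    for cell, lab in items:
        by_label[lab].append(cell)
    rows = []
    for lab, cells in by_label.items():
        if len(cells) < 2:
            continue
        if two_sisters_only and len(cells) != 2:
            continue
        for a, b in combinations(sorted(cells), 2):
            rows.append((lab, a, b))
    return pd.DataFrame(rows, columns=["label", "cell_a", "cell_b"])
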