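"""Regulon-activity aggregation and metaprogram-specific TF selection.

Takes an externally produced binarized cells x regulons activity matrix (one
column per transcription-factor regulon, entries 0/1) and (1) aggregates it to
the proportion of active cells per cell subpopulation, (2) selects regulons
specific to a metaprogram: average relative activity above 0.5 there and at
least 50% greater than in every other metaprogram.  Regulon inference itself
(co-expression modules, motif pruning, per-cell binarization) is an input, not
computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RegulonActivityTable:
    """Metaprograms x regulons mean-activity proportions plus group sizes."""

    activity: pd.DataFrame
    group_sizes: pd.Series


def aggregate_activity(
    binary: pd.DataFrame, labels: pd.Series
) -> RegulonActivityTable:
    """Proportion of active cells per (metaprogram, regulon).

    ``binary`` must contain only 0/1; ``labels`` maps every cell to its
    metaprogram.
    """
    vals = binary.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("activity matrix must be binary")
    labels = labels.reindex(binary.index)
    if labels.isna().any():
        raise ValueError("labels must cover all cells")
    grouped = binary.groupby(labels, observed=True)
    return RegulonActivityTable(grouped.mean(), grouped.size().rename("n_cells"))


def select_specific_tfs(
    table: RegulonActivityTable,
    min_activity: float = 0.5,
    min_ratio: float = 1.5,
) -> dict[str, list[str]]:
    """Regulons specific to each metaprogram.

    A regulon is selected for metaprogram m iff its activity there strictly
    exceeds ``min_activity`` and is at least ``min_ratio`` times its activity
    in every other metaprogram.  With ``min_ratio`` > 1 a regulon can be
    specific to at most one metaprogram.
    """
    act = table.activity
    if act.shape[0] < 2:
        warnings.warn("single metaprogram: specificity ratio rule is vacuous")
    out: dict[str, list[str]] = {m: [] for m in act.index}
    for reg in act.columns:
        col = act[reg]
        for m in act.index:
            others = col.drop(m)
            if col[m] > min_activity and (
                others.empty or col[m] >= min_ratio * others.max()
            ):
                out[m].append(reg)
    return out
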