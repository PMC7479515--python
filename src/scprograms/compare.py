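"""Cross-program and cross-tumor comparison.

Three comparison operators: (1) pairwise Pearson correlation of program score
vectors over a shared cell set (with a hierarchical display ordering),
(2) correlation of population median expression profiles against reference
cell-type profiles restricted to pooled signature genes (restricting to
informative genes suppresses background correlation), and (3) a shared/specific
gene classification between two tumor types from aggregated log2 expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class ProgramCorrelation:
    """Symmetric programs x programs Pearson matrix plus dendrogram order."""

    matrix: pd.DataFrame
    order: list[str]


def correlate_program_scores(scores: pd.DataFrame) -> ProgramCorrelation:
    """Pairwise Pearson correlation of program scores over cells.

    Zero-variance score vectors yield NaN correlations (reported as missing).
    The dendrogram order comes from Ward linkage on 1 - r with NaNs treated as
    zero correlation.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = scores.corr()
    zero_var = scores.std(ddof=0) == 0
    if zero_var.any():
        logger.warning(
            "zero-variance score vectors: %s", list(scores.columns[zero_var])
        )
    filled = corr.fillna(0.0).to_numpy()
    np.fill_diagonal(filled, 1.0)
    if len(corr) > 1:
        dist = squareform(np.clip(1.0 - filled, 0.0, None), checks=False)
        order = [corr.columns[i] for i in leaves_list(linkage(dist, method="ward"))]
    else:
        order = list(corr.columns)
    return ProgramCorrelation(corr, order)


def correlate_profiles(
    population_profiles: pd.DataFrame,
    reference_profiles: pd.DataFrame,
    pooled_genes: list[str],
) -> pd.DataFrame:
    """Pearson correlation of population vs reference profiles on pooled genes.

    Both inputs are genes x profiles (columns = population / reference names).
    Genes missing from either side are dropped pairwise (logged); fewer than 3
    shared genes is an error.
    """
    shared = [
        g
        for g in pooled_genes
        if g in population_profiles.index and g in reference_profiles.index
    ]
    dropped = len(pooled_genes) - len(shared)
    if dropped:
        logger.info("dropped %d pooled genes missing from a profile set", dropped)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between profile sets")
    pop = population_profiles.loc[shared]
    ref = reference_profiles.loc[shared]
    out = pd.DataFrame(index=pop.columns, columns=ref.columns, dtype=float)
    for p in pop.columns:
        for r in ref.columns:
            out.loc[p, r] = np.corrcoef(pop[p], ref[r])[0, 1]
    return out


def shared_specific_genes(
    expr_a: pd.Series,
    expr_b: pd.Series,
    name_a: str = "A",
    name_b: str = "B",
    expr_min: float = 3.0,
    diff_min: float = 2.0,
) -> pd.DataFrame:
    """Classify genes as common / A-specific / B-specific / none.

    Inputs are aggregated log2 expression per gene in each tumor type.
    common: both above ``expr_min`` (this takes precedence even when the
    difference also exceeds ``diff_min``); X-specific: X above ``expr_min``
    and X - other above ``diff_min``; otherwise none.
    """
    genes = expr_a.index.intersection(expr_b.index)
    a, b = expr_a[genes], expr_b[genes]
    cls = pd.Series("none", index=genes, dtype=object)
    cls[(a > expr_min) & (a - b > diff_min)] = f"{name_a}-specific"
    cls[(b > expr_min) & (b - a > diff_min)] = f"{name_b}-specific"
    cls[(a > expr_min) & (b > expr_min)] = "common"
    return pd.DataFrame({name_a: a, name_b: b, "gene_class": cls})
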