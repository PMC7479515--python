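"""Control-gene-matched signature scoring and cell-state assignment.

The score of gene set G in cell i is

    SC(i) = mean Er(G, i) - mean Er(G_cont, i)

where the control set G_cont pools, for every gene in G, the 100 genes with
the most similar aggregate expression Ea (excluding the gene itself).  The
control set therefore mirrors the expression-level distribution of G while
being 100-fold larger, so a random gene set scores ~0 and scores are
comparable across expression regimes.

Cells are assigned to the metaprogram with their maximal score; a cell is
called cycling when the larger of its S-phase and G2M scores exceeds 1.  The
same threshold-free difference construction yields the neural-stem-cell (NSC)
score (NSC-like program score minus the maximum of the two differentiation
programs) and, for non-NSC-like cells, a lineage score separating the glial
from the ependymal trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, require_scale

logger = logging.getLogger(__name__)


def build_control_sets(
    ea: pd.Series, signature: list[str], n_control: int = 100
) -> dict[str, list[str]]:
    """For each signature gene, the ``n_control`` genes closest in Ea.

    Ties in |Ea difference| are broken by gene id; the query gene is never in
    its own control set.  If the universe holds fewer than ``n_control`` other
    genes, all of them are used.
    """
    ea = ea.sort_index()
    universe = ea.index
    controls: dict[str, list[str]] = {}
    for gene in signature:
        if gene not in universe:
            raise KeyError(f"signature gene {gene!r} absent from the gene universe")
        diff = (ea - ea[gene]).abs().drop(gene)
        order = diff.reset_index()
        order.columns = ["gene_id", "diff"]
        order = order.sort_values(["diff", "gene_id"], kind="stable")
        controls[gene] = order["gene_id"].head(n_control).tolist()
    return controls


def score_cells(
    er: ExpressionMatrix, signature: list[str], control_map: dict[str, list[str]]
) -> pd.Series:
    """SC per cell: mean Er over the signature minus mean over pooled controls.

    Controls of all signature genes are concatenated with multiplicity before
    averaging (the 100-fold-larger pooled construction).
    """
    require_scale(er, "centered")
    if not signature:
        raise ValueError("empty signature")
    present = [g for g in signature if g in er.gene_ids]
    if len(present) < len(signature):
        logger.info("%d signature genes absent from matrix", len(signature) - len(present))
    if not present:
        raise ValueError("no signature genes present in the matrix")
    pooled: list[str] = []
    for g in present:
        pooled.extend(control_map[g])
    vals = er.values
    sig_mean = vals[present].mean(axis=1)
    ctrl_mean = vals[pooled].mean(axis=1) if pooled else 0.0
    return (sig_mean - ctrl_mean).rename("SC")


def score_signatures(
    er: ExpressionMatrix,
    signatures: dict[str, list[str]],
    ea: pd.Series,
    n_control: int = 100,
) -> pd.DataFrame:
    """Score several signatures at once; returns cells x signatures."""
    out = {}
    for name, genes in signatures.items():
        genes = [g for g in genes if g in ea.index]
        ctrl = build_control_sets(ea, genes, n_control=n_control)
        out[name] = score_cells(er, genes, ctrl)
    return pd.DataFrame(out, index=er.cell_ids)


@dataclass
class CellStates:
    """Per-cell state table: assigned program, cycling flag, raw scores."""

    table: pd.DataFrame
    scores: pd.DataFrame


def assign_states(
    scores: pd.DataFrame,
    metaprogram_ids: list[str] | None = None,
    s_id: str = "S",
    g2m_id: str = "G2M",
    cyc_threshold: float = 1.0,
) -> CellStates:
    """Assign each cell to its maximal-score metaprogram and call cycling.

    Ties at the maximum are broken lexicographically by metaprogram id (and
    logged).  Cycling iff max(SC_S, SC_G2M) > ``cyc_threshold`` (strict); if
    either cycling signature is missing the call is left as NA.
    """
    if metaprogram_ids is None:
        metaprogram_ids = [c for c in scores.columns if c not in (s_id, g2m_id)]
    sub = scores[sorted(metaprogram_ids)]
    assigned = sub.idxmax(axis=1)  # idxmax returns the first (lexicographic) max
    n_ties = int((sub.eq(sub.max(axis=1), axis=0).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("%d cells had tied maximal scores; lexicographic tie-break", n_ties)

    if s_id in scores.columns and g2m_id in scores.columns:
        cycling = scores[[s_id, g2m_id]].max(axis=1) > cyc_threshold
    else:
        logger.warning("S/G2M signatures missing; cycling left undefined")
        cycling = pd.Series(pd.NA, index=scores.index, dtype="boolean")

    table = pd.DataFrame(
        {"metaprogram": assigned, "cycling": cycling, "max_score": sub.max(axis=1)}
    )
    return CellStates(table, scores)


def nsc_lineage(
    scores: pd.DataFrame, nsc_id: str, glial_id: str, ependymal_id: str
) -> pd.DataFrame:
    """NSC and lineage scores for a hierarchy rooted in an NSC-like program.

    nsc_score = SC_nsc - max(SC_glial, SC_ependymal); cells with nsc_score <= 0
    ("non-NSC-like") get lineage_score = SC_glial - SC_ependymal (positive
    toward the glial-progenitor trajectory, negative toward ependymal).
    """
    for pid in (nsc_id, glial_id, ependymal_id):
        if pid not in scores.columns:
            raise KeyError(f"missing program score {pid!r}")
    nsc = scores[nsc_id] - scores[[glial_id, ependymal_id]].max(axis=1)
    lineage = scores[glial_id] - scores[ependymal_id]
    lineage = lineage.where(nsc <= 0)
    return pd.DataFrame({"nsc_score": nsc, "lineage_score": lineage})
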