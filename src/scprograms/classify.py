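"""Malignant / normal / excluded cell classification.

CNA status alone misses CNA-quiet tumors and marker expression alone misses
ambiguous transcriptomes, so the two are integrated: cells cluster on relative
expression, clusters are labeled as normal cell types when their mean marker
score clears a threshold, and each cell's (cluster label, CNA call) pair maps
to a final class.  Discordant cells are excluded rather than guessed — except
in samples explicitly listed as CNA-quiet, where CNA-negative cells outside
normal clusters are rescued as malignant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix, require_scale

logger = logging.getLogger(__name__)


@dataclass
class CellAnnotation:
    """Final per-cell labels.

    ``table`` columns: ``cluster_id``, ``normal_type`` (NA when the cell's
    cluster has no normal label), ``cna_call``, ``final_class`` in
    {malignant, normal, excluded}, ``override_applied``.
    """

    table: pd.DataFrame

    def counts(self) -> pd.Series:
        return self.table["final_class"].value_counts()


def cluster_cells(
    er: ExpressionMatrix, n_pcs: int = 20, k: int = 8, seed: int = 0
) -> pd.Series:
    """K-means over the top principal components of relative expression."""
    require_scale(er, "centered")
    if k > er.n_cells:
        raise ValueError("more clusters requested than cells")
    x = er.values.to_numpy()
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs >= 1 and np.abs(x).sum() > 0:
        x = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    return pd.Series(km.labels_, index=er.cell_ids, name="cluster_id")


def label_normal_clusters(
    cluster_ids: pd.Series,
    marker_scores: pd.DataFrame,
    threshold: float = 1.0,
) -> dict[int, str]:
    """Label clusters with the normal cell type whose mean marker score wins.

    ``marker_scores`` is cells x normal-types (SC scores from the scoring
    module).  A cluster gets type T iff mean SC_T over its cells exceeds
    ``threshold`` and every other type's mean; a tie above threshold is
    resolved toward the larger mean (exact ties: lexicographic, logged).
    """
    labels: dict[int, str] = {}
    means = marker_scores.groupby(cluster_ids).mean()
    for cid, row in means.iterrows():
        best = row.max()
        if best > threshold:
            winners = sorted(row.index[row == best])
            if len(winners) > 1:
                logger.info("cluster %s: tie between %s; taking %s", cid, winners, winners[0])
            labels[int(cid)] = winners[0]
    return labels


def classify_cells(
    cluster_ids: pd.Series,
    cluster_labels: dict[int, str],
    cna_calls: pd.Series,
    sample_ids: pd.Series | None = None,
    override_samples=(),
) -> CellAnnotation:
    """Combine cluster labels and CNA calls into final classes.

    normal    = in a normal-labeled cluster AND CNA-negative;
    malignant = CNA-positive AND not in a normal-labeled cluster;
    otherwise discordant -> excluded, unless the cell's sample is in
    ``override_samples``: then CNA-negative cells outside normal clusters are
    treated as malignant (the CNA-quiet-sample rescue rule).
    """
    cells = cluster_ids.index
    if not cna_calls.index.equals(cells):
        cna_calls = cna_calls.reindex(cells)
    if cna_calls.isna().any():
        raise ValueError("cells missing a CNA call")
    override_samples = set(override_samples)
    if override_samples and sample_ids is None:
        raise ValueError("override_samples given but no sample_ids")

    rows = []
    for cell in cells:
        in_normal = int(cluster_ids[cell]) in cluster_labels
        ntype = cluster_labels.get(int(cluster_ids[cell]))
        pos = bool(cna_calls[cell])
        override = False
        if in_normal and not pos:
            cls = "normal"
        elif pos and not in_normal:
            cls = "malignant"
        else:
            cls = "excluded"
            if (
                not pos
                and not in_normal
                and sample_ids is not None
                and sample_ids[cell] in override_samples
            ):
                cls, override = "malignant", True
        rows.append(
            (int(cluster_ids[cell]), ntype if cls == "normal" else None, pos, cls, override)
        )
    table = pd.DataFrame(
        rows,
        index=cells,
        columns=["cluster_id", "normal_type", "cna_call", "final_class", "override_applied"],
    )
    return CellAnnotation(table)
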