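"""Copy-number inference from smoothed relative expression.

Genes are ordered along each chromosome and the relative expression Er
(clipped to +/-``cap`` to stop single-gene outliers mimicking dosage) is
averaged over a dense sliding window of ``window_size`` genes.  Chromosome-arm
gains and losses then appear as coherent shifts of the window profile.  CNA
status is called per sample by hierarchically clustering the window profiles of
query cells together with spike-in reference profiles from known non-malignant
cells: clusters that absorb at least half of the spike-ins anchor the
CNA-negative class, everything else is called CNA-positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .matrix import ExpressionMatrix, GeneAnnotation, require_scale

logger = logging.getLogger(__name__)


@dataclass
class CNAProfile:
    """Cells x windows moving-average matrix plus per-cell summary.

    ``window_index`` maps window id -> (chromosome, member gene ids).
    ``signal`` is the mean squared window value per cell, a label-free measure
    of how far a cell's profile departs from flat; note that with a mostly
    malignant cohort the centering baseline is itself malignant, so for
    calling, :func:`call_cna_status` re-baselines the signal against the
    spike-in reference mean.  ``cna_call`` is filled by the calling step.
    """

    window_values: pd.DataFrame
    window_index: dict[str, tuple[str, list[str]]]
    signal: pd.Series
    cna_call: pd.Series | None = None


def order_genes(annotation: GeneAnnotation) -> dict[str, list[str]]:
    """Per-chromosome gene lists, stably sorted by (chromosome, start).

    Genes lacking chromosome or position are excluded (counted in the log).
    """
    tab = annotation.table
    if tab.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    usable = tab.dropna(subset=["chromosome", "start"])
    n_dropped = len(tab) - len(usable)
    if n_dropped:
        logger.info("excluded %d genes without coordinates", n_dropped)
    ordered = usable.sort_values(["chromosome", "start"], kind="stable")
    return {
        chrom: list(sub.index) for chrom, sub in ordered.groupby("chromosome", sort=True)
    }


def compute_cna_profile(
    er: ExpressionMatrix,
    order: dict[str, list[str]],
    window_size: int = 100,
    cap: float = 3.0,
) -> CNAProfile:
    """Moving-average CNA profile of clipped relative expression.

    Window value = mean of Er clipped to [-cap, +cap] over ``window_size``
    consecutive genes within one chromosome, step 1.  A chromosome with fewer
    genes than ``window_size`` contributes a single window over all its genes.
    """
    require_scale(er, "centered")
    if not order:
        raise ValueError("empty chromosome set")
    clipped = er.values.clip(-cap, cap)

    cols, names, index = [], [], {}
    for chrom, genes in order.items():
        genes = [g for g in genes if g in er.gene_ids]
        if not genes:
            continue
        block = clipped[genes].to_numpy()
        if len(genes) < window_size:
            starts = [0]
            width = len(genes)
        else:
            starts = range(len(genes) - window_size + 1)
            width = window_size
        csum = np.cumsum(np.pad(block, ((0, 0), (1, 0))), axis=1)
        for s in starts:
            wid = f"{chrom}:{s}"
            cols.append((csum[:, s + width] - csum[:, s]) / width)
            names.append(wid)
            index[wid] = (chrom, genes[s : s + width])

    values = pd.DataFrame(np.column_stack(cols), index=er.cell_ids, columns=names)
    signal = (values**2).mean(axis=1).rename("cna_signal")
    return CNAProfile(values, index, signal)


def call_cna_status(
    profile: CNAProfile,
    reference_profiles: pd.DataFrame,
    k_clusters: int = 2,
    linkage_method: str = "ward",
) -> pd.DataFrame:
    """Call each query cell CNA-positive or CNA-negative.

    Query window profiles are pooled with spike-in ``reference_profiles``
    (same window columns) and hierarchically clustered on correlation distance
    (1 - Pearson).  The tree is cut into ``k_clusters``; a cluster anchors the
    CNA-negative class when it holds at least 50% of all spike-ins, or when
    spike-ins make up at least 50% of its members (so a flat cohort whose
    cells are indistinguishable from the references is all-negative no matter
    how the tree splits).

    Returns a DataFrame over query cells with ``cna_call`` (True =
    CNA-positive) and ``signal``, the mean squared deviation of the cell's
    windows from the reference mean profile — reported for every cell
    regardless of call.  The call is also stored on ``profile``.
    """
    missing = [c for c in profile.window_values.columns if c not in reference_profiles.columns]
    if missing:
        raise ValueError("reference profiles lack query windows; compute on the same gene order")
    if len(reference_profiles) < k_clusters:
        raise ValueError("fewer reference profiles than requested clusters")

    ref = reference_profiles[profile.window_values.columns]
    pooled = np.vstack([profile.window_values.to_numpy(), ref.to_numpy()])
    # correlation distance is undefined for flat profiles; jitter-free guard:
    sd = pooled.std(axis=1)
    if (sd == 0).any():
        dist = pdist(pooled)  # euclidean fallback when any profile is constant
    else:
        dist = pdist(pooled, metric="correlation")
    labels = fcluster(linkage(dist, method=linkage_method), t=k_clusters, criterion="maxclust")

    n_query = len(profile.window_values)
    ref_labels = labels[n_query:]
    ref_counts = pd.Series(ref_labels).value_counts()
    all_counts = pd.Series(labels).value_counts()
    negative_clusters = set(ref_counts.index[ref_counts >= 0.5 * len(ref_labels)])
    negative_clusters |= {
        lab for lab in ref_counts.index if ref_counts[lab] >= 0.5 * all_counts[lab]
    }

    call = pd.Series(
        [lab not in negative_clusters for lab in labels[:n_query]],
        index=profile.window_values.index,
        name="cna_call",
    )
    ref_mean = ref.mean(axis=0)
    signal = (
        ((profile.window_values - ref_mean) ** 2).mean(axis=1).rename("signal")
    )
    profile.cna_call = call
    return pd.DataFrame({"cna_call": call, "signal": signal})


def call_cna_by_sample(
    profile: CNAProfile,
    sample_ids: pd.Series,
    reference_profiles: pd.DataFrame,
    k_clusters: int = 2,
) -> pd.DataFrame:
    """Run :func:`call_cna_status` independently within each sample."""
    calls = []
    for _, cells in sample_ids.groupby(sample_ids).groups.items():
        sub = CNAProfile(
            profile.window_values.loc[cells], profile.window_index, profile.signal.loc[cells]
        )
        calls.append(call_cna_status(sub, reference_profiles, k_clusters=k_clusters))
    merged = pd.concat(calls).reindex(profile.window_values.index)
    profile.cna_call = merged["cna_call"]
    return merged
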