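"""Expression transforms and quality-control filters.

Implements the standard full-length (Smart-seq2-like, TPM) and droplet
(10X-like, UMI) preprocessing conventions:

* ``E = log2(TPM/10 + 1)`` log transform,
* cell QC by detected-gene count and housekeeping expression (TPM data) or by
  a detected-gene window around the cohort mean plus a mitochondrial-UMI cap
  (UMI data),
* gene filtering by expression prevalence,
* per-gene aggregate expression ``Ea = log2(mean TPM + 1)``,
* mean-centering into relative expression ``Er`` within cell groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, require_scale

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-cell QC metrics with pass/fail flags.

    ``table`` has one row per *input* cell with columns ``n_detected_genes``,
    ``mean_housekeeping`` (TPM mode) or ``mito_fraction`` (UMI mode), ``passed``
    and ``reason`` (empty string when passed).
    """

    table: pd.DataFrame

    @property
    def n_passed(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.table["passed"]).sum())


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """E = log2(TPM/10 + 1), elementwise; zeros map to zero."""
    require_scale(m, "tpm")
    vals = m.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative TPM values")
    logged = np.log2(vals / 10.0 + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(logged, index=m.cell_ids, columns=m.gene_ids), "log", m.cell_groups
    )


def qc_filter_smartseq(
    m: ExpressionMatrix,
    housekeeping_genes,
    min_genes: int = 2000,
    min_hk: float = 2.5,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-quality cells from a TPM matrix.

    A cell is kept iff it detects at least ``min_genes`` genes (TPM > 0) and its
    mean housekeeping expression on the E scale is at least ``min_hk``.
    """
    require_scale(m, "tpm")
    hk = [g for g in housekeeping_genes if g in m.gene_ids]
    if len(hk) == 0:
        raise ValueError("housekeeping gene set is empty or absent from the matrix")

    vals = m.values
    detected = (vals > 0).sum(axis=1)
    hk_e = np.log2(vals[hk] / 10.0 + 1.0).mean(axis=1)
    passed = (detected >= min_genes) & (hk_e >= min_hk)

    reason = pd.Series("", index=m.cell_ids, dtype=object)
    reason[detected < min_genes] = f"detected_genes<{min_genes}"
    low_hk = hk_e < min_hk
    reason[low_hk & (detected >= min_genes)] = f"housekeeping_E<{min_hk}"
    report = QCReport(
        pd.DataFrame(
            {
                "n_detected_genes": detected,
                "mean_housekeeping": hk_e,
                "passed": passed,
                "reason": reason,
            }
        )
    )
    return m.subset_cells(m.cell_ids[passed]), report


def filter_genes(
    m: ExpressionMatrix, min_tpm: float = 10.0, min_cells: int = 10
) -> ExpressionMatrix:
    """Keep genes with TPM > ``min_tpm`` in at least ``min_cells`` cells."""
    require_scale(m, "tpm")
    keep = (m.values > min_tpm).sum(axis=0) >= min_cells
    return m.subset_genes(m.gene_ids[keep])


def aggregate_expression(m: ExpressionMatrix) -> pd.Series:
    """Ea(i) = log2(mean TPM of gene i across cells + 1)."""
    require_scale(m, "tpm")
    if m.n_cells == 0:
        raise ValueError("empty matrix")
    return np.log2(m.values.mean(axis=0) + 1.0).rename("Ea")


def center_expression(m: ExpressionMatrix, by_group: bool = True) -> ExpressionMatrix:
    """Center each gene to mean zero, yielding relative expression Er.

    With ``by_group=True`` (and ``cell_groups`` set) the per-gene mean is
    removed within each group — the within-compartment convention.  With
    ``by_group=False`` centering runs across all cells, the pan-compartment
    re-centering used before cross-compartment score comparison.
    """
    require_scale(m, "log", "centered")
    vals = m.values
    if by_group and m.cell_groups is not None:
        centered = vals.copy()
        for grp, idx in vals.groupby(m.cell_groups, observed=True).groups.items():
            block = vals.loc[idx]
            if len(idx) == 1:
                logger.info("group %r has a single cell; Er is all-zero for it", grp)
            centered.loc[idx] = block - block.mean(axis=0)
    else:
        centered = vals - vals.mean(axis=0)
    return ExpressionMatrix(centered, "centered", m.cell_groups)


def qc_filter_umi(
    counts: ExpressionMatrix,
    mito_genes=None,
    mito_prefix: str = "MT-",
    max_mito: float = 0.05,
) -> tuple[ExpressionMatrix, QCReport]:
    """Filter a UMI count matrix.

    A cell is kept iff its detected-gene count lies in [mean/2, 2*mean], where
    the mean is taken over all input cells before any filtering, and its
    mitochondrial-UMI fraction is at most ``max_mito``.  Mitochondrial genes
    are ``mito_genes`` if given, else genes whose id starts with
    ``mito_prefix``; if none exist the mito rule is skipped with a warning.
    """
    require_scale(counts, "umi")
    vals = counts.values
    detected = (vals > 0).sum(axis=1)
    mean_genes = float(detected.mean())

    if mito_genes is None:
        mito_genes = [g for g in counts.gene_ids if str(g).startswith(mito_prefix)]
    else:
        mito_genes = [g for g in mito_genes if g in counts.gene_ids]

    total = vals.sum(axis=1)
    if mito_genes:
        with np.errstate(invalid="ignore"):
            mito_frac = vals[mito_genes].sum(axis=1) / total.replace(0, np.nan)
        mito_frac = mito_frac.fillna(0.0)
        mito_ok = mito_frac <= max_mito
    else:
        warnings.warn("no mitochondrial genes found; mito-fraction rule skipped")
        mito_frac = pd.Series(np.nan, index=counts.cell_ids)
        mito_ok = pd.Series(True, index=counts.cell_ids)

    in_window = (detected >= mean_genes / 2.0) & (detected <= 2.0 * mean_genes)
    passed = in_window & mito_ok

    reason = pd.Series("", index=counts.cell_ids, dtype=object)
    reason[~in_window] = "detected_genes_outside_[mean/2,2*mean]"
    reason[in_window & ~mito_ok] = f"mito_fraction>{max_mito}"
    report = QCReport(
        pd.DataFrame(
            {
                "n_detected_genes": detected,
                "mito_fraction": mito_frac,
                "passed": passed,
                "reason": reason,
            }
        )
    )
    return counts.subset_cells(counts.cell_ids[passed]), report
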