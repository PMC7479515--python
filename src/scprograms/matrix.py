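"""Scale-tagged expression containers.

Cells are rows, genes are columns throughout the package.  The ``scale`` tag
tracks which transform a matrix is on:

``tpm``
    transcripts per million; every cell sums to 1e6 and values are >= 0.
``umi``
    raw UMI counts (10X-like); values are >= 0 integers.
``log``
    E = log2(TPM/10 + 1).  The /10 rescale reflects the ~1e5-transcript
    complexity of a single-cell library.
``centered``
    relative expression Er = E - mean(E) per gene within a centering group;
    basis for CNA windows and signature scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("tpm", "umi", "log", "centered")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with a scale tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Cells in rows (index = cell ids), genes in columns (columns = gene
        ids).
    scale : str
        One of ``tpm``, ``umi``, ``log``, ``centered``.
    cell_groups : pandas.Series, optional
        Per-cell group label (e.g. anatomical compartment); aligned to
        ``values.index``.
    """

    values: pd.DataFrame
    scale: str
    cell_groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.scale in ("tpm", "umi") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.scale} matrix contains negative values")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.cell_groups is not None:
            self.cell_groups = pd.Series(self.cell_groups).reindex(self.values.index)

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        groups = None if self.cell_groups is None else self.cell_groups.loc[cell_ids]
        return ExpressionMatrix(self.values.loc[cell_ids], self.scale, groups)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, gene_ids], self.scale, self.cell_groups)


@dataclass
class GeneAnnotation:
    """Per-gene chromosome/arm coordinates plus aggregate expression.

    ``table`` columns: ``chromosome``, ``arm``, ``start``, ``end`` (0-based
    half-open), indexed by gene id.  ``aggregate`` holds Ea(i) =
    log2(mean TPM + 1) once computed; it is NaN until then.
    """

    table: pd.DataFrame
    aggregate: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene ids in annotation")
        if self.aggregate is not None:
            agg = pd.Series(self.aggregate).reindex(self.table.index)
            if (agg.dropna() < 0).any():
                raise ValueError("aggregate expression must be >= 0")
            self.aggregate = agg

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


def require_scale(m: ExpressionMatrix, *scales: str) -> None:
    if m.scale not in scales:
        raise ValueError(f"expected scale in {scales}, got {m.scale!r}")
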