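"""Plain-text readers/writers for the package's tabular artifacts.

Expression matrices travel either as MatrixMarket (.mtx with cell/gene TSVs,
cells in rows) or as dense TSV; gene annotation is a BED-like TSV (chrom,
start, end, gene_id; 0-based half-open); truth tables, scores, calls and
curves are TSV round-trips of their DataFrames.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import io as scio
from scipy import sparse

from .matrix import ExpressionMatrix, GeneAnnotation


def write_matrix_mtx(m: ExpressionMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx``, ``<prefix>.cells.tsv``, ``<prefix>.genes.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(m.values.to_numpy()))
    pd.Series(m.cell_ids).to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False, header=False)
    pd.Series(m.gene_ids).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False, header=False)


def read_matrix_mtx(prefix: str | Path, scale: str) -> ExpressionMatrix:
    prefix = str(prefix)
    vals = sparse.csr_matrix(scio.mmread(prefix + ".mtx")).toarray()
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t", header=None)[0]
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0]
    return ExpressionMatrix(pd.DataFrame(vals, index=cells, columns=genes), scale)


def write_matrix_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, scale: str) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0), scale)


def write_annotation_bed(ann: GeneAnnotation, path: str | Path) -> None:
    """BED-like TSV: chromosome, start, end, gene_id (no header)."""
    tab = ann.table.reset_index()
    tab = tab[["chromosome", "start", "end", tab.columns[0]]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tab.to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path: str | Path) -> GeneAnnotation:
    tab = pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start", "end", "gene_id"]
    ).set_index("gene_id")
    return GeneAnnotation(tab[["chromosome", "start", "end"]])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
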