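"""Plain-text readers and writers for the pipeline's interchange formats.

TSV is the default for matrices (small at this cohort scale), MTX plus
row/column index files is available for sparse matrices, mutations travel
long-form (sample_id, gene, status), and gene sets use GMT semantics (see
:mod:`amlsig.genesets`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from .preprocess import ExpressionMatrix

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_expression_mtx",
    "read_expression_mtx",
    "write_metadata_tsv",
    "read_metadata_tsv",
    "write_mutations_long",
    "read_mutations_long",
]


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path, transform_state: str = "raw_counts") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = None
    return ExpressionMatrix(values=values, transform_state=transform_state)


def write_expression_mtx(expr: ExpressionMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.txt`` / ``.samples.txt``."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), scipy.sparse.csr_matrix(expr.values.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(expr.gene_ids) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(expr.sample_ids) + "\n")


def read_expression_mtx(prefix: str | Path, transform_state: str = "raw_counts") -> ExpressionMatrix:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().split()
    samples = prefix.with_suffix(".samples.txt").read_text().split()
    return ExpressionMatrix(
        values=pd.DataFrame(mat, index=genes, columns=samples),
        transform_state=transform_state,
    )


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_mutations_long(mut: pd.DataFrame, path: str | Path) -> None:
    """Binary samples x genes matrix to long form (sample_id, gene, status)."""
    long = (
        mut.rename_axis(index="sample_id", columns="gene")
        .stack()
        .rename("status")
        .reset_index()
    )
    long.to_csv(path, sep="\t", index=False)


def read_mutations_long(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    mat = long.pivot(index="sample_id", columns="gene", values="status").fillna(0).astype(int)
    mat.columns.name = None
    return mat
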