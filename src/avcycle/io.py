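"""File I/O dialects: Matrix Market + TSV expression matrices, GMT gene sets.

All text formats are UTF-8, tab-separated, '.' decimal, unquoted.  Sparse
matrices are written 1-based per the Matrix Market standard as genes x
cells with sibling ``genes.tsv`` / ``barcodes.tsv`` name files; dense TSVs
carry genes as the header row and cell ids in the first column.  Duplicate
gene or cell names are rejected rather than deduplicated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
]


def _check_unique(names, what: str):
    names = list(names)
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate {what} name(s): {dupes[:5]}")
    return names


def write_expression(path, matrix: pd.DataFrame) -> None:
    """Write a cells x genes matrix as .mtx (+ genes.tsv/barcodes.tsv) or dense .tsv."""
    path = Path(path)
    _check_unique(matrix.columns, "gene")
    _check_unique(matrix.index, "cell")
    if path.suffix == ".mtx":
        m = sparse.csr_matrix(np.asarray(matrix, dtype=float).T)  # genes x cells
        spio.mmwrite(str(path), m)
        pd.Series(matrix.columns).to_csv(path.with_name("genes.tsv"),
                                         sep="\t", index=False, header=False)
        pd.Series(matrix.index).to_csv(path.with_name("barcodes.tsv"),
                                       sep="\t", index=False, header=False)
    elif path.suffix == ".tsv":
        matrix.to_csv(path, sep="\t", index_label="cell_id")
    else:
        raise ValueError(f"unsupported expression format: {path.suffix!r}")


def read_expression(path) -> pd.DataFrame:
    """Read an expression matrix written by :func:`write_expression`.

    Returns a cells x genes DataFrame; integer-valued matrices come back
    with an integer dtype so write/read round-trips are exact.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        genes_file = path.with_name("genes.tsv")
        barcodes_file = path.with_name("barcodes.tsv")
        for f in (genes_file, barcodes_file):
            if not f.exists():
                raise FileNotFoundError(f"expected sibling file {f} next to {path}")
        try:
            m = spio.mmread(str(path))
        except Exception as e:  # malformed header or out-of-range (0-based) indices
            raise ValueError(f"malformed Matrix Market file {path}: {e}") from e
        genes = _check_unique(pd.read_csv(genes_file, sep="\t", header=None)[0], "gene")
        cells = _check_unique(pd.read_csv(barcodes_file, sep="\t", header=None)[0], "cell")
        dense = np.asarray(sparse.coo_matrix(m).todense())
        if dense.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{path}: matrix is {dense.shape} but names give "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        df = pd.DataFrame(dense.T, index=cells, columns=genes)
    elif path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        _check_unique(df.columns, "gene")
        _check_unique(df.index, "cell")
    else:
        raise ValueError(f"unsupported expression format: {path.suffix!r}")
    values = df.to_numpy()
    if values.size and np.all(np.isfinite(values)) and np.all(values == np.round(values)):
        df = df.astype(np.int64)
    return df


def write_gmt(path, gene_sets: dict, description: str = "avcycle") -> None:
    """Write gene sets to GMT (name, description, genes — tab-separated)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


def read_gmt(path) -> dict:
    """Read a GMT file into an ordered {set name: [genes]} mapping."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name + description")
            name = parts[0]
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            out[name] = [g for g in parts[2:] if g]
    return out
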