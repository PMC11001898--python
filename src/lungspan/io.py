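"""Readers and writers for the plain-text formats the pipeline touches.

Expression bundles are 10x-style triplets: a Matrix Market coordinate file
(genes x cells, 1-based on disk), a one-gene-per-line TSV and a
one-barcode-per-line TSV, plus a cell-metadata TSV with header columns
``cell, sample, group, cell_type`` (``cell_type`` may be empty; ``n_feature``
and ``percent_mt`` are derived from the counts when absent).

Gene sets come as GMT (``name<TAB>description<TAB>gene...``) or two-column
CSV (``set_name,gene``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    MITO_PREFIX_DEFAULT,
    CellAnnotation,
    CountMatrix,
    GeneSet,
)

log = logging.getLogger("lungspan")

__all__ = [
    "read_expression_bundle",
    "write_expression_bundle",
    "read_gene_sets",
    "write_results",
    "read_gene_list",
]


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_expression_bundle(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path,
    mito_prefix: str = MITO_PREFIX_DEFAULT,
) -> tuple[CountMatrix, CellAnnotation]:
    """Read and validate a counts bundle plus its cell metadata.

    The matrix rows/columns are aligned to the identifier files; metadata
    rows are aligned to the barcode order. Missing ``n_feature`` /
    ``percent_mt`` columns are computed from the (unfiltered) counts.
    """
    mat = scipy.io.mmread(str(mtx_path))
    genes = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    dense_data = mat.tocoo().data
    if dense_data.size and (np.any(dense_data < 0)
                            or not np.allclose(dense_data, np.round(dense_data))):
        raise ValueError("MTX contains negative or non-integral entries")
    counts = CountMatrix(genes, barcodes, sp.csr_matrix(mat))

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "cell" not in meta.columns:
        raise ValueError("metadata must have a 'cell' column")
    for col in ("n_feature", "percent_mt"):
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col])
    missing = set(barcodes) - set(meta["cell"])
    if missing:
        raise ValueError(
            f"missing annotation for {len(missing)} barcode(s), "
            f"e.g. {sorted(missing)[0]!r}"
        )
    ann = CellAnnotation.from_frame(meta, counts, mito_prefix=mito_prefix)
    return counts, ann


def write_expression_bundle(
    counts: CountMatrix,
    ann: CellAnnotation,
    outdir: str | Path,
    prefix: str = "matrix",
) -> dict[str, Path]:
    """Write the MTX/TSV triplet plus metadata; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / f"{prefix}.mtx",
        "genes": outdir / f"{prefix}.genes.tsv",
        "barcodes": outdir / f"{prefix}.barcodes.tsv",
        "metadata": outdir / f"{prefix}.metadata.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), counts.counts.tocoo(), field="integer")
    paths["genes"].write_text("".join(g + "\n" for g in counts.genes))
    paths["barcodes"].write_text("".join(c + "\n" for c in counts.cells))
    meta = ann.table.reset_index(names="cell")
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT or two-column CSV, preserving file order."""
    path = Path(path)
    names: list[str] = []
    members: dict[str, list[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path.name}:{lineno}: malformed GMT line "
                        "(need name, description, >=1 gene)"
                    )
                name, genes = parts[0], [g for g in parts[2:] if g]
                if not genes:
                    raise ValueError(f"{path.name}:{lineno}: empty gene set {name!r}")
                if name not in members:
                    names.append(name)
                    members[name] = []
                members[name].extend(genes)
    else:
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("gene-set CSV needs columns (set_name, gene)")
        for name, gene in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
            if name not in members:
                names.append(name)
                members[name] = []
            members[name].append(gene)
    sets = []
    for name in names:
        seen: set[str] = set()
        dedup = [g for g in members[name] if not (g in seen or seen.add(g))]
        sets.append(GeneSet(name, frozenset(dedup)))
    return sets


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Plain text, one gene per line (e.g. a disease gene list)."""
    path = Path(path)
    genes = _read_lines(path)
    if not genes:
        raise ValueError(f"{path.name}: empty gene list")
    return GeneSet(name or path.stem, frozenset(genes))


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tabular result as TSV: header, floats at 6 significant digits,
    rows in input order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
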