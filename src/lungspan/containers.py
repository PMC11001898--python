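"""Domain containers shared by every pipeline stage.

Conventions
-----------
* Matrices are **genes x cells**, mirroring the on-disk Matrix Market
  triplet layout of 10x-style bundles. On disk MTX is 1-based; every
  in-memory index in this package is 0-based.
* The five ordered life-stage groups are labelled ``T1 < T2 < T3 < T4 < T5``
  (first/second/last trimester, non-aging adult, aging adult).
* Mitochondrial genes are recognised by a symbol prefix (default ``MT-``);
  gene symbols are matched case-sensitively throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

GROUPS: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5")
MITO_PREFIX_DEFAULT = "MT-"

__all__ = [
    "GROUPS",
    "MITO_PREFIX_DEFAULT",
    "CountMatrix",
    "CellAnnotation",
    "NormalizedMatrix",
    "GeneSet",
    "group_categorical",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what}: {dup!r}")


def group_categorical(values: Iterable[str]) -> pd.Categorical:
    """Ordered categorical over the five life-stage groups."""
    cat = pd.Categorical(list(values), categories=list(GROUPS), ordered=True)
    if cat.isna().any():
        bad = sorted(set(v for v in values if v not in GROUPS))
        raise ValueError(f"unknown group label(s): {bad}")
    return cat


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifier lists."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.cells, "cell barcode")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative UMI counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integral UMI counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)

    def total_counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def total_counts_per_gene(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def n_features_per_cell(self) -> np.ndarray:
        """Genes with count > 0, per cell (nFeature)."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def percent_mito(self, prefix: str = MITO_PREFIX_DEFAULT) -> np.ndarray:
        """Percent of each cell's UMIs coming from ``prefix``-named genes.

        Computed on the matrix as given (conventionally the unfiltered one).
        Cells with zero total get 0.
        """
        mask = np.array([g.startswith(prefix) for g in self.genes])
        total = self.total_counts_per_cell().astype(float)
        if not mask.any():
            return np.zeros(self.n_cells)
        mito = np.asarray(self.counts[mask].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * mito / total, 0.0)
        return pct

    def subset(self, gene_mask: np.ndarray | None = None,
               cell_mask: np.ndarray | None = None) -> "CountMatrix":
        genes = self.genes
        cells = self.cells
        counts = self.counts
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            genes = [g for g, keep in zip(genes, gene_mask) if keep]
            counts = counts[gene_mask]
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            cells = [c for c, keep in zip(cells, cell_mask) if keep]
            counts = counts[:, cell_mask]
        return CountMatrix(genes, cells, sp.csr_matrix(counts))


@dataclass
class CellAnnotation:
    """Per-cell metadata: sample, ordered group, cell type, QC covariates.

    Thin wrapper around a DataFrame indexed by barcode with columns
    ``sample``, ``group`` (ordered categorical T1..T5), ``cell_type``,
    ``n_feature`` and ``percent_mt``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample", "group", "cell_type", "n_feature", "percent_mt")

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing column(s): {missing}")
        _check_unique(list(df.index.astype(str)), "cell barcode")
        df.index = df.index.astype(str)
        df["group"] = group_categorical(df["group"].astype(str))
        df["n_feature"] = df["n_feature"].astype(int)
        if (df["n_feature"] < 0).any():
            raise ValueError("negative n_feature")
        pm = df["percent_mt"].astype(float)
        if ((pm < 0) | (pm > 100)).any():
            raise ValueError("percent_mt outside [0, 100]")
        df["percent_mt"] = pm
        self.table = df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, counts: CountMatrix | None = None,
                   mito_prefix: str = MITO_PREFIX_DEFAULT) -> "CellAnnotation":
        """Build from a metadata frame, deriving QC covariates from counts
        when absent."""
        df = df.copy()
        if "cell" in df.columns:
            df = df.set_index("cell")
        if counts is not None:
            order = pd.Index(counts.cells)
            missing = order.difference(df.index)
            if len(missing):
                raise ValueError(
                    f"missing annotation for {len(missing)} barcode(s), "
                    f"e.g. {missing[0]!r}"
                )
            df = df.loc[order]
            if "n_feature" not in df.columns:
                df["n_feature"] = counts.n_features_per_cell()
            if "percent_mt" not in df.columns:
                df["percent_mt"] = counts.percent_mito(mito_prefix)
        if "cell_type" not in df.columns:
            df["cell_type"] = ""
        df["cell_type"] = df["cell_type"].fillna("").astype(str)
        return cls(df)

    @property
    def cells(self) -> list[str]:
        return list(self.table.index)

    def loc(self, barcodes: Sequence[str]) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[list(barcodes)])

    def matches(self, matrix) -> bool:
        """True when the barcode order equals ``matrix.cells`` (count or
        normalized matrix)."""
        return list(self.table.index) == list(matrix.cells)

    # normalized matrices carry the same .cells contract
    matches_norm = matches


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix of CP10K log-normalized expression.

    value(g, c) = ln(1 + 10000 * count(g, c) / total(c)), natural log.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.cells, "cell barcode")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("normalized matrix shape mismatch")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative normalized values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene symbols (Gj of the module score)."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> list[str]:
        """Members present in ``universe``, in universe order."""
        members = self.genes
        return [g for g in universe if g in members]
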