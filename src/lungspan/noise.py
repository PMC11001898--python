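"""Per-cell transcriptional-noise statistics.

Two estimator variants:

``noise_to_celltype_mean``
    Euclidean distance of each cell's log-normalized profile to its stratum
    centroid (arithmetic mean vector), over the full gene universe. Strata
    are either cell types pooled across age groups (``by_celltype``) or cell
    type x group (``by_celltype_and_group``, the default used for the
    summaries so that age trends are not absorbed into the centroids).

``noise_invariant_variant``
    Euclidean distance of each cell to the mean profile over **all** cells,
    restricted to a set of *invariant genes*: genes are binned into
    ``n_bins`` equally sized mean-abundance bins and, within each bin, the
    lowest-coefficient-of-variation fraction is selected (at least one gene
    per bin). Larger distance = less transcriptional stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellAnnotation, GeneSet, NormalizedMatrix

log = logging.getLogger("lungspan")

__all__ = [
    "NoiseConfig",
    "NoiseResult",
    "noise_to_celltype_mean",
    "select_invariant_genes",
    "noise_invariant_variant",
    "summarize_noise",
    "equal_size_bins",
]


@dataclass(frozen=True)
class NoiseConfig:
    n_bins: int = 10
    invariant_fraction: float = 0.10
    grouping: str = "by_celltype_and_group"  # or "by_celltype"

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not 0 < self.invariant_fraction <= 1:
            raise ValueError("invariant_fraction must be in (0, 1]")
        if self.grouping not in ("by_celltype", "by_celltype_and_group"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class NoiseResult:
    """Per-cell noise distances with their stratum labels."""

    table: pd.DataFrame  # columns: cell, cell_type, group, distance
    variant: str         # "celltype_mean" | "invariant_gene"

    def frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["variant"] = self.variant
        return out


def noise_to_celltype_mean(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    cfg: NoiseConfig = NoiseConfig(),
) -> NoiseResult:
    """Distance of each cell to its stratum centroid over all genes.

    Strata with fewer than 2 cells are excluded with a warning (their
    distance to a single-cell centroid is identically zero and carries no
    information).
    """
    if not ann.matches_norm(norm):
        raise ValueError("annotation does not cover the normalized matrix")
    ct = ann.table["cell_type"].to_numpy()
    if (pd.Series(ct) == "").any():
        raise ValueError("every cell needs a non-empty cell_type")
    grp = ann.table["group"].astype(str).to_numpy()
    if cfg.grouping == "by_celltype_and_group":
        strata = pd.Series([f"{a}|{b}" for a, b in zip(ct, grp)])
    else:
        strata = pd.Series(ct)

    rows = []
    X = norm.values  # genes x cells
    for stratum, members in strata.groupby(strata).groups.items():
        cols = np.asarray(members)
        if cols.size < 2:
            log.warning("stratum %r has < 2 cells; excluded", stratum)
            continue
        sub = X[:, cols]
        centroid = sub.mean(axis=1, keepdims=True)
        d = np.sqrt(((sub - centroid) ** 2).sum(axis=0))
        for c, dist in zip(cols, d):
            rows.append((norm.cells[c], ct[c], grp[c], float(dist)))
    table = pd.DataFrame(rows, columns=["cell", "cell_type", "group", "distance"])
    order = {b: i for i, b in enumerate(norm.cells)}
    table = table.sort_values("cell", key=lambda s: s.map(order),
                              ignore_index=True)
    return NoiseResult(table, "celltype_mean")


def equal_size_bins(order: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split ranked indices into ``n_bins`` contiguous bins of (near-)equal
    size; when sizes do not divide evenly the remainder goes to the
    highest-abundance bins."""
    n = order.size
    if n < n_bins:
        raise ValueError(f"fewer items ({n}) than bins ({n_bins})")
    base = n // n_bins
    rem = n % n_bins
    sizes = [base + (1 if i >= n_bins - rem else 0) for i in range(n_bins)]
    bins, start = [], 0
    for s in sizes:
        bins.append(order[start:start + s])
        start += s
    return bins


def select_invariant_genes(
    norm: NormalizedMatrix,
    cfg: NoiseConfig = NoiseConfig(),
    name: str = "invariant",
) -> GeneSet:
    """Lowest-CV genes per mean-abundance bin, evenly across abundance.

    Genes with zero mean are excluded up front (their CV is undefined).
    Within each of ``n_bins`` equally sized bins (by mean log-normalized
    abundance, ascending), genes are ranked by coefficient of variation
    sd/mean over cells and the lowest ``ceil(fraction * bin_size)`` (>= 1)
    are kept.
    """
    X = norm.values
    mean = X.mean(axis=1)
    nonzero = np.flatnonzero(mean > 0)
    if nonzero.size < cfg.n_bins:
        raise ValueError(
            f"need >= {cfg.n_bins} genes with nonzero mean, have {nonzero.size}")
    sd = X[nonzero].std(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(nonzero.size)
    cv = sd / mean[nonzero]
    order = nonzero[np.argsort(mean[nonzero], kind="stable")]
    cv_of = dict(zip(nonzero, cv))
    selected: list[int] = []
    for bin_idx in equal_size_bins(order, cfg.n_bins):
        take = max(1, int(np.ceil(cfg.invariant_fraction * bin_idx.size)))
        ranked = sorted(bin_idx, key=lambda i: (cv_of[i], i))
        selected.extend(ranked[:take])
    return GeneSet(name, frozenset(norm.genes[i] for i in selected))


def noise_invariant_variant(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    invariant: GeneSet,
) -> NoiseResult:
    """Distance of each cell to the all-cell mean over the invariant genes."""
    if not ann.matches_norm(norm):
        raise ValueError("annotation does not cover the normalized matrix")
    members = invariant.intersect(norm.genes)
    if not members:
        raise ValueError("invariant gene set is disjoint from the matrix")
    rows = [norm.genes.index(g) for g in members]
    sub = norm.values[rows]
    centroid = sub.mean(axis=1, keepdims=True)
    d = np.sqrt(((sub - centroid) ** 2).sum(axis=0))
    table = pd.DataFrame({
        "cell": norm.cells,
        "cell_type": ann.table["cell_type"].to_numpy(),
        "group": ann.table["group"].astype(str).to_numpy(),
        "distance": d,
    })
    return NoiseResult(table, "invariant_gene")


def summarize_noise(res: NoiseResult) -> pd.DataFrame:
    """Boxplot summaries per (cell_type, group): median, quartiles, n.

    Quartiles use linear interpolation. Empty strata produce no row.
    """
    if res.table.empty:
        raise ValueError("empty noise result")
    rows = []
    for (ct, grp), sub in res.table.groupby(["cell_type", "group"],
                                            sort=True, observed=True):
        d = sub["distance"].to_numpy()
        if d.size == 0:
            continue
        rows.append((ct, grp, float(np.median(d)),
                     float(np.quantile(d, 0.25)), float(np.quantile(d, 0.75)),
                     int(d.size)))
    return pd.DataFrame(
        rows, columns=["cell_type", "group", "median", "q1", "q3", "n"])
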