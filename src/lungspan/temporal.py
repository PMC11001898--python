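"""Time-course co-expression modules over the five ordered groups.

The input to module discovery is a per-gene pseudobulk trajectory: the mean
log-normalized expression over the selected cells of each group T1..T5,
z-scored per gene so that trajectories of different magnitude are
comparable. Soft modules are found with fuzzy c-means (k = 6 by default,
fuzzifier m = 2), restarted from several seeded random initializations and
keeping the lowest objective. Module centroids are then labelled by a
simple thresholded step rule (development-up, T3-peak, aging-down, flat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import GROUPS, CellAnnotation, NormalizedMatrix

log = logging.getLogger("lungspan")

__all__ = [
    "TimeCourseMatrix",
    "ClusterResult",
    "pseudobulk_timecourse",
    "fuzzy_cmeans",
    "classify_trend",
    "label_centroids",
]


@dataclass
class TimeCourseMatrix:
    """Gene x 5-group trajectories: raw group means and z-scored rows."""

    raw: pd.DataFrame      # genes x T1..T5 mean log-normalized expression
    zscored: pd.DataFrame  # same, standardized per gene (constant rows dropped)

    def __post_init__(self) -> None:
        for df in (self.raw, self.zscored):
            if list(df.columns) != list(GROUPS):
                raise ValueError(f"columns must be {GROUPS}, got {list(df.columns)}")
        z = self.zscored.to_numpy()
        if z.size:
            if np.abs(z.mean(axis=1)).max() > 1e-9:
                raise ValueError("z-scored rows must have mean 0")
            if np.abs(z.std(axis=1) - 1).max() > 1e-9:
                raise ValueError("z-scored rows must have sd 1")


def pseudobulk_timecourse(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    cell_type_filter: str | None = None,
    gene_filter: Sequence[str] | None = None,
) -> TimeCourseMatrix:
    """Per-group mean expression per gene, z-scored per gene.

    ``cell_type_filter`` restricts to one cell type; ``gene_filter`` to a
    gene subset. Every group must retain at least one cell. Genes constant
    across the five group means are dropped from the z-scored matrix with a
    warning (they carry no trajectory).
    """
    if not ann.matches(norm):
        raise ValueError("annotation does not cover the normalized matrix")
    mask = np.ones(norm.n_cells, dtype=bool)
    if cell_type_filter is not None:
        mask &= (ann.table["cell_type"] == cell_type_filter).to_numpy()
    genes = list(norm.genes)
    rows = np.arange(norm.n_genes)
    if gene_filter is not None:
        wanted = [g for g in gene_filter if g in set(norm.genes)]
        if not wanted:
            raise ValueError("gene filter excludes every matrix gene")
        index = {g: i for i, g in enumerate(norm.genes)}
        rows = np.array([index[g] for g in wanted])
        genes = wanted
    grp = ann.table["group"].astype(str).to_numpy()
    means = np.empty((rows.size, len(GROUPS)))
    for j, g in enumerate(GROUPS):
        cols = np.flatnonzero(mask & (grp == g))
        if cols.size == 0:
            raise ValueError(f"group {g} has no cells after filtering")
        means[:, j] = norm.values[np.ix_(rows, cols)].mean(axis=1)
    raw = pd.DataFrame(means, index=genes, columns=list(GROUPS))
    sd = means.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant gene trajectory(ies) dropped", constant.sum())
    keep = ~constant
    z = (means[keep] - means[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    zscored = pd.DataFrame(z, index=[g for g, k in zip(genes, keep) if k],
                           columns=list(GROUPS))
    return TimeCourseMatrix(raw, zscored)


@dataclass
class ClusterResult:
    """Soft co-expression modules from fuzzy c-means."""

    k: int
    m: float
    memberships: pd.DataFrame  # genes x k, rows sum to 1
    centroids: pd.DataFrame    # k x 5 groups
    objective: float
    objective_trace: np.ndarray
    seed: int

    @property
    def hard_labels(self) -> pd.Series:
        return self.memberships.idxmax(axis=1).rename("module")


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """u(g,c) = 1 / sum_l (d_gc/d_gl)^(2/(m-1)); exact hits get weight 1."""
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        U[hit] = 0.0
        U[hit, zero[hit].argmax(axis=1)] = 1.0
    return U


def _fcm_once(
    X: np.ndarray, k: int, m: float, rng: np.random.Generator,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    n = X.shape[0]
    # k-means++-style D^2 init: data-row centroids spread over the data
    # (flat random memberships would collapse every centroid onto the
    # grand mean, and uniform row picks often miss small clusters)
    chosen = [int(rng.integers(n))]
    closest = ((X - X[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        total = closest.sum()
        if total <= 0:
            pool = np.setdiff1d(np.arange(n), chosen)
            chosen.append(int(rng.choice(pool)))
            continue
        nxt = int(rng.choice(n, p=closest / total))
        chosen.append(nxt)
        closest = np.minimum(closest, ((X - X[nxt]) ** 2).sum(axis=1))
    C = X[chosen].copy()
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    U = _fcm_memberships(d2, m)
    trace = []
    prev_J = np.inf
    for _ in range(max_iter):
        Um = U ** m
        C = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        J = float((Um * d2).sum())
        trace.append(J)
        U = _fcm_memberships(d2, m)
        if abs(prev_J - J) <= tol * max(1.0, abs(prev_J)):
            break
        prev_J = J
    return U, C, J, np.asarray(trace)


def fuzzy_cmeans(
    tc: TimeCourseMatrix | pd.DataFrame,
    k: int = 6,
    m: float = 2.0,
    seed: int = 0,
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterResult:
    """Standard fuzzy c-means on z-scored trajectories.

    ``u(g, c) = 1 / sum_l (d(g, c) / d(g, l))^(2/(m-1))`` and
    ``c = sum_g u^m x / sum_g u^m``. Runs ``restarts`` seeded random
    initializations and keeps the lowest final objective J; J is
    non-increasing along each run. Accepts a TimeCourseMatrix (its z-scored
    frame is used) or any gene x group frame.
    """
    Z = tc.zscored if isinstance(tc, TimeCourseMatrix) else tc
    X = Z.to_numpy(dtype=float)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if X.shape[0] < k:
        raise ValueError(f"need >= {k} genes, have {X.shape[0]}")
    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        U, C, J, trace = _fcm_once(X, k, m, rng, tol, max_iter)
        if best is None or J < best[2]:
            best = (U, C, J, trace)
    U, C, J, trace = best
    # deterministic module order: by centroid argmax group, then first coord
    order = np.lexsort((C[:, 0], C.argmax(axis=1)))
    C = C[order]
    U = U[:, order]
    names = [f"module_{i + 1}" for i in range(k)]
    return ClusterResult(
        k=k, m=m,
        memberships=pd.DataFrame(U, index=Z.index, columns=names),
        centroids=pd.DataFrame(C, index=names, columns=list(Z.columns)),
        objective=J, objective_trace=trace, seed=seed,
    )


def classify_trend(centroid: Sequence[float], epsilon: float = 0.1
                   ) -> tuple[str, set[str]]:
    """Label a 5-point trajectory by thresholded consecutive steps.

    Steps are the four consecutive differences, mapped to {+, 0, -} at
    ``+-epsilon``. Flags (non-exclusive):

    * ``development_up``: steps T1->T2 and T2->T3 non-negative, at least
      one positive;
    * ``t3_peak``: development_up AND steps T3->T4, T4->T5 non-positive
      with at least one negative;
    * ``aging_down``: step T4->T5 negative.

    The primary label follows the precedence
    t3_peak > development_up > aging_down > flat. Returns
    ``(primary, flags)``. The rule is a repository convention for reading
    centroids, not a fitted model.
    """
    c = np.asarray(centroid, dtype=float)
    if c.size != 5:
        raise ValueError("centroid must have 5 ordered values")
    diffs = np.diff(c)
    sign = np.where(diffs > epsilon, 1, np.where(diffs < -epsilon, -1, 0))
    flags: set[str] = set()
    dev_up = (sign[0] >= 0 and sign[1] >= 0) and (sign[0] > 0 or sign[1] > 0)
    if dev_up:
        flags.add("development_up")
    if dev_up and (sign[2] <= 0 and sign[3] <= 0) and (sign[2] < 0 or sign[3] < 0):
        flags.add("t3_peak")
    if sign[3] < 0:
        flags.add("aging_down")
    for label in ("t3_peak", "development_up", "aging_down"):
        if label in flags:
            return label, flags
    return "flat", flags


def label_centroids(result: ClusterResult, epsilon: float = 0.1) -> pd.DataFrame:
    """Primary trend label and flags for each module centroid."""
    rows = []
    for name, row in result.centroids.iterrows():
        primary, flags = classify_trend(row.to_numpy(), epsilon)
        rows.append((name, primary, ",".join(sorted(flags))))
    return pd.DataFrame(rows, columns=["module", "primary", "flags"])
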