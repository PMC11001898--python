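"""Synthetic scRNA-seq generator for the development-and-aging pipeline.

The generator plants, in a negative-binomial (Gamma-Poisson) count model,
the structures the analysis is designed to detect:

* five ordered life-stage groups T1..T5 with configurable cells per group;
* several cell types, each with a block of marker genes up-shifted in that
  type;
* lognormal per-cell library-size factors and a mitochondrial gene block
  with a configurable expected UMI share;
* group-dependent **dispersion inflation** (default: T5 cells draw with a
  doubled NB dispersion) — this raises every cell's distance to its stratum
  centroid without moving the centroid, isolating the transcriptional-noise
  statistic from mean shifts;
* temporal gene programs whose group-level mean trajectories follow named
  patterns on the group rank 1..5 (``dev_up``, ``t3_peak``, ``aging_down``,
  ``flat``), with a log-scale amplitude;
* a designated focal gene (default ``FTL``) following the
  up-in-development / down-in-aging trajectory;
* optional low-dispersion "housekeeping" genes spread evenly across the
  abundance range (ground truth for invariant-gene selection).

Counts for gene g in cell c are NB with mean
``mu = base_g * pattern_g(rank) * marker_g(type) * size_factor_c`` and
gene-wise dispersion ``phi_g * kappa_group``, sampled as
Poisson(Gamma(1/phi, mu*phi)). A fixed seed gives bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .containers import GROUPS, CellAnnotation, CountMatrix

log = logging.getLogger("lungspan")

__all__ = [
    "PATTERN_SHAPES",
    "pattern_multipliers",
    "TemporalProgram",
    "CellTypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_timecourse_profiles",
    "simulate_correlated_scores",
    "simulate_two_group_counts",
]

# Log-scale trajectory shapes over group ranks 1..5, in [0, 1].
PATTERN_SHAPES: dict[str, np.ndarray] = {
    "dev_up": np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
    "t3_peak": np.array([0.0, 0.5, 1.0, 0.5, 0.0]),
    "aging_down": np.array([1.0, 1.0, 1.0, 1.0, 0.0]),
    "dev_up_aging_down": np.array([0.0, 0.5, 1.0, 1.0, 0.2]),
    "flat": np.zeros(5),
}


def pattern_multipliers(pattern: str, amplitude: float) -> np.ndarray:
    """Mean multiplier per group rank: exp(amplitude * shape)."""
    try:
        shape = PATTERN_SHAPES[pattern]
    except KeyError:
        raise ValueError(
            f"unknown pattern {pattern!r}; one of {sorted(PATTERN_SHAPES)}"
        ) from None
    return np.exp(amplitude * shape)


@dataclass(frozen=True)
class TemporalProgram:
    pattern: str
    n_genes: int
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_SHAPES:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    proportion: float
    n_marker_genes: int = 20
    marker_fold_change: float = 4.0


def _default_cell_types() -> list[CellTypeSpec]:
    return [
        CellTypeSpec("AT1", 0.3),
        CellTypeSpec("AT2", 0.4),
        CellTypeSpec("FB", 0.3),
    ]


def _default_programs() -> list[TemporalProgram]:
    return [
        TemporalProgram("dev_up", 100, 2.0),
        TemporalProgram("t3_peak", 100, 2.0),
        TemporalProgram("aging_down", 100, 2.0),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic lung lifespan dataset."""

    n_genes: int = 2000
    cells_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: 200 for g in GROUPS})
    cell_types: Sequence[CellTypeSpec] = field(default_factory=_default_cell_types)
    base_mean_shape: float = 0.5   # Gamma shape of per-gene base means
    base_mean_scale: float = 2.0   # Gamma scale (=> mean 1 UMI/gene/cell-equivalent)
    dispersion: float = 0.2        # baseline NB dispersion phi (1/size)
    dispersion_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 1.0, "T2": 1.0, "T3": 1.0,
                                 "T4": 1.0, "T5": 2.0})
    library_size_mu: float = 0.0   # lognormal location of cell size factors
    library_size_sigma: float = 0.35
    mito_fraction: float = 5.0     # expected % of UMIs from MT- genes
    n_mito_genes: int = 13
    n_housekeeping: int = 0        # low-dispersion genes spread over abundance
    housekeeping_dispersion: float = 0.01
    temporal_programs: Sequence[TemporalProgram] = field(
        default_factory=_default_programs)
    focal_gene: str = "FTL"
    focal_amplitude: float = 2.0
    signature_link: float = 0.8    # target Pearson r, focal gene vs planted score
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(n <= 0 for n in self.cells_per_group.values()):
            raise ValueError("cells_per_group entries must be positive")
        if any(k < 1 for k in self.dispersion_multiplier.values()):
            raise ValueError("dispersion multipliers must be >= 1")
        if not abs(self.signature_link) <= 1:
            raise ValueError("|signature_link| must be <= 1")
        reserved = (self.n_mito_genes + self.n_housekeeping + 1
                    + sum(ct.n_marker_genes for ct in self.cell_types)
                    + sum(p.n_genes for p in self.temporal_programs))
        if reserved > self.n_genes:
            raise ValueError(
                f"infeasible config: {reserved} structured genes exceed "
                f"n_genes={self.n_genes}"
            )

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests."""

    program_of_gene: dict[str, str]          # gene -> pattern (structured only)
    marker_genes: dict[str, list[str]]       # cell type -> marker genes
    housekeeping_genes: list[str]
    mito_genes: list[str]
    dispersion_multiplier: dict[str, float]  # group -> kappa
    focal_gene: str
    focal_pattern: str
    signature_link: float

    def frame(self) -> pd.DataFrame:
        rows = [(g, p) for g, p in self.program_of_gene.items()]
        return pd.DataFrame(rows, columns=["gene", "pattern"])


def simulate_dataset(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[CountMatrix, CellAnnotation, GroundTruth]:
    """Draw one dataset under ``config``; bit-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    groups = [g for g in GROUPS if g in config.cells_per_group]
    if not groups:
        raise ValueError("cells_per_group selects no known group")

    # --- gene bookkeeping -------------------------------------------------
    n = config.n_genes
    gene_names: list[str] = []
    mito_genes = [f"MT-G{i + 1}" for i in range(config.n_mito_genes)]
    gene_names.extend(mito_genes)
    marker_genes: dict[str, list[str]] = {}
    for ct in config.cell_types:
        marker_genes[ct.name] = [
            f"MK-{ct.name}-{i + 1}" for i in range(ct.n_marker_genes)]
        gene_names.extend(marker_genes[ct.name])
    housekeeping = [f"HK{i + 1}" for i in range(config.n_housekeeping)]
    gene_names.extend(housekeeping)
    program_of_gene: dict[str, str] = {}
    for j, prog in enumerate(config.temporal_programs):
        for i in range(prog.n_genes):
            name = f"PG{j + 1}-{prog.pattern}-{i + 1}"
            gene_names.append(name)
            program_of_gene[name] = prog.pattern
    gene_names.append(config.focal_gene)
    program_of_gene[config.focal_gene] = "dev_up_aging_down"
    n_background = n - len(gene_names)
    gene_names.extend(f"BG{i + 1}" for i in range(n_background))

    # --- per-gene base means and dispersions ------------------------------
    base = rng.gamma(config.base_mean_shape, config.base_mean_scale, size=n)
    base = np.maximum(base, 1e-3)
    idx = {g: i for i, g in enumerate(gene_names)}
    if housekeeping:
        # spread housekeepers evenly over the abundance range of the rest
        others = np.delete(base, [idx[g] for g in housekeeping])
        # mid-quantile spacing: close to an even count per abundance decile
        probs = (np.arange(len(housekeeping)) + 0.5) / len(housekeeping)
        qs = np.quantile(others, probs)
        for g, q in zip(housekeeping, qs):
            base[idx[g]] = max(q, 1e-3)
    # temporal-program genes (and the focal gene) draw their base means
    # from the above-median part of the base distribution: a trajectory
    # planted on an essentially unexpressed gene is not a recoverable signal
    prog_rows = [idx[g] for g in program_of_gene]
    if prog_rows:
        u = rng.uniform(0.5, 1.0, size=len(prog_rows))
        base[prog_rows] = scipy.stats.gamma.ppf(
            u, config.base_mean_shape, scale=config.base_mean_scale)

    phi = np.full(n, config.dispersion)
    for g in housekeeping:
        phi[idx[g]] = config.housekeeping_dispersion

    # --- per-gene group trajectories (rank 1..5) --------------------------
    traj = np.ones((n, len(GROUPS)))
    amp_of_pattern = {p.pattern: p.amplitude for p in config.temporal_programs}
    for g, pattern in program_of_gene.items():
        if g == config.focal_gene:
            amp = config.focal_amplitude
        else:
            amp = amp_of_pattern[pattern]
        traj[idx[g]] = pattern_multipliers(pattern, amp)

    # mito base means sized against the program-inflated expected totals so
    # the expected UMI share matches mito_fraction (averaged over groups,
    # weighted by cells per group)
    if config.n_mito_genes:
        f = config.mito_fraction / 100.0
        w = np.array([config.cells_per_group.get(g, 0) for g in GROUPS],
                     dtype=float)
        w /= w.sum()
        nonmito = slice(config.n_mito_genes, n)
        expected_nonmito = float(
            (base[nonmito, None] * traj[nonmito]).sum(axis=0) @ w)
        p_total = sum(ct.proportion for ct in config.cell_types)
        for ct in config.cell_types:
            mk_rows = [idx[g] for g in marker_genes[ct.name]]
            if mk_rows:
                expected_nonmito += (
                    ct.proportion / p_total * (ct.marker_fold_change - 1.0)
                    * float((base[mk_rows, None] * traj[mk_rows]).sum(axis=0) @ w))
        base[: config.n_mito_genes] = (
            f / (1 - f) * expected_nonmito / config.n_mito_genes)

    # --- cells ------------------------------------------------------------
    props = np.array([ct.proportion for ct in config.cell_types], dtype=float)
    props = props / props.sum()
    barcodes: list[str] = []
    cell_group: list[str] = []
    cell_type: list[str] = []
    cell_sample: list[str] = []
    for g in groups:
        n_cells = config.cells_per_group[g]
        counts_per_type = np.floor(props * n_cells).astype(int)
        counts_per_type[-1] = n_cells - counts_per_type[:-1].sum()
        for ct, m in zip(config.cell_types, counts_per_type):
            for i in range(m):
                barcodes.append(f"{g}-{ct.name}-{len(barcodes):05d}")
                cell_group.append(g)
                cell_type.append(ct.name)
        half = n_cells // 2
        cell_sample.extend(
            f"{g}_s1" if i < half else f"{g}_s2" for i in range(n_cells))
    n_cells_total = len(barcodes)
    size_factors = rng.lognormal(
        config.library_size_mu, config.library_size_sigma, size=n_cells_total)

    group_rank = np.array([GROUPS.index(g) for g in cell_group])
    kappa = np.array([config.dispersion_multiplier.get(g, 1.0)
                      for g in cell_group])

    # --- mean matrix ------------------------------------------------------
    mu = base[:, None] * traj[:, group_rank]
    for ct in config.cell_types:
        mask = np.array([t == ct.name for t in cell_type])
        rows = [idx[g] for g in marker_genes[ct.name]]
        if rows:
            mu[np.ix_(rows, mask)] *= ct.marker_fold_change
    mu = mu * size_factors[None, :]

    # --- NB sampling: Poisson(Gamma(1/phi_gc, mu*phi_gc)) -----------------
    phi_gc = phi[:, None] * kappa[None, :]
    lam = rng.gamma(1.0 / phi_gc, mu * phi_gc)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(gene_names, barcodes, sp.csr_matrix(counts))
    meta = pd.DataFrame({
        "cell": barcodes,
        "sample": cell_sample,
        "group": cell_group,
        "cell_type": cell_type,
    })
    ann = CellAnnotation.from_frame(meta, cm)
    truth = GroundTruth(
        program_of_gene=program_of_gene,
        marker_genes=marker_genes,
        housekeeping_genes=housekeeping,
        mito_genes=mito_genes,
        dispersion_multiplier=dict(config.dispersion_multiplier),
        focal_gene=config.focal_gene,
        focal_pattern="dev_up_aging_down",
        signature_link=config.signature_link,
    )
    log.info("simulated %d genes x %d cells", n, n_cells_total)
    return cm, ann, truth


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def simulate_timecourse_profiles(
    patterns: Sequence[str] | None = None,
    n_genes_each: int = 100,
    sigma: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x 5-group z-profiles around planted pattern centroids.

    Each gene's profile is the z-scored base pattern plus iid N(0, sigma)
    noise (flat genes scatter around the origin). Returns the profile frame
    and the true pattern label per gene. This is the module-discovery test
    bed for fuzzy c-means.
    """
    if patterns is None:
        patterns = ["dev_up", "aging_down", "t3_peak",
                    "dev_down", "t3_trough", "flat"]
    rng = np.random.default_rng(seed)
    bases = {
        "dev_up": PATTERN_SHAPES["dev_up"],
        "aging_down": PATTERN_SHAPES["aging_down"],
        "t3_peak": PATTERN_SHAPES["t3_peak"],
        "dev_down": -PATTERN_SHAPES["dev_up"],
        "t3_trough": -PATTERN_SHAPES["t3_peak"],
        "dev_up_aging_down": PATTERN_SHAPES["dev_up_aging_down"],
        "flat": PATTERN_SHAPES["flat"],
    }
    rows, labels, names = [], [], []
    for p in patterns:
        if p not in bases:
            raise ValueError(f"unknown pattern {p!r}")
        b = bases[p]
        z = np.zeros(5) if p == "flat" else _zscore_rows(b[None, :])[0]
        noise = rng.normal(0.0, sigma, size=(n_genes_each, 5))
        rows.append(z[None, :] + noise)
        labels.extend([p] * n_genes_each)
        names.extend(f"{p}-{i + 1}" for i in range(n_genes_each))
    profiles = pd.DataFrame(
        np.vstack(rows), index=names, columns=list(GROUPS))
    return profiles, pd.Series(labels, index=names, name="pattern")


def simulate_correlated_scores(
    expression: np.ndarray,
    r0: float,
    seed: int = 0,
    loc: float = 0.5,
    scale: float = 0.15,
    floor: float | None = 0.02,
) -> np.ndarray:
    """Per-cell signature scores with target Pearson r against ``expression``.

    score = loc + scale * (r0 * z(expr) + sqrt(1-r0^2) * eps). With
    ``floor`` set (default just above the 0.01 correlation gate) the scores
    are affinely shifted up so none falls below it: gating on the score
    selects on the noise term and would otherwise attenuate the realized
    gated-subset correlation below the planted r0. The shift changes no
    Pearson correlation.
    """
    if not -1 <= r0 <= 1:
        raise ValueError("|r0| must be <= 1")
    rng = np.random.default_rng(seed)
    x = np.asarray(expression, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("expression is constant; cannot plant a correlation")
    z = (x - x.mean()) / sd
    eps = rng.standard_normal(x.size)
    scores = loc + scale * (r0 * z + np.sqrt(1 - r0 ** 2) * eps)
    if floor is not None and scores.min() < floor:
        scores = scores + (floor - scores.min())
    return scores


def simulate_two_group_counts(
    n_genes: int = 2000,
    n_de: int = 0,
    log2_fc: float = 1.0,
    cells_per_group: int = 200,
    dispersion: float = 0.2,
    library_size_sigma: float = 0.35,
    base_mean_shape: float = 0.5,
    base_mean_scale: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, CellAnnotation, list[str]]:
    """Two-group (T4 vs T5) NB counts with ``n_de`` genes shifted in T5.

    Lean generator for DEG power/null-FDR experiments; returns the planted
    DE gene names. ``n_de = 0`` gives a global null.
    """
    rng = np.random.default_rng(seed)
    base = np.maximum(rng.gamma(base_mean_shape, base_mean_scale, n_genes), 0.05)
    # plant DE only in detectably expressed genes (above-median base mean);
    # a fold change on an unexpressed gene is not an identifiable signal
    if n_de:
        expressed = np.flatnonzero(base >= np.median(base))
        de_rows = rng.choice(expressed, size=n_de, replace=False)
    else:
        de_rows = np.array([], int)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    n_cells = 2 * cells_per_group
    size = rng.lognormal(0.0, library_size_sigma, n_cells)
    group = np.array(["T4"] * cells_per_group + ["T5"] * cells_per_group)
    mu = np.tile(base[:, None], (1, n_cells)) * size[None, :]
    if n_de:
        mu[np.ix_(de_rows, group == "T5")] *= 2.0 ** log2_fc
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    barcodes = [f"{g}-{i:05d}" for i, g in enumerate(group)]
    cm = CountMatrix(genes, barcodes, sp.csr_matrix(counts))
    meta = pd.DataFrame({
        "cell": barcodes,
        "sample": [f"{g}_s1" for g in group],
        "group": group,
        "cell_type": "AT2",
    })
    ann = CellAnnotation.from_frame(meta, cm)
    return cm, ann, [genes[i] for i in de_rows]
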