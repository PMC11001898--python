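"""lungspan: transcriptional-noise, signature-scoring and time-course
analysis of lung development-and-aging single-cell RNA-seq.

The public surface re-exports the domain containers and the one function
per analysis stage; see the module docstrings for the statistics.
"""

import logging

__version__ = "0.1.0"

from .containers import (  # noqa: E402,F401
    GROUPS,
    CellAnnotation,
    CountMatrix,
    GeneSet,
    NormalizedMatrix,
)
from .correlation import CorrelationResult, score_gene_correlation  # noqa: F401
from .degs import bh_adjust, deg_t_test, overlap_disease_genes  # noqa: F401
from .groupstats import (  # noqa: F401
    ContingencyTable2x2,
    SummaryStats,
    TestResult,
    anova_dunnett,
    check_assumptions,
    mann_whitney_test,
    two_sample_t_from_summary,
    yates_chi_square,
)
from .io import (  # noqa: F401
    read_expression_bundle,
    read_gene_list,
    read_gene_sets,
    write_expression_bundle,
    write_results,
)
from .noise import (  # noqa: F401
    NoiseConfig,
    NoiseResult,
    noise_invariant_variant,
    noise_to_celltype_mean,
    select_invariant_genes,
    summarize_noise,
)
from .pipeline import RunManifest, run_pipeline  # noqa: F401
from .qc import QCReport, QCThresholds, normalize, qc_filter  # noqa: F401
from .scoring import (  # noqa: F401
    ControlGeneAssignment,
    ScoreResult,
    assign_control_genes,
    module_score,
    score_gene_sets,
)
from .simulate import (  # noqa: F401
    SimulationConfig,
    TemporalProgram,
    CellTypeSpec,
    GroundTruth,
    simulate_correlated_scores,
    simulate_dataset,
    simulate_timecourse_profiles,
    simulate_two_group_counts,
)
from .temporal import (  # noqa: F401
    ClusterResult,
    TimeCourseMatrix,
    classify_trend,
    fuzzy_cmeans,
    label_centroids,
    pseudobulk_timecourse,
)


def setup_logging(quiet: bool = False) -> None:
    """Structured logging to stderr; ``quiet`` raises the level to ERROR."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s: %(message)s"))
    logger = logging.getLogger("lungspan")
    logger.handlers[:] = [handler]
    logger.setLevel(logging.ERROR if quiet else logging.INFO)
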