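"""End-to-end orchestration from a plain-text configuration file.

The configuration is INI-style key=value sections. Stages run in dependency
order — simulate (or load), qc, normalize (implicit), then the requested
analysis stages (noise, score, tca, deg, correlate) — and every stochastic
stage must name an explicit seed in its section; omitting it is a
configuration error. Stage outputs are plain TSV/MTX so any stage can be
re-run standalone; a JSON run manifest records the configuration snapshot,
seeds, and sha256 hashes of every output file.

Example configuration::

    [global]
    outdir = run1

    [simulate]
    seed = 7
    n_genes = 1000
    cells_per_group = 150

    [qc]
    min_features = 200
    max_percent_mt = 10
    min_gene_umi = 5

    [noise]
    variant = centroid
    grouping = by_celltype_and_group

    [score]
    seed = 7
    gene_sets = sets.gmt

    [tca]
    seed = 7
    k = 6
    cell_type = AT2

    [deg]
    group_a = T5
    group_b = T4
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import GROUPS
from .correlation import score_gene_correlation
from .degs import deg_t_test
from .io import (read_expression_bundle, read_gene_sets,
                 write_expression_bundle, write_results)
from .noise import (NoiseConfig, noise_invariant_variant,
                    noise_to_celltype_mean, select_invariant_genes,
                    summarize_noise)
from .qc import QCThresholds, normalize, qc_filter
from .scoring import score_gene_sets
from .simulate import SimulationConfig, simulate_dataset
from .temporal import fuzzy_cmeans, label_centroids, pseudobulk_timecourse

log = logging.getLogger("lungspan")

__all__ = ["RunManifest", "run_pipeline", "ConfigError"]

STAGE_ORDER = ("simulate", "qc", "noise", "score", "tca", "deg", "correlate")
STOCHASTIC_STAGES = {"simulate", "score", "tca"}


class ConfigError(ValueError):
    """Configuration schema violation, tagged with the offending key path."""


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    stages: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # stage -> {path: sha256}
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "config": self.config,
            "seeds": self.seeds,
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
        }, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: RunManifest, stage: str, paths: dict[str, Path]) -> None:
    manifest.stages.append(stage)
    manifest.outputs[stage] = {str(p): _sha256(Path(p)) for p in paths.values()}


def _require_seed(cfg: configparser.ConfigParser, section: str) -> int:
    if not cfg.has_option(section, "seed"):
        raise ConfigError(f"[{section}] seed: stochastic stage needs an "
                          "explicit seed")
    return cfg.getint(section, "seed")


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the stages named in the configuration file, in order."""
    config_path = Path(config_path)
    cfg = configparser.ConfigParser()
    if not cfg.read(config_path):
        raise ConfigError(f"cannot read config {config_path}")

    outdir = Path(cfg.get("global", "outdir", fallback="lungspan_run"))
    if not outdir.is_absolute():
        outdir = config_path.parent / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    snapshot = {s: dict(cfg.items(s)) for s in cfg.sections()}
    seeds = {s: cfg.getint(s, "seed")
             for s in cfg.sections()
             if s in STOCHASTIC_STAGES and cfg.has_option(s, "seed")}
    manifest = RunManifest(config=snapshot, seeds=seeds, version=__version__)

    counts = ann = None
    stage = "?"
    try:
        # --- input: simulate or load -----------------------------------
        if cfg.has_section("simulate"):
            stage = "simulate"
            seed = _require_seed(cfg, "simulate")
            sim = SimulationConfig(
                n_genes=cfg.getint("simulate", "n_genes", fallback=2000),
                cells_per_group={
                    g: cfg.getint("simulate", "cells_per_group", fallback=200)
                    for g in GROUPS},
                seed=seed,
            )
            counts, ann, _truth = simulate_dataset(sim)
            paths = write_expression_bundle(counts, ann, outdir, "simulated")
            _record(manifest, "simulate", paths)
        elif cfg.has_section("input"):
            stage = "input"
            for key in ("mtx", "genes", "barcodes", "metadata"):
                if not cfg.has_option("input", key):
                    raise ConfigError(f"[input] {key}: required path missing")
            counts, ann = read_expression_bundle(
                cfg.get("input", "mtx"), cfg.get("input", "genes"),
                cfg.get("input", "barcodes"), cfg.get("input", "metadata"))
        else:
            raise ConfigError("config needs a [simulate] or [input] section")

        # --- qc + normalize ---------------------------------------------
        if cfg.has_section("qc"):
            stage = "qc"
            thr = QCThresholds(
                min_features=cfg.getint("qc", "min_features", fallback=200),
                max_percent_mt=cfg.getfloat("qc", "max_percent_mt", fallback=10.0),
                min_gene_umi=cfg.getint("qc", "min_gene_umi", fallback=5),
            )
            counts, ann, report = qc_filter(counts, ann, thr)
            path = write_results(report.frame(), outdir / "qc_report.tsv")
            _record(manifest, "qc", {"report": path})
        norm = normalize(counts)

        # --- analysis stages --------------------------------------------
        if cfg.has_section("noise"):
            stage = "noise"
            ncfg = NoiseConfig(
                n_bins=cfg.getint("noise", "bins", fallback=10),
                invariant_fraction=cfg.getfloat("noise", "fraction", fallback=0.10),
                grouping=cfg.get("noise", "grouping",
                                 fallback="by_celltype_and_group"),
            )
            variant = cfg.get("noise", "variant", fallback="centroid")
            if variant == "centroid":
                res = noise_to_celltype_mean(norm, ann, ncfg)
            elif variant == "invariant":
                inv = select_invariant_genes(norm, ncfg)
                res = noise_invariant_variant(norm, ann, inv)
            else:
                raise ConfigError(f"[noise] variant: unknown {variant!r}")
            p1 = write_results(res.frame(), outdir / "noise_per_cell.tsv")
            p2 = write_results(summarize_noise(res), outdir / "noise_summary.tsv")
            _record(manifest, "noise", {"per_cell": p1, "summary": p2})

        if cfg.has_section("score"):
            stage = "score"
            seed = _require_seed(cfg, "score")
            if not cfg.has_option("score", "gene_sets"):
                raise ConfigError("[score] gene_sets: path missing")
            gspath = Path(cfg.get("score", "gene_sets"))
            if not gspath.is_absolute():
                gspath = config_path.parent / gspath
            sets = read_gene_sets(gspath)
            results = score_gene_sets(
                norm, sets,
                n_bins=cfg.getint("score", "bins", fallback=25),
                controls_per_gene=cfg.getint("score", "controls", fallback=100),
                seed=seed)
            frame = pd.concat([r.frame() for r in results], ignore_index=True)
            path = write_results(frame, outdir / "scores.tsv")
            _record(manifest, "score", {"scores": path})

        if cfg.has_section("tca"):
            stage = "tca"
            seed = _require_seed(cfg, "tca")
            tc = pseudobulk_timecourse(
                norm, ann,
                cell_type_filter=cfg.get("tca", "cell_type", fallback=None))
            result = fuzzy_cmeans(
                tc,
                k=cfg.getint("tca", "k", fallback=6),
                m=cfg.getfloat("tca", "m", fallback=2.0),
                seed=seed,
                restarts=cfg.getint("tca", "restarts", fallback=20))
            p1 = write_results(result.centroids.reset_index(names="module"),
                               outdir / "tca_centroids.tsv")
            p2 = write_results(result.memberships.reset_index(names="gene"),
                               outdir / "tca_memberships.tsv")
            p3 = write_results(label_centroids(result), outdir / "tca_trends.tsv")
            _record(manifest, "tca",
                    {"centroids": p1, "memberships": p2, "trends": p3})

        if cfg.has_section("deg"):
            stage = "deg"
            table = deg_t_test(
                norm, ann,
                group_a=cfg.get("deg", "group_a", fallback="T5"),
                group_b=cfg.get("deg", "group_b", fallback="T4"),
                min_pct=cfg.getfloat("deg", "min_pct", fallback=0.1),
                logfc_threshold=cfg.getfloat("deg", "logfc", fallback=0.25))
            path = write_results(table, outdir / "deg.tsv")
            _record(manifest, "deg", {"deg": path})

        if cfg.has_section("correlate"):
            stage = "correlate"
            if not cfg.has_option("correlate", "gene"):
                raise ConfigError("[correlate] gene: required")
            if not cfg.has_option("correlate", "gene_sets"):
                raise ConfigError("[correlate] gene_sets: path missing")
            seed = (cfg.getint("correlate", "seed")
                    if cfg.has_option("correlate", "seed")
                    else seeds.get("score", 0))
            gspath = Path(cfg.get("correlate", "gene_sets"))
            if not gspath.is_absolute():
                gspath = config_path.parent / gspath
            sets = read_gene_sets(gspath)
            score_results = score_gene_sets(norm, sets, seed=seed)
            groups = tuple(cfg.get("correlate", "groups", fallback="T4,T5")
                           .split(","))
            res = score_gene_correlation(
                norm, ann, cfg.get("correlate", "gene"), score_results,
                groups=groups,
                score_gate=cfg.getfloat("correlate", "gate", fallback=0.01))
            frame = pd.DataFrame([r.frame_row() for r in res])
            path = write_results(frame, outdir / "correlations.tsv")
            _record(manifest, "correlate", {"correlations": path})
    except ConfigError:
        raise
    except Exception as exc:  # tag failures with the stage that raised
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    log.info("pipeline finished: %d stage(s), manifest at %s",
             len(manifest.stages), manifest_path)
    return manifest
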