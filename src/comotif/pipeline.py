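"""End-to-end orchestration: flanks -> NMF -> filtering -> clustering -> summary.

The pipeline is a plain function over in-memory anchor records (or input
files), fully deterministic under a single seed that fans out to every
stochastic stage.  Multiple datasets can be analyzed together, pooling their
core motifs before clustering so that shared co-binding patterns collapse
into one archetype with a cross-dataset support count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from ._rng import STAGE_NMF, stage_seed
from .anchors import AnchorRecord, dataset_size_gate, read_anchors
from .calibration import CalibrationResult, calibrate_gini_threshold, shuffle_flanks
from .clustering import Archetype, Cluster, build_archetype, cluster_motifs
from .encoding import build_flank_matrices
from .motif_stats import (
    CoreMotif,
    MotifCandidate,
    evaluate_candidate,
    filter_candidates,
    trim_to_core,
    write_rejection_log,
)
from .nmf import discover_candidates
from .summary import CoBindingPattern, build_patterns, write_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of a discovery run."""

    flank_length: int = 30
    anchor_length: int = 10
    k_min: int = 3
    k_max: int = 6
    ic_min: float = 2.0
    gini_min: float = 0.5
    cor_min: float = 0.6
    ncor_min: float = 0.4
    edge_ic_min: float = 0.1
    min_sites: int = 1000
    force: bool = False
    seed: int = 0
    heatmap: bool = False
    # optional file inputs for run_pipeline
    input_path: Optional[str] = None
    input_format: str = "fasta"
    genome: Optional[str] = None

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


@dataclass
class DiscoveryOutput:
    """Per-dataset candidate discovery results."""

    dataset: str
    candidates: list[MotifCandidate]
    kept: list[MotifCandidate]
    rejected: list[MotifCandidate]
    cores: list[CoreMotif]


@dataclass
class AnalysisResult:
    config: RunConfig
    gates: dict[str, bool]
    discoveries: dict[str, DiscoveryOutput]
    clusters: list[Cluster]
    archetypes: list[Archetype]
    patterns: list[CoBindingPattern]
    dataset_sizes: dict[str, int]


def discover_cores(
    records: Sequence[AnchorRecord],
    config: RunConfig,
    dataset: str = "",
    seed: Optional[int] = None,
) -> DiscoveryOutput:
    """Candidate discovery and filtering for one anchor set."""
    seed = config.seed if seed is None else seed
    upstream, downstream = build_flank_matrices(list(records))
    pfms = discover_candidates(
        upstream, downstream, records,
        k_range=(config.k_min, config.k_max),
        seed=seed, dataset=dataset,
    )
    candidates = [evaluate_candidate(p) for p in pfms]
    kept, rejected = filter_candidates(candidates, config.ic_min, config.gini_min)
    cores = [trim_to_core(c) for c in kept]
    logger.info(
        "dataset %s: %d candidates, %d kept, %d cores",
        dataset or "<unnamed>", len(candidates), len(kept), len(cores),
    )
    return DiscoveryOutput(dataset, candidates, kept, rejected, cores)


def analyze_datasets(
    datasets: dict[str, Sequence[AnchorRecord]],
    config: RunConfig,
) -> AnalysisResult:
    """Run discovery on every dataset, pool cores, cluster and summarize."""
    gates: dict[str, bool] = {}
    discoveries: dict[str, DiscoveryOutput] = {}
    pooled: list[CoreMotif] = []
    sizes: dict[str, int] = {}
    for ds_idx, (name, records) in enumerate(sorted(datasets.items())):
        records = list(records)
        sizes[name] = len(records)
        gate = dataset_size_gate(records, config.min_sites)
        gates[name] = gate.passed
        if not gate.passed and not config.force:
            logger.warning("dataset %s gated out (%d sites); skipping discovery", name, gate.count)
            discoveries[name] = DiscoveryOutput(name, [], [], [], [])
            continue
        out = discover_cores(
            records, config, dataset=name,
            seed=stage_seed(config.seed, STAGE_NMF, ds_idx),
        )
        discoveries[name] = out
        pooled.extend(out.cores)

    clusters = cluster_motifs(pooled, config.cor_min, config.ncor_min)
    archetypes = [build_archetype(c, config.edge_ic_min) for c in clusters]
    patterns = build_patterns(archetypes, sizes, config.edge_ic_min)
    return AnalysisResult(
        config=config,
        gates=gates,
        discoveries=discoveries,
        clusters=clusters,
        archetypes=archetypes,
        patterns=patterns,
        dataset_sizes=sizes,
    )


def run_dataset(
    records: Sequence[AnchorRecord],
    config: Optional[RunConfig] = None,
    dataset: str = "anchors",
) -> AnalysisResult:
    """Single-dataset convenience wrapper around :func:`analyze_datasets`."""
    return analyze_datasets({dataset: records}, config or RunConfig())


def run_pipeline(
    config: RunConfig,
    out_dir: Union[str, Path],
    records: Optional[Sequence[AnchorRecord]] = None,
    dataset: str = "anchors",
) -> AnalysisResult:
    """Full run with outputs written to ``out_dir``.

    Records may be passed in memory or read from ``config.input_path``.
    Writes the summary TSV, archetype motif files, co-bound BED, rejection
    log and the serialized configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if records is None:
        if config.input_path is None:
            raise ValueError("either records or config.input_path is required")
        records = read_anchors(
            config.input_path, config.input_format,
            config.anchor_length, config.flank_length, config.genome,
        )
    result = analyze_datasets({dataset: records}, config)
    config.to_yaml(out_dir / "config.yaml")
    write_summary(
        result.patterns, out_dir,
        records_by_dataset={dataset: list(records)},
        heatmap=config.heatmap,
    )
    rejected = [c for d in result.discoveries.values() for c in d.rejected]
    write_rejection_log(rejected, out_dir / "rejected_candidates.tsv")
    return result


def run_multi(
    datasets: dict[str, Sequence[AnchorRecord]],
    config: RunConfig,
    out_dir: Optional[Union[str, Path]] = None,
) -> AnalysisResult:
    """Joint analysis of several anchor sets with pooled clustering."""
    result = analyze_datasets(datasets, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        write_summary(
            result.patterns, out_dir,
            records_by_dataset={k: list(v) for k, v in datasets.items()},
            heatmap=config.heatmap,
        )
        rejected = [c for d in result.discoveries.values() for c in d.rejected]
        write_rejection_log(rejected, out_dir / "rejected_candidates.tsv")
    return result


def calibrate_datasets(
    datasets: dict[str, Sequence[AnchorRecord]],
    config: Optional[RunConfig] = None,
    fdr_target: float = 0.01,
) -> CalibrationResult:
    """Calibrate the Gini threshold from shuffled-flank nulls.

    For every dataset, candidate Gini scores are collected from the real
    flanks and from mononucleotide-shuffled flanks; the pooled distributions
    set the threshold at the target FDR.
    """
    config = config or RunConfig()
    real, null = [], []
    for ds_idx, (name, records) in enumerate(sorted(datasets.items())):
        records = list(records)
        out = discover_cores(
            records, config, dataset=name,
            seed=stage_seed(config.seed, STAGE_NMF, ds_idx),
        )
        real.extend(c.gini for c in out.candidates)
        shuffled = shuffle_flanks(records, seed=stage_seed(config.seed, STAGE_NMF, ds_idx, 999))
        null_out = discover_cores(
            shuffled, config, dataset=f"{name}:null",
            seed=stage_seed(config.seed, STAGE_NMF, ds_idx, 1000),
        )
        null.extend(c.gini for c in null_out.candidates)
    return calibrate_gini_threshold(real, null, fdr_target)
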