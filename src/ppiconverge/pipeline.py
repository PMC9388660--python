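"""Full pipeline orchestration: raw evidence -> ranked convergent targets.

Stage order: read evidence -> collapse -> evidence filter -> cell-type
restriction -> graph -> membership statistics -> Monte Carlo null ->
convergence filters + seed re-expansion -> composite scores -> top-N.
Every intermediate table is written to the output directory together
with a stage-count log and a machine-readable run manifest, so runs are
auditable and reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import interactions_io as iio
from . import expression_atlas as ea
from . import ego_network as ego
from .null_model import ConvergenceAnalyzer
from .prioritization import composite_scores, top_targets

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run (defaults: 2-publication
    or 2-method evidence, radius 2, 1000 replicates, 3 SD, top 25,
    human taxon)."""

    interactions: str
    atlas: str
    seeds: str
    output_dir: str
    symbol_map: str | None = None
    taxon: int = iio.HUMAN_TAXON
    target_clusters: Sequence[str] = field(default_factory=list)
    min_publications: int = 2
    min_methods: int = 2
    min_level: float = 0.0
    radius: int = 2
    replicates: int = 1000
    sd_multiplier: float = 3.0
    min_membership: int = 2
    top_n: int = 25
    include_restored_seeds: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        for name, path in [
            ("interactions", self.interactions),
            ("atlas", self.atlas),
            ("seeds", self.seeds),
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")
        if self.symbol_map and not Path(self.symbol_map).exists():
            raise FileNotFoundError(f"symbol_map path does not exist: {self.symbol_map}")
        checks = [
            ("taxon", self.taxon, 1),
            ("min_publications", self.min_publications, 1),
            ("min_methods", self.min_methods, 1),
            ("radius", self.radius, 0),
            ("replicates", self.replicates, 1),
            ("min_membership", self.min_membership, 0),
            ("top_n", self.top_n, 1),
        ]
        for name, value, lo in checks:
            if value < lo:
                raise ValueError(f"{name} must be >= {lo}, got {value}")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if not self.target_clusters:
            raise ValueError("target_clusters must name at least one cluster")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("read_evidence")
        records = iio.read_interaction_table(config.interactions)
        counts["evidence_records"] = len(records)

        _stage("collapse_and_filter_edges")
        edges = iio.collapse_to_edges(records, taxon=config.taxon)
        counts["collapsed_edges"] = len(edges)
        edges = iio.filter_edges(
            edges,
            min_publications=config.min_publications,
            min_methods=config.min_methods,
        )
        counts["filtered_edges"] = len(edges)
        iio.write_edge_table(edges, out / "edges.tsv")

        _stage("cell_type_restriction")
        atlas = ea.read_atlas(config.atlas)
        allowed = ea.genes_present(
            atlas, config.target_clusters, min_level=config.min_level
        )
        graph = ego.build_graph(edges)
        counts["nodes_before_restriction"] = graph.number_of_nodes()
        graph = ego.restrict_to_genes(graph, allowed)
        counts["nodes"] = graph.number_of_nodes()
        counts["edges"] = graph.number_of_edges()

        _stage("membership_and_null")
        seed_symbols = ego.read_seed_list(config.seeds)
        analyzer = ConvergenceAnalyzer(
            radius=config.radius,
            replicates=config.replicates,
            sd_multiplier=config.sd_multiplier,
            min_membership=config.min_membership,
            random_state=config.rng_seed,
        ).fit(graph, seed_symbols)
        counts["seeds_total"] = len(analyzer.stats_.seeds.genes)
        counts["seeds_present"] = len(analyzer.stats_.seeds.present)
        counts["seeds_missing"] = len(analyzer.stats_.seeds.missing)
        counts["genes_retained"] = len(analyzer.retained_)
        analyzer.stats_.to_frame().to_csv(
            out / "membership.tsv", sep="\t", index=False
        )
        analyzer.results_.to_csv(out / "convergence.tsv", sep="\t", index=False)

        _stage("composite_scores")
        metrics = ea.atlas_metrics(
            atlas,
            analyzer.results_.loc[analyzer.results_["retained"], "gene"].tolist(),
            config.target_clusters,
            min_level=config.min_level,
        )
        metrics.to_csv(out / "atlas_metrics.tsv", sep="\t", index=False)
        scores = composite_scores(
            analyzer.results_,
            metrics,
            include_restored_seeds=config.include_restored_seeds,
        )
        counts["genes_scored"] = len(scores)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        top = top_targets(scores, n=config.top_n)
        (out / "top_targets.txt").write_text("\n".join(top) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in asdict(config).items()
        },
        "counts": counts,
        "top_targets": top,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("stage counts: %s", counts)
    return manifest
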