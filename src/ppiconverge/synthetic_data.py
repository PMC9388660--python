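"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators, all seeded and deterministic:

* evidence tables in the BioGRID TAB3 column layout, with controllable
  probabilities of a second supporting publication, a second
  experimental method, and off-taxon contamination — plus the exact
  ground truth of which pairs survive the default evidence filter;
* non-negative log-normal expression atlases with designated genes
  enriched in the target clusters by a known factor;
* graphs with planted convergent hubs: hub nodes wired to every seed so
  their 2-hop membership proportion is 1 by construction, over an
  Erdős–Rényi background (optionally a configuration-model background
  with the same degree sequence, for stress tests).

These emulate what the analysis needs — evidence multiplicity, planted
enrichment, planted convergence — not the degree distribution of real
interactomes or the cluster structure of real atlases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression_atlas import ExpressionAtlas
from .ego_network import SeedList
from .interactions_io import BIOGRID_TAB3_COLUMNS, HUMAN_TAXON

_OFF_TAXON = 10090  # mouse, as the contaminating organism
_SYSTEMS = ["Two-hybrid", "Affinity Capture-MS", "Co-fractionation"]


@dataclass(frozen=True)
class EvidenceTruth:
    """Ground truth for a generated evidence table."""

    pairs: tuple[tuple[str, str], ...]  # all sampled on-taxon pairs
    multi_evidence_pairs: frozenset[tuple[str, str]]  # survive default filter


@dataclass(frozen=True)
class PlantedConvergenceTruth:
    """A graph with hubs adjacent to every seed, plus labels."""

    graph: nx.Graph
    seeds: SeedList
    planted_hubs: frozenset[str]
    background_nodes: frozenset[str]


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_interaction_table(
    path: str | Path,
    n_genes: int = 50,
    n_pairs: int = 100,
    p_second_pub: float = 0.5,
    p_second_method: float = 0.0,
    p_off_taxon: float = 0.0,
    rng_seed: int = 0,
) -> EvidenceTruth:
    """Write a TAB3-layout evidence table and return its ground truth.

    Each sampled gene pair gets one base evidence row; with probability
    ``p_second_pub`` an extra row from a second publication, and with
    ``p_second_method`` an extra row from a second experimental system.
    A fraction ``p_off_taxon`` of pairs is written with a non-target
    organism on both interactors. ``multi_evidence_pairs`` lists the
    on-taxon pairs that meet the default 2-publications-or-2-methods
    filter.
    """
    max_pairs = n_genes * (n_genes - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"cannot sample {n_pairs} pairs from {n_genes} genes")
    rng = np.random.default_rng(rng_seed)
    genes = _gene_names(n_genes)
    tri_i, tri_j = np.triu_indices(n_genes, k=1)
    idx = rng.choice(max_pairs, size=n_pairs, replace=False)
    rows = []
    kept_pairs: list[tuple[str, str]] = []
    multi: set[tuple[str, str]] = set()
    for pair_no, i in enumerate(np.sort(idx)):
        a, b = genes[tri_i[i]], genes[tri_j[i]]
        off = rng.random() < p_off_taxon
        taxon = _OFF_TAXON if off else HUMAN_TAXON
        base_pub = f"PUBMED:{100000 + pair_no}"
        rows.append((a, b, taxon, taxon, base_pub, _SYSTEMS[0], "physical"))
        extra_pub = rng.random() < p_second_pub
        extra_method = rng.random() < p_second_method
        if extra_pub:
            rows.append(
                (a, b, taxon, taxon, f"PUBMED:{200000 + pair_no}", _SYSTEMS[0], "physical")
            )
        if extra_method:
            rows.append((a, b, taxon, taxon, base_pub, _SYSTEMS[1], "physical"))
        if not off:
            kept_pairs.append((a, b))
            if extra_pub or extra_method:
                multi.add((a, b))
    header = "\t".join(BIOGRID_TAB3_COLUMNS[f] for f in BIOGRID_TAB3_COLUMNS)
    lines = ["#" + header]
    lines += ["\t".join(str(x) for x in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n")
    return EvidenceTruth(
        pairs=tuple(kept_pairs), multi_evidence_pairs=frozenset(multi)
    )


def generate_atlas(
    n_genes: int = 100,
    n_clusters: int = 10,
    n_target_clusters: int = 3,
    enriched_genes: Sequence[str] = (),
    enrichment_factor: float = 10.0,
    noise_sigma: float = 0.5,
    rng_seed: int = 0,
    gene_names: Sequence[str] | None = None,
) -> tuple[ExpressionAtlas, list[str]]:
    """Log-normal atlas with designated genes enriched in the target
    clusters by ``enrichment_factor``; returns (atlas, target clusters).

    Cluster labels follow the Dropviz convention (``SN_4.1`` ...), with
    the first ``n_target_clusters`` as the target cell type. Baseline
    values are exp(N(0, noise_sigma)); ``noise_sigma=0`` gives exact
    factor recovery.
    """
    if enrichment_factor <= 1:
        raise ValueError("enrichment_factor must be > 1")
    rng = np.random.default_rng(rng_seed)
    genes = (
        [g.upper() for g in gene_names]
        if gene_names is not None
        else _gene_names(n_genes)
    )
    clusters = [f"SN_4.{i + 1}" for i in range(n_target_clusters)] + [
        f"OTHER_{i + 1}" for i in range(n_clusters - n_target_clusters)
    ]
    values = np.exp(rng.normal(0.0, noise_sigma, size=(len(genes), n_clusters)))
    df = pd.DataFrame(values, index=genes, columns=clusters)
    targets = clusters[:n_target_clusters]
    for g in enriched_genes:
        df.loc[g.upper(), targets] *= enrichment_factor
    return ExpressionAtlas(values=df), targets


def generate_planted_convergence(
    n_nodes: int = 200,
    n_seeds: int = 20,
    n_hubs: int = 2,
    p_background: float = 0.02,
    rng_seed: int = 0,
    background: str = "erdos_renyi",
) -> PlantedConvergenceTruth:
    """Graph with ``n_hubs`` nodes wired to every seed over a random
    background.

    Every hub is adjacent to every seed — and to nothing else, so the
    planted convergence signal is exactly the hub-seed wiring and the
    truth labels stay clean (a hub with random background edges would
    promote its neighbors into unintended full-membership nodes). At
    radius >= 1 each hub's membership proportion is exactly 1.
    ``background`` is 'erdos_renyi' (each non-hub edge independent with
    ``p_background``) or 'configuration' (degree sequence of an
    Erdős–Rényi draw, rewired).
    """
    if n_hubs + n_seeds > n_nodes:
        raise ValueError("n_hubs + n_seeds exceeds n_nodes")
    names = _gene_names(n_nodes, prefix="N")
    hubs = names[:n_hubs]
    seeds = names[n_hubs : n_hubs + n_seeds]
    rest = names[n_hubs + n_seeds :]
    rng = np.random.default_rng(rng_seed)
    if background == "erdos_renyi":
        bg = nx.erdos_renyi_graph(n_nodes, p_background, seed=int(rng.integers(2**31)))
    elif background == "configuration":
        proto = nx.erdos_renyi_graph(
            n_nodes, p_background, seed=int(rng.integers(2**31))
        )
        degrees = [d for _, d in proto.degree()]
        multigraph = nx.configuration_model(
            degrees, seed=int(rng.integers(2**31))
        )
        bg = nx.Graph(multigraph)
        bg.remove_edges_from(nx.selfloop_edges(bg))
    else:
        raise ValueError(f"unknown background model '{background}'")
    graph = nx.relabel_nodes(bg, dict(enumerate(names)))
    for h in hubs:  # hubs carry only the planted hub-seed edges
        graph.remove_edges_from(list(graph.edges(h)))
    graph.add_nodes_from(names)
    graph.add_edges_from((h, s) for h in hubs for s in seeds)
    return PlantedConvergenceTruth(
        graph=graph,
        seeds=SeedList.from_symbols(seeds, graph),
        planted_hubs=frozenset(hubs),
        background_nodes=frozenset(rest),
    )


def write_seed_list(seeds: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(seeds) + "\n")
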