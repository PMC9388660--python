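"""Filtered PPI graph and ego-community membership statistics.

A "community" here is the 2-hop ego neighborhood of a seed gene: the set
of nodes at unweighted shortest-path distance <= radius from the seed,
the seed itself included (distance 0). For a seed list, each gene's
membership number counts the seed communities containing it, and the
membership proportion divides by the number of communities (= seeds
actually present in the graph).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .interactions_io import InteractionEdge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedList:
    """Ordered unique seed gene symbols, split by graph presence."""

    genes: tuple[str, ...]
    present: frozenset[str] = frozenset()
    missing: frozenset[str] = frozenset()

    @classmethod
    def from_symbols(
        cls, symbols: Iterable[str], graph: nx.Graph | None = None
    ) -> "SeedList":
        ordered = tuple(dict.fromkeys(s.strip().upper() for s in symbols if s.strip()))
        if graph is None:
            return cls(genes=ordered, present=frozenset(ordered), missing=frozenset())
        present = frozenset(g for g in ordered if g in graph)
        return cls(
            genes=ordered,
            present=present,
            missing=frozenset(ordered) - present,
        )


@dataclass(frozen=True)
class CommunityStats:
    """Per-gene membership counts for one seed list at one radius."""

    seeds: SeedList
    radius: int
    n_communities: int
    membership_number: dict[str, int]
    membership_proportion: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        seed_set = set(self.seeds.genes)
        rows = [
            {
                "gene": g,
                "membership_number": n,
                "membership_proportion": self.membership_proportion[g],
                "is_seed": g in seed_set,
            }
            for g, n in sorted(self.membership_number.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "membership_number", "membership_proportion", "is_seed"],
        )


def build_graph(edges: Sequence[InteractionEdge]) -> nx.Graph:
    """Undirected simple graph over the edge endpoints."""
    g = nx.Graph()
    g.add_edges_from(e.gene_pair for e in edges)
    return g


def restrict_to_genes(graph: nx.Graph, allowed: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``nodes & allowed`` (cell-type restriction)."""
    allowed = set(allowed)
    return graph.subgraph(n for n in graph.nodes if n in allowed).copy()


def community(graph: nx.Graph, gene: str, radius: int = 2) -> set[str]:
    """Nodes at shortest-path distance <= radius from ``gene``, inclusive."""
    if gene not in graph:
        raise KeyError(f"gene '{gene}' is not a node of the graph")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    return set(nx.single_source_shortest_path_length(graph, gene, cutoff=radius))


def read_seed_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s.upper())
    return list(dict.fromkeys(out))


def membership_stats(
    graph: nx.Graph,
    seeds: SeedList | Iterable[str],
    radius: int = 2,
) -> CommunityStats:
    """Membership number and proportion of every gene reached by at least
    one seed community.

    Genes never reached are absent from the maps (sparse representation).
    Seeds missing from the graph induce no community and do not count in
    the proportion denominator; they are logged and carried on the
    returned :class:`SeedList` for the later re-expansion step.
    """
    if not isinstance(seeds, SeedList):
        seeds = SeedList.from_symbols(seeds, graph)
    elif not seeds.present and not seeds.missing:
        seeds = SeedList.from_symbols(seeds.genes, graph)
    if not seeds.present:
        raise ValueError("no seed gene is present in the graph")
    if seeds.missing:
        logger.info(
            "%d seed(s) absent from graph: %s",
            len(seeds.missing),
            sorted(seeds.missing),
        )
    counts: dict[str, int] = {}
    for s in sorted(seeds.present):
        for g in community(graph, s, radius):
            counts[g] = counts.get(g, 0) + 1
    n_communities = len(seeds.present)
    return CommunityStats(
        seeds=seeds,
        radius=radius,
        n_communities=n_communities,
        membership_number=counts,
        membership_proportion={g: n / n_communities for g, n in counts.items()},
    )
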