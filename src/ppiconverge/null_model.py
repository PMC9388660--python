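"""Monte Carlo null model for ego-community membership and the
convergence filters.

Observed membership proportions are compared against the distribution
obtained when seed sets of the same size are drawn uniformly at random
from the graph's nodes. For each node the null provides a mean and
standard deviation of membership proportion across replicates; the
observed statistic is then (a) divided by the null mean to give a fold
enrichment ("connectivity value", in the spirit of the Panther-style
overrepresentation ratio) and (b) thresholded at mean + 3 SD. Genes in
only one community are excluded, and input seed genes dropped anywhere
along the pipeline are restored to the output list with a flag.

Under uniform sampling without replacement the null is exactly
hypergeometric: for a node v whose ego ball holds m_v of the N nodes,
the number of the k random seeds that land inside the ball is
Hypergeometric(N, m_v, k). ``closed_form_null`` exposes these exact
moments as an analytic oracle for the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .ego_network import CommunityStats, SeedList, membership_stats

RESULT_COLUMNS = [
    "gene",
    "observed_membership_number",
    "observed_proportion",
    "expected_mean",
    "expected_sd",
    "fold_enrichment",
    "passes_sd_filter",
    "passes_membership_filter",
    "is_restored_seed",
    "retained",
]


@dataclass(frozen=True)
class NullSummary:
    """Per-node null mean/SD of membership proportion.

    ``replicates`` is 0 for the analytic (closed-form) summary, which has
    no Monte Carlo error and no RNG seed.
    """

    replicates: int
    seed_set_size: int
    radius: int
    node_mean: dict[str, float]
    node_sd: dict[str, float]
    rng_seed: int | None = None


def _ball_matrix(graph: nx.Graph, radius: int) -> tuple[list[str], sp.csr_matrix]:
    """Sorted node list and boolean CSR B with B[i, j] = 1 iff node j lies
    within ``radius`` hops of node i (diagonal included)."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for n in nodes:
        i = index[n]
        for m in nx.single_source_shortest_path_length(graph, n, cutoff=radius):
            rows.append(i)
            cols.append(index[m])
    n_nodes = len(nodes)
    data = np.ones(len(rows), dtype=np.float64)
    return nodes, sp.csr_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))


def simulate_null(
    graph: nx.Graph,
    seed_set_size: int,
    replicates: int = 1000,
    radius: int = 2,
    rng_seed: int | None = None,
) -> NullSummary:
    """Monte Carlo null: membership proportions for random seed sets.

    Each replicate draws ``seed_set_size`` distinct nodes uniformly
    without replacement; every node's membership proportion is computed
    (nodes in no community contribute 0). Means use divisor R, standard
    deviations the sample divisor R - 1. Deterministic given ``rng_seed``.
    """
    n_nodes = graph.number_of_nodes()
    if not 1 <= seed_set_size <= n_nodes:
        raise ValueError(
            f"seed_set_size {seed_set_size} outside [1, {n_nodes}] for this graph"
        )
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    nodes, balls = _ball_matrix(graph, radius)
    rng = np.random.default_rng(rng_seed)
    # Replicate-by-node sampling indicator; counts = S @ B gives each
    # node's membership number in each replicate in one sparse product.
    rows = np.repeat(np.arange(replicates), seed_set_size)
    cols = np.concatenate(
        [rng.choice(n_nodes, size=seed_set_size, replace=False) for _ in range(replicates)]
    )
    sampler = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(replicates, n_nodes)
    )
    proportions = np.asarray((sampler @ balls).todense()) / seed_set_size
    means = proportions.mean(axis=0)
    sds = (
        proportions.std(axis=0, ddof=1)
        if replicates > 1
        else np.zeros(n_nodes)
    )
    return NullSummary(
        replicates=replicates,
        seed_set_size=seed_set_size,
        radius=radius,
        node_mean=dict(zip(nodes, means.tolist())),
        node_sd=dict(zip(nodes, sds.tolist())),
        rng_seed=rng_seed,
    )


def closed_form_null(
    graph: nx.Graph, seed_set_size: int, radius: int = 2
) -> NullSummary:
    """Exact hypergeometric null moments (no randomness).

    For node v with ball size m out of N nodes and k random seeds, the
    membership proportion X/k has mean m/N and variance
    (1/k) (m/N) (1 - m/N) (N - k)/(N - 1); a single-node graph has
    variance 0 by convention.
    """
    n_nodes = graph.number_of_nodes()
    if not 1 <= seed_set_size <= n_nodes:
        raise ValueError(
            f"seed_set_size {seed_set_size} outside [1, {n_nodes}] for this graph"
        )
    nodes, balls = _ball_matrix(graph, radius)
    m = np.asarray(balls.sum(axis=1)).ravel()
    frac = m / n_nodes
    if n_nodes == 1:
        var = np.zeros(1)
    else:
        fpc = (n_nodes - seed_set_size) / (n_nodes - 1)
        var = frac * (1.0 - frac) * fpc / seed_set_size
    return NullSummary(
        replicates=0,
        seed_set_size=seed_set_size,
        radius=radius,
        node_mean=dict(zip(nodes, frac.tolist())),
        node_sd=dict(zip(nodes, np.sqrt(var).tolist())),
        rng_seed=None,
    )


def convergence_table(
    stats: CommunityStats,
    null: NullSummary,
    seeds: SeedList | None = None,
    sd_multiplier: float = 3.0,
    min_membership: int = 2,
) -> pd.DataFrame:
    """Apply the overrepresentation filters and seed re-expansion.

    For every gene with observed membership: fold enrichment divides the
    observed proportion by max(null mean, floor) where floor =
    1/(replicates x n_communities) — the smallest nonzero proportion the
    simulation can resolve; ``passes_sd_filter`` requires the observed
    proportion to reach null mean + sd_multiplier x SD; genes in fewer
    than ``min_membership`` communities fail the membership filter. A
    gene is ``retained`` when it passes both. Input seed genes not
    retained are appended with ``is_restored_seed`` True and their raw
    observed statistics (zeros when absent from the graph).
    """
    if stats.radius != null.radius:
        raise ValueError(
            f"radius mismatch: stats at {stats.radius}, null at {null.radius}"
        )
    missing_nodes = [g for g in stats.membership_number if g not in null.node_mean]
    if missing_nodes:
        raise ValueError(
            "stats and null were computed on different node universes; "
            f"e.g. {missing_nodes[:5]} absent from the null summary"
        )
    seeds = seeds or stats.seeds
    floor = 1.0 / (max(null.replicates, 1) * stats.n_communities)
    rows = []
    for gene in sorted(stats.membership_number):
        number = stats.membership_number[gene]
        prop = stats.membership_proportion[gene]
        mean = null.node_mean[gene]
        sd = null.node_sd[gene]
        rows.append(
            {
                "gene": gene,
                "observed_membership_number": number,
                "observed_proportion": prop,
                "expected_mean": mean,
                "expected_sd": sd,
                "fold_enrichment": prop / max(mean, floor),
                "passes_sd_filter": prop >= mean + sd_multiplier * sd,
                "passes_membership_filter": number >= min_membership,
                "is_restored_seed": False,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    df["retained"] = df["passes_sd_filter"] & df["passes_membership_filter"]
    retained_genes = set(df.loc[df["retained"], "gene"])
    restored = []
    for gene in seeds.genes:
        if gene in retained_genes:
            continue
        number = stats.membership_number.get(gene, 0)
        mean = null.node_mean.get(gene, 0.0)
        sd = null.node_sd.get(gene, 0.0)
        prop = stats.membership_proportion.get(gene, 0.0)
        restored.append(
            {
                "gene": gene,
                "observed_membership_number": number,
                "observed_proportion": prop,
                "expected_mean": mean,
                "expected_sd": sd,
                "fold_enrichment": prop / max(mean, floor),
                "passes_sd_filter": prop >= mean + sd_multiplier * sd,
                "passes_membership_filter": number >= min_membership,
                "is_restored_seed": True,
                "retained": True,
            }
        )
    if restored:
        # seeds already listed as non-retained rows are replaced by their
        # flagged copies so each gene appears once
        restored_df = pd.DataFrame(restored, columns=RESULT_COLUMNS)
        df = df[~df["gene"].isin(restored_df["gene"])]
        df = pd.concat([df, restored_df], ignore_index=True)
    return df.sort_values(
        ["retained", "fold_enrichment", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)


class NullModel(BaseEstimator):
    """Per-node null distribution of ego-community membership proportion.

    Parameters
    ----------
    replicates : int, default 1000
        Monte Carlo replicates (ignored when ``method='closed_form'``).
    radius : int, default 2
        Ego-community radius in edges.
    method : {'monte_carlo', 'closed_form'}
        Simulation or exact hypergeometric moments.
    random_state : int or None
        Seed for the replicate sampler.

    Attributes
    ----------
    node_mean_, node_sd_ : dict
        Per-node null mean and SD of membership proportion.
    summary_ : NullSummary
    """

    def __init__(
        self,
        replicates: int = 1000,
        radius: int = 2,
        method: str = "monte_carlo",
        random_state: int | None = None,
    ):
        self.replicates = replicates
        self.radius = radius
        self.method = method
        self.random_state = random_state

    def fit(self, graph: nx.Graph, seed_set_size: int) -> "NullModel":
        if self.method == "monte_carlo":
            self.summary_ = simulate_null(
                graph,
                seed_set_size,
                replicates=self.replicates,
                radius=self.radius,
                rng_seed=self.random_state,
            )
        elif self.method == "closed_form":
            self.summary_ = closed_form_null(
                graph, seed_set_size, radius=self.radius
            )
        else:
            raise ValueError(f"unknown method '{self.method}'")
        self.node_mean_ = self.summary_.node_mean
        self.node_sd_ = self.summary_.node_sd
        return self


class ConvergenceAnalyzer(BaseEstimator):
    """End-to-end convergence analysis of a seed list on a PPI graph.

    Fitting runs the ego-community membership statistics, the Monte Carlo
    null, the 3-SD and membership-number filters, and the seed
    re-expansion, leaving the full per-gene table in ``results_``.

    Attributes
    ----------
    stats_ : CommunityStats
    null_ : NullSummary
    results_ : pandas.DataFrame
        One row per gene (observed and expected statistics, fold
        enrichment, filter flags, ``retained``).
    retained_ : list of str
        Genes retained by the filters plus restored seeds.
    """

    def __init__(
        self,
        radius: int = 2,
        replicates: int = 1000,
        sd_multiplier: float = 3.0,
        min_membership: int = 2,
        random_state: int | None = None,
    ):
        self.radius = radius
        self.replicates = replicates
        self.sd_multiplier = sd_multiplier
        self.min_membership = min_membership
        self.random_state = random_state

    def fit(
        self, graph: nx.Graph, seeds: SeedList | Iterable[str]
    ) -> "ConvergenceAnalyzer":
        self.stats_ = membership_stats(graph, seeds, radius=self.radius)
        self.null_ = simulate_null(
            graph,
            seed_set_size=len(self.stats_.seeds.present),
            replicates=self.replicates,
            radius=self.radius,
            rng_seed=self.random_state,
        )
        self.results_ = convergence_table(
            self.stats_,
            self.null_,
            seeds=self.stats_.seeds,
            sd_multiplier=self.sd_multiplier,
            min_membership=self.min_membership,
        )
        self.retained_ = self.results_.loc[
            self.results_["retained"], "gene"
        ].tolist()
        return self
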