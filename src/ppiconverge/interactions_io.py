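"""Parse interaction-evidence tables and collapse them into filtered edges.

The input is a BioGRID TAB3-style tab-delimited table: one row per piece
of experimental evidence that two proteins interact, carrying the two
interactor symbols, the organism taxon of each interactor, a publication
identifier, and the experimental system that produced the evidence.
Rows are collapsed to one undirected edge per gene pair with distinct
publication / method counts, and edges are kept when they are supported
by at least ``min_publications`` publications OR at least ``min_methods``
distinct experimental methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the semantic fields in a BioGRID TAB3 header.
BIOGRID_TAB3_COLUMNS: Mapping[str, str] = {
    "interactor_a": "Official Symbol Interactor A",
    "interactor_b": "Official Symbol Interactor B",
    "organism_a": "Organism ID Interactor A",
    "organism_b": "Organism ID Interactor B",
    "publication_id": "Publication Source",
    "experimental_system": "Experimental System",
    "experimental_system_type": "Experimental System Type",
}

_SEMANTIC_FIELDS = tuple(BIOGRID_TAB3_COLUMNS)

HUMAN_TAXON = 9606


@dataclass(frozen=True)
class TableDialect:
    """Maps the seven semantic evidence columns onto file column names.

    ``columns`` maps semantic field names (``interactor_a`` ...) to the
    header names (or 0-based integer indices for headerless files) used
    in a particular dump. Defaults to the BioGRID TAB3 header names.
    """

    columns: Mapping[str, str | int] = field(
        default_factory=lambda: dict(BIOGRID_TAB3_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [f for f in _SEMANTIC_FIELDS if f not in self.columns]
        if missing:
            raise ValueError(
                f"dialect is missing mappings for semantic column(s): {missing}"
            )


@dataclass(frozen=True)
class EvidenceRecord:
    """One row of raw interaction evidence."""

    interactor_a: str
    interactor_b: str
    organism_a: int
    organism_b: int
    publication_id: str
    experimental_system: str
    experimental_system_type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.interactor_a.strip() or not self.interactor_b.strip():
            raise ValueError("interactor symbols must be non-empty")
        if self.organism_a <= 0 or self.organism_b <= 0:
            raise ValueError("taxon ids must be positive integers")


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected gene pair with distinct evidence counts.

    ``gene_pair`` is stored in lexicographic order so that the edge for
    (B, A) and (A, B) is the same object value.
    """

    gene_pair: tuple[str, str]
    n_publications: int
    n_methods: int
    n_evidence: int

    def __post_init__(self) -> None:
        a, b = self.gene_pair
        if a == b:
            raise ValueError(f"self-loop edge not allowed: {a}")
        if a > b:
            object.__setattr__(self, "gene_pair", (b, a))
        if min(self.n_publications, self.n_methods) < 1:
            raise ValueError("evidence counts must be >= 1")
        if self.n_evidence < max(self.n_publications, self.n_methods):
            raise ValueError("n_evidence < max(n_publications, n_methods)")


_SYSTEM_TYPES = {"physical", "genetic"}


def _normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def read_interaction_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[EvidenceRecord]:
    """Read a tab-delimited evidence table into :class:`EvidenceRecord` rows.

    The first non-comment line is taken as the header (a leading ``#`` on
    the header, as written by BioGRID, is stripped). Rows whose taxon ids
    do not parse as positive integers are skipped and counted in the log,
    not fatal: public interaction dumps contain malformed rows.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    by_index = all(isinstance(v, int) for v in dialect.columns.values())
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        header=None if by_index else 0,
        comment=None,
        keep_default_na=False,
    )
    if not by_index:
        # BioGRID prefixes its header line with '#'
        df.columns = [str(c).lstrip("#").strip() for c in df.columns]
        df = df[~df.iloc[:, 0].astype(str).str.startswith("#")]
    for fld, col in dialect.columns.items():
        if by_index:
            if col >= df.shape[1]:
                raise KeyError(
                    f"dialect maps '{fld}' to column index {col} but the "
                    f"table has only {df.shape[1]} columns"
                )
        elif col not in df.columns:
            raise KeyError(
                f"dialect maps '{fld}' to column '{col}', not found in header"
            )

    def _col(fld: str) -> pd.Series:
        c = dialect.columns[fld]
        return df.iloc[:, c] if by_index else df[c]

    records: list[EvidenceRecord] = []
    n_skipped = 0
    rows = zip(
        _col("interactor_a"),
        _col("interactor_b"),
        _col("organism_a"),
        _col("organism_b"),
        _col("publication_id"),
        _col("experimental_system"),
        _col("experimental_system_type"),
    )
    for a, b, org_a, org_b, pub, system, system_type in rows:
        try:
            taxon_a, taxon_b = int(org_a), int(org_b)
            system_type = str(system_type).strip().lower()
            if system_type not in _SYSTEM_TYPES:
                system_type = "unknown"
            records.append(
                EvidenceRecord(
                    interactor_a=_normalize_symbol(str(a)),
                    interactor_b=_normalize_symbol(str(b)),
                    organism_a=taxon_a,
                    organism_b=taxon_b,
                    publication_id=str(pub).strip(),
                    experimental_system=str(system).strip(),
                    experimental_system_type=system_type,
                )
            )
        except (ValueError, TypeError):
            n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d unparseable row(s) in %s", n_skipped, path)
    return records


def collapse_to_edges(
    records: Iterable[EvidenceRecord],
    taxon: int = HUMAN_TAXON,
    system_type: str | None = None,
) -> list[InteractionEdge]:
    """Collapse evidence rows into one edge per unordered gene pair.

    Keeps only records where both interactors belong to ``taxon``
    (9606 = human by default), discards self-loops, deduplicates
    identical (pair, publication, system) evidence tuples, and counts
    distinct publications, distinct experimental systems, and distinct
    (publication, system) tuples per pair. Both physical and genetic
    evidence count unless ``system_type`` restricts to one kind.
    """
    seen: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for rec in records:
        if rec.organism_a != taxon or rec.organism_b != taxon:
            continue
        if system_type is not None and rec.experimental_system_type != system_type:
            continue
        if rec.interactor_a == rec.interactor_b:
            continue
        pair = tuple(sorted((rec.interactor_a, rec.interactor_b)))
        seen.setdefault(pair, set()).add(
            (rec.publication_id, rec.experimental_system)
        )
    if not seen:
        logger.warning("no edges survive organism/self-loop filtering")
    edges = []
    for pair in sorted(seen):
        evidence = seen[pair]
        edges.append(
            InteractionEdge(
                gene_pair=pair,
                n_publications=len({pub for pub, _ in evidence}),
                n_methods=len({sys for _, sys in evidence}),
                n_evidence=len(evidence),
            )
        )
    return edges


def filter_edges(
    edges: Sequence[InteractionEdge],
    min_publications: int = 2,
    min_methods: int = 2,
) -> list[InteractionEdge]:
    """Keep edges supported by >=min_publications publications OR
    >=min_methods distinct experimental methods (disjunctive), preserving
    input order."""
    if min(min_publications, min_methods) < 1:
        raise ValueError("thresholds must be >= 1")
    return [
        e
        for e in edges
        if e.n_publications >= min_publications or e.n_methods >= min_methods
    ]


def edges_to_frame(edges: Sequence[InteractionEdge]) -> pd.DataFrame:
    """Edge sequence as a DataFrame (gene_a, gene_b, counts)."""
    return pd.DataFrame(
        [
            {
                "gene_a": e.gene_pair[0],
                "gene_b": e.gene_pair[1],
                "n_publications": e.n_publications,
                "n_methods": e.n_methods,
                "n_evidence": e.n_evidence,
            }
            for e in edges
        ],
        columns=["gene_a", "gene_b", "n_publications", "n_methods", "n_evidence"],
    )


def write_edge_table(edges: Sequence[InteractionEdge], path: str | Path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False)


def read_edge_table(path: str | Path) -> list[InteractionEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        InteractionEdge(
            gene_pair=(str(r.gene_a), str(r.gene_b)),
            n_publications=int(r.n_publications),
            n_methods=int(r.n_methods),
            n_evidence=int(r.n_evidence),
        )
        for r in df.itertuples()
    ]
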