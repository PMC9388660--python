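"""Deterministic gene-list intersection reports (Venn decompositions).

Supports the cross-list comparisons behind the convergence figures:
counts and member symbols for every region of the Venn decomposition of
two or more gene lists, with an optional symbol map applied first (e.g.
mouse -> human homolog symbols) so lists from different species can be
compared. Unmapped symbols pass through unchanged; all comparison is on
upper-cased symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class GeneList:
    """A labeled set of unique, case-normalized gene symbols."""

    label: str
    genes: frozenset[str]

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "GeneList":
        return cls(
            label=label,
            genes=frozenset(s.strip().upper() for s in symbols if s.strip()),
        )

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "GeneList":
        path = Path(path)
        symbols = [
            line.strip()
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls.from_symbols(label or path.stem, symbols)


@dataclass(frozen=True)
class SymbolMap:
    """source symbol -> target symbol; unmapped symbols pass through."""

    pairs: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SymbolMap":
        return cls(
            pairs={
                s.strip().upper(): t.strip().upper() for s, t in pairs
            }
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SymbolMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("symbol map needs two tab-separated columns")
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def apply(self, genes: Iterable[str]) -> frozenset[str]:
        return frozenset(self.pairs.get(g, g) for g in genes)


def intersect(
    lists: Sequence[GeneList], mapping: SymbolMap | None = None
) -> pd.DataFrame:
    """Every region of the Venn decomposition of two or more lists.

    Returns one row per non-trivial membership pattern: the lists a
    region belongs to, its size, and its member symbols (alphabetical,
    semicolon-joined). Empty regions are reported with count 0 so the
    report shape depends only on the number of lists.
    """
    if len(lists) < 2:
        raise ValueError("need at least two gene lists to intersect")
    labels = [gl.label for gl in lists]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate list labels: {labels}")
    sets = {
        gl.label: (mapping.apply(gl.genes) if mapping else gl.genes)
        for gl in lists
    }
    universe = frozenset().union(*sets.values())
    rows = []
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            outside = [l for l in labels if l not in inside]
            region = frozenset.intersection(*(sets[l] for l in inside))
            for l in outside:
                region = region - sets[l]
            rows.append(
                {
                    "region": "&".join(inside),
                    "n_lists": r,
                    "count": len(region),
                    "genes": ";".join(sorted(region)),
                }
            )
    df = pd.DataFrame(rows, columns=["region", "n_lists", "count", "genes"])
    assert df["count"].sum() == len(universe)
    return df
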