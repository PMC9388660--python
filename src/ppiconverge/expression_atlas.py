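"""Gene x cell-cluster expression atlas and the cell-type quantities.

The atlas is an abstract non-negative matrix of mean expression per
(gene, cluster), e.g. a Dropviz-style brain single-cell summary. Three
quantities feed the pipeline:

* presence  — expression above a threshold in at least one target cluster
  (used to restrict the interactome to the cell type of interest);
* abundance — mean expression over the target clusters ("Expression");
* relative enrichment — target mean over off-target mean, with a small
  pseudocount guard ("Relative Enrichment in Cell Type").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionAtlas:
    """Non-negative mean-expression matrix over unique genes x clusters."""

    values: pd.DataFrame  # genes as index (upper-case), clusters as columns

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene label(s): {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cluster label(s): {dup}")
        arr = df.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            bad = np.argwhere(~(np.isfinite(arr) & (arr >= 0)))[0]
            raise ValueError(
                "atlas values must be finite and non-negative; offending "
                f"cell at gene '{df.index[bad[0]]}', cluster '{df.columns[bad[1]]}'"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.values.columns)

    def _check_clusters(self, target_clusters: Iterable[str]) -> list[str]:
        targets = list(dict.fromkeys(target_clusters))
        unknown = [c for c in targets if c not in self.values.columns]
        if unknown:
            raise KeyError(
                f"unknown cluster label(s) {unknown}; valid labels: "
                f"{list(self.values.columns)}"
            )
        if not targets:
            raise ValueError("target cluster set is empty")
        return targets


def read_atlas(path: str | Path) -> ExpressionAtlas:
    """Read a delimited gene x cluster matrix (TSV or CSV by extension).

    First column holds gene labels (upper-cased on read), first row holds
    cluster labels. Negative or non-numeric cells are fatal.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty or df.shape[0] == 0:
        raise ValueError(f"no genes found in atlas file {path}")
    df.index = [str(g).strip().upper() for g in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    if non_numeric:
        raise ValueError(f"non-numeric values in cluster column(s) {non_numeric}")
    return ExpressionAtlas(values=df.astype(float))


def genes_present(
    atlas: ExpressionAtlas,
    target_clusters: Iterable[str],
    min_level: float = 0.0,
) -> set[str]:
    """Genes whose expression strictly exceeds ``min_level`` in at least
    one target cluster — the cell-type presence filter."""
    targets = atlas._check_clusters(target_clusters)
    mask = (atlas.values[targets] > min_level).any(axis=1)
    return set(atlas.values.index[mask])


def abundance(
    atlas: ExpressionAtlas, gene: str, target_clusters: Iterable[str]
) -> float:
    """Mean expression of ``gene`` over the target clusters.

    A gene absent from the atlas returns NaN (treated as 0 in scoring and
    flagged); it is not an error, since the interaction evidence and the
    atlas come from different sources.
    """
    targets = atlas._check_clusters(target_clusters)
    gene = gene.strip().upper()
    if gene not in atlas.values.index:
        return float("nan")
    return float(atlas.values.loc[gene, targets].mean())


def default_pseudocount(atlas: ExpressionAtlas) -> float:
    """1e-6 of the atlas-wide maximum (1e-6 if the atlas is all zero)."""
    top = float(atlas.values.to_numpy().max()) if atlas.values.size else 0.0
    return 1e-6 * top if top > 0 else 1e-6


def relative_enrichment(
    atlas: ExpressionAtlas,
    gene: str,
    target_clusters: Iterable[str],
    pseudocount: float | None = None,
) -> float:
    """(target mean + pc) / (off-target mean + pc) for one gene.

    The pseudocount (default 1e-6 of the atlas maximum) keeps the ratio
    finite for genes expressed only in the target clusters. Genes absent
    from the atlas return NaN.
    """
    targets = atlas._check_clusters(target_clusters)
    off = [c for c in atlas.values.columns if c not in targets]
    if not off:
        raise ValueError(
            "relative enrichment needs at least one non-target cluster"
        )
    if pseudocount is None:
        pseudocount = default_pseudocount(atlas)
    gene = gene.strip().upper()
    if gene not in atlas.values.index:
        return float("nan")
    row = atlas.values.loc[gene]
    return float(
        (row[targets].mean() + pseudocount) / (row[off].mean() + pseudocount)
    )


def atlas_metrics(
    atlas: ExpressionAtlas,
    genes: Sequence[str],
    target_clusters: Iterable[str],
    min_level: float = 0.0,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-gene metric table: abundance, relative_enrichment, present flag.

    Genes missing from the atlas get abundance 0, enrichment 0 and
    ``in_atlas`` False, so downstream scoring stays total.
    """
    targets = atlas._check_clusters(target_clusters)
    present = genes_present(atlas, targets, min_level=min_level)
    rows = []
    for g in genes:
        gu = g.strip().upper()
        ab = abundance(atlas, gu, targets)
        en = relative_enrichment(atlas, gu, targets, pseudocount=pseudocount)
        in_atlas = not np.isnan(ab)
        rows.append(
            {
                "gene": gu,
                "abundance": 0.0 if np.isnan(ab) else ab,
                "relative_enrichment": 0.0 if np.isnan(en) else en,
                "present": gu in present,
                "in_atlas": in_atlas,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "abundance", "relative_enrichment", "present", "in_atlas"]
    )
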