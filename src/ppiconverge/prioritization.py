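"""Three-variable composite score and top-target ranking.

Each retained gene carries three raw values: connectivity (the fold
enrichment from the null model), expression (raw abundance in the target
cell type), and relative enrichment (cell-type specificity ratio). Each
is divided by the highest value in its category across the scored gene
set, so every normalized variable lies in [0, 1], and the three are
summed:

    connectivity/max + expression/max + enrichment/max  =  composite,

with a maximum composite score of 3.0 for a gene that tops all three
categories.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

RAW_COLUMNS = ["connectivity_raw", "expression_raw", "enrichment_raw"]
NORM_COLUMNS = ["connectivity_norm", "expression_norm", "enrichment_norm"]


class CompositeScorer(BaseEstimator, TransformerMixin):
    """Max-normalize the three prioritization variables and sum them.

    ``fit`` learns the per-category maxima over the scored gene set;
    ``transform`` divides each raw value by its category maximum and adds
    the ``composite`` column. A category whose maximum is 0 normalizes to
    all zeros (with a warning) rather than dividing by zero.

    Attributes
    ----------
    max_ : dict
        Raw-column name -> category maximum learned at fit time.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "CompositeScorer":
        X = self._validate(X)
        self.max_ = {c: float(X[c].max()) for c in RAW_COLUMNS}
        for c, m in self.max_.items():
            if m == 0:
                logger.warning("category maximum for %s is 0; normalized to 0", c)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X).copy()
        for raw, norm in zip(RAW_COLUMNS, NORM_COLUMNS):
            m = self.max_[raw]
            X[norm] = X[raw] / m if m > 0 else 0.0
        X["composite"] = X[NORM_COLUMNS].sum(axis=1)
        return X

    @staticmethod
    def _validate(X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a DataFrame with the three raw columns")
        if X.empty:
            raise ValueError("nothing to score: empty gene table")
        missing = [c for c in RAW_COLUMNS if c not in X.columns]
        if missing:
            raise KeyError(f"missing raw score column(s): {missing}")
        vals = X[RAW_COLUMNS].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("raw score values must be finite and non-negative")
        return X


def composite_scores(
    convergence: pd.DataFrame,
    atlas_metrics: pd.DataFrame,
    include_restored_seeds: bool = False,
) -> pd.DataFrame:
    """Score the retained convergent genes.

    ``convergence`` is the table from :func:`convergence_table`;
    ``atlas_metrics`` the per-gene abundance/enrichment table. The scored
    set is the retained genes; seeds restored only by the expansion step
    are excluded unless ``include_restored_seeds``. Genes missing atlas
    metrics score 0 in those categories and are flagged ``in_atlas``
    False.
    """
    scored = convergence[convergence["retained"]].copy()
    if not include_restored_seeds:
        passes = scored["passes_sd_filter"] & scored["passes_membership_filter"]
        scored = scored[passes]
    if scored.empty:
        raise ValueError("nothing to score: no gene survives the filters")
    metrics = atlas_metrics.set_index("gene")
    table = pd.DataFrame(
        {
            "gene": scored["gene"].to_numpy(),
            "connectivity_raw": scored["fold_enrichment"].to_numpy(dtype=float),
        }
    )
    table["expression_raw"] = [
        float(metrics["abundance"].get(g, 0.0)) for g in table["gene"]
    ]
    table["enrichment_raw"] = [
        float(metrics["relative_enrichment"].get(g, 0.0)) for g in table["gene"]
    ]
    table["in_atlas"] = [
        bool(metrics["in_atlas"].get(g, False)) if "in_atlas" in metrics else True
        for g in table["gene"]
    ]
    scorer = CompositeScorer().fit(table)
    out = scorer.transform(table)
    out = out.sort_values(["composite", "gene"], ascending=[False, True])
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def top_targets(table: pd.DataFrame, n: int = 25) -> list[str]:
    """Top ``n`` genes by composite score, ties broken alphabetically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = table.sort_values(["composite", "gene"], ascending=[False, True])
    return ranked["gene"].head(n).tolist()
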