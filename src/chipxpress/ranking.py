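"""Rank fusion: combine ChIP binding ranks with expression correlation ranks.

For TF-bound genes present in the expression compendium, the fused score is

    R_g = w * P_g + (1 - w) * A_g

where P_g is the ChIP-only rank (best peak rank order), A_g is the rank by
truncated absolute correlation a_{t,g} (rank 1 = largest a), and w in [0, 1]
weights the binding evidence. Smaller R means a better candidate functional
target. Defaults are c = 0 and w = 0.1. With w = 1 the fused order equals
the ChIP-only order; with w = 0 it equals the correlation order restricted
to bound genes — which still uses ChIP information, through the bound set
itself. Bound genes without an expression measurement cannot be scored and
are reported separately as unranked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .compendium import ExpressionCompendium
from .correlation import TruncationParams, truncated_abs_correlation_all
from .genomics import BoundGeneRanking


@dataclass(frozen=True)
class RankParams:
    c: float = 0.0
    w: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"weight w must be in [0, 1], got {self.w}")


RANKING_COLUMNS = ["gene_id", "R", "P", "A", "a", "n_used"]


@dataclass
class ChIPXpressRanking:
    """Fused ranking (sorted by R ascending) plus the unranked remainder."""

    table: pd.DataFrame  # columns RANKING_COLUMNS, sorted by R
    unranked: list[str]
    params: RankParams

    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()


def _order_by_correlation(results, p_of=None):
    """Order correlation results by a descending; invalid results last.

    Ties in a break by smaller P (when available), then gene_id. Invalid
    results are ordered among themselves by gene_id.
    """
    def key(res):
        p = p_of.get(res.gene_id, 0) if p_of else 0
        if res.valid:
            return (0, -res.a, p, res.gene_id)
        return (1, 0.0, 0, res.gene_id)

    return sorted(results, key=key)


def geo_only_rank(
    cp: ExpressionCompendium,
    tf_id: str,
    params: RankParams = RankParams(),
    min_samples: int = 3,
) -> pd.DataFrame:
    """Rank every compendium gene by truncated absolute correlation alone.

    Returns a DataFrame (gene_id, A, a, n_used, valid) sorted by A. Genes
    with an undefined correlation come after all valid genes.
    """
    tparams = TruncationParams(c=params.c, min_samples=min_samples)
    results = truncated_abs_correlation_all(cp, tf_id, cp.gene_ids, tparams)
    ordered = _order_by_correlation(results)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in ordered],
            "A": range(1, len(ordered) + 1),
            "a": [r.a for r in ordered],
            "n_used": [r.n_used for r in ordered],
            "valid": [r.valid for r in ordered],
        }
    )


def chipxpress_rank(
    bound: BoundGeneRanking,
    cp: ExpressionCompendium,
    tf_id: str,
    params: RankParams = RankParams(),
    min_samples: int = 3,
) -> ChIPXpressRanking:
    """Fuse the ChIP-only ranking with compendium correlations.

    Bound genes absent from the compendium go to ``unranked``. The remaining
    G' genes get P re-ranked to 1..G' (original order preserved, so P and A
    share one scale), A assigned by a descending, and R = w*P + (1-w)*A,
    sorted ascending with ties broken by smaller P then gene_id.
    """
    if len(bound) == 0:
        raise ValueError("empty bound-gene ranking")
    if not cp.has_gene(tf_id):
        raise KeyError(f"TF not in compendium: {tf_id}")
    w = params.w

    in_cp = [g for g in bound if cp.has_gene(g.gene_id)]
    unranked = [g.gene_id for g in bound if not cp.has_gene(g.gene_id)]
    in_cp.sort(key=lambda g: g.P)
    P = {g.gene_id: i + 1 for i, g in enumerate(in_cp)}

    tparams = TruncationParams(c=params.c, min_samples=min_samples)
    results = truncated_abs_correlation_all(
        cp, tf_id, [g.gene_id for g in in_cp], tparams
    )
    ordered = _order_by_correlation(results, p_of=P)
    A = {res.gene_id: i + 1 for i, res in enumerate(ordered)}
    by_gene = {res.gene_id: res for res in results}

    rows = []
    for g in in_cp:
        res = by_gene[g.gene_id]
        r_score = w * P[g.gene_id] + (1.0 - w) * A[g.gene_id]
        rows.append(
            {
                "gene_id": g.gene_id,
                "R": r_score,
                "P": P[g.gene_id],
                "A": A[g.gene_id],
                "a": res.a if res.valid else math.nan,
                "n_used": res.n_used,
            }
        )
    rows.sort(key=lambda row: (row["R"], row["P"], row["gene_id"]))
    table = pd.DataFrame(rows, columns=RANKING_COLUMNS)
    return ChIPXpressRanking(table=table, unranked=unranked, params=params)


def write_ranking(ranking: ChIPXpressRanking, path) -> None:
    """Write the fused ranking TSV and the sidecar ``<path>.unranked.txt``."""
    table = ranking.table.copy()
    table.insert(0, "rank", range(1, len(table) + 1))
    table.to_csv(path, sep="\t", index=False)
    with open(f"{path}.unranked.txt", "w", encoding="utf-8") as fh:
        for g in ranking.unranked:
            fh.write(g + "\n")
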