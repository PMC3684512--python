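"""Evaluation against gold-standard functional targets.

Gold-standard functional targets are genes both bound in the ChIP data and
differentially expressed under TF perturbation. A ranking is scored by its
positive predictive value PPV(k) = |top-k ∩ gold| / k, and summarized by the
normalized AUC over a horizon n:

    nAUC(n) = (1/n) * sum_{k=1..n} PPV(k)

i.e. the area under the PPV curve divided by the total plot area; 1 means
every one of the top-n genes is a gold-standard target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium
from .genomics import BoundGeneRanking
from .ranking import RankParams, chipxpress_rank, geo_only_rank


@dataclass(frozen=True)
class GoldStandard:
    gene_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


@dataclass
class PPVCurve:
    list_sizes: list[int]
    ppv: list[float]


@dataclass
class NAUCSummary:
    n: int
    nauc: float
    method: str = ""
    dataset: str = ""


def make_gold_standard(bound_genes: Iterable[str], de_genes: Iterable[str]) -> GoldStandard:
    """Intersect bound genes with differentially expressed genes."""
    gold = frozenset(bound_genes) & frozenset(de_genes)
    if not gold:
        warnings.warn("empty gold standard: bound and DE gene sets are disjoint")
    return GoldStandard(gold)


def _cum_hits(ranked_genes: Sequence[str], gold: GoldStandard) -> np.ndarray:
    hits = np.fromiter((g in gold for g in ranked_genes), dtype=float, count=len(ranked_genes))
    return np.cumsum(hits)


def ppv_curve(
    ranked_genes: Sequence[str],
    gold: GoldStandard,
    list_sizes: Sequence[int],
) -> PPVCurve:
    """PPV at each requested top-list size; sizes beyond the ranking are truncated."""
    if len(ranked_genes) == 0:
        raise ValueError("empty ranking")
    cum = _cum_hits(ranked_genes, gold)
    sizes: list[int] = []
    for k in sorted(set(int(k) for k in list_sizes)):
        if k < 1:
            raise ValueError("list size must be >= 1")
        if k > len(ranked_genes):
            warnings.warn(
                f"list size {k} exceeds ranking length {len(ranked_genes)}; truncated"
            )
            k = len(ranked_genes)
        if k not in sizes:
            sizes.append(k)
    return PPVCurve(sizes, [float(cum[k - 1] / k) for k in sizes])


def nauc(ranked_genes: Sequence[str], gold: GoldStandard, n: int, method: str = "", dataset: str = "") -> NAUCSummary:
    """Mean PPV over list sizes 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(ranked_genes) == 0:
        raise ValueError("empty ranking")
    if n > len(ranked_genes):
        raise ValueError(f"n={n} exceeds ranking length {len(ranked_genes)}")
    cum = _cum_hits(ranked_genes[:n], gold)
    value = float(np.mean(cum / np.arange(1, n + 1)))
    return NAUCSummary(n=n, nauc=value, method=method, dataset=dataset)


def compare_methods(
    bound: BoundGeneRanking,
    cp: ExpressionCompendium,
    tf_id: str,
    gold: GoldStandard,
    grid: Sequence[tuple[float, float]],
    n_values: Sequence[int],
    dataset: str = "dataset",
) -> pd.DataFrame:
    """nAUC table for ChIP-only, correlation-only and fused rankings.

    ``grid`` holds (c, w) pairs for the fused method; the correlation-only
    baseline is computed for every distinct c, both restricted to the shared
    evaluable universe (bound genes present in the compendium) and,
    unrestricted, over all compendium genes. All methods are scored against
    the same gold standard with nAUC at each n.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    universe = [g.gene_id for g in bound if cp.has_gene(g.gene_id)]
    rows: list[dict] = []

    def add(method: str, c, w, ranked: Sequence[str]) -> None:
        for n in n_values:
            horizon = min(int(n), len(ranked))
            summary = nauc(ranked, gold, horizon, method=method, dataset=dataset)
            rows.append(
                {
                    "dataset": dataset,
                    "method": method,
                    "c": c,
                    "w": w,
                    "n": int(n),
                    "nauc": summary.nauc,
                }
            )

    add("chipx_only", np.nan, np.nan, universe)

    for c in sorted(set(c for c, _ in grid)):
        fused0 = chipxpress_rank(bound, cp, tf_id, RankParams(c=c, w=0.0))
        add("geo_only", c, np.nan, fused0.gene_ids())
        unrestricted = geo_only_rank(cp, tf_id, RankParams(c=c, w=0.0))
        add("geo_only_all_genes", c, np.nan, unrestricted["gene_id"].tolist())

    for c, w in grid:
        fused = chipxpress_rank(bound, cp, tf_id, RankParams(c=c, w=w))
        add("chipxpress", c, w, fused.gene_ids())

    return pd.DataFrame(rows, columns=["dataset", "method", "c", "w", "n", "nauc"])


def read_gold_standard(path) -> GoldStandard:
    """One gene id per line."""
    with open(path, encoding="utf-8") as fh:
        genes = frozenset(line.strip() for line in fh if line.strip())
    return GoldStandard(genes)


def write_gold_standard(gold: GoldStandard, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(gold.gene_ids):
            fh.write(g + "\n")
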