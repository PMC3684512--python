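"""Truncated Pearson correlation between a TF and candidate target genes.

Gene regulation is context dependent: when a transcription factor (TF) is
not expressed, its targets may still be switched on or off by other
regulators, which dilutes the global TF-target correlation across a
heterogeneous compendium. The truncated correlation restricts the Pearson
coefficient to the samples C = {i : x_ti >= c} in which the TF's
standardized expression is at least a cutoff c; because every gene row is a
z-score, c = 0 keeps exactly the samples where the TF is above its own
average. The truncated absolute correlation a_{t,g} = |r_{t,g}| then scores
regulatory strength regardless of activation or repression. c = -inf
recovers the ordinary Pearson correlation over all samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compendium import ExpressionCompendium

WARN_NONE = "none"
WARN_MILD = "mild"  # statistic below the 25th percentile of all genes
WARN_STRONG = "strong"  # below the 5th percentile


@dataclass(frozen=True)
class TruncationParams:
    """Cutoff ``c`` (standardized expression units; -inf allowed) and the
    minimum number of retained samples for a correlation to be valid."""

    c: float = 0.0
    min_samples: int = 3

    def __post_init__(self) -> None:
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")


@dataclass
class TruncatedCorrelationResult:
    gene_id: str
    r: float
    a: float
    n_used: int
    valid: bool


@dataclass
class TFExpressionDiagnostics:
    """Pre-standardization expression statistics of the TF, positioned within
    the all-gene distribution of the same statistic.

    A TF expressed at consistently low level or with little variation across
    the compendium yields uninformative correlations; each of mean, variance
    and coefficient of variation is flagged ``strong`` below the 5th
    percentile of all genes, ``mild`` below the 25th, else ``none``.
    """

    tf_id: str
    mean: float
    variance: float
    cv: float
    quantile_position: dict[str, float] = field(default_factory=dict)
    warnings: dict[str, str] = field(default_factory=dict)


def _tf_row(cp: ExpressionCompendium, tf_id: str) -> np.ndarray:
    if not cp.has_gene(tf_id):
        raise KeyError(f"TF not in compendium: {tf_id}")
    return cp.values[cp.gene_index(tf_id)]


def truncated_abs_correlation_all(
    cp: ExpressionCompendium,
    tf_id: str,
    gene_ids,
    params: TruncationParams = TruncationParams(),
) -> list[TruncatedCorrelationResult]:
    """Truncated correlation of the TF with each requested gene.

    Results come back in input order. A gene absent from the compendium, a
    truncation set smaller than ``min_samples``, or zero variance of either
    variable within the truncation set yields an invalid result (r and a are
    NaN) rather than an error.
    """
    x = _tf_row(cp, tf_id)
    mask = x >= params.c
    n = int(mask.sum())

    gene_ids = list(gene_ids)
    present = [g for g in gene_ids if cp.has_gene(g)]
    out: dict[str, TruncatedCorrelationResult] = {}
    for g in gene_ids:
        if g not in out:
            out[g] = TruncatedCorrelationResult(g, math.nan, math.nan, 0, False)

    if present and n >= params.min_samples:
        xs = x[mask]
        x_const = np.ptp(xs) == 0.0
        idx = np.fromiter((cp.gene_index(g) for g in present), dtype=int)
        Y = cp.values[np.ix_(idx, np.flatnonzero(mask))]
        y_const = np.ptp(Y, axis=1) == 0.0
        xc = xs - xs.mean()
        Yc = Y - Y.mean(axis=1, keepdims=True)
        sxx = float(xc @ xc)
        syy = np.einsum("ij,ij->i", Yc, Yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Yc @ xc) / np.sqrt(syy * sxx)
        r = np.clip(r, -1.0, 1.0)
        ok = (~y_const) & (not x_const)
        for g, rg, good in zip(present, r, ok):
            if good:
                out[g] = TruncatedCorrelationResult(g, float(rg), float(abs(rg)), n, True)
            else:
                out[g] = TruncatedCorrelationResult(g, math.nan, math.nan, n, False)
    elif present:
        for g in present:
            out[g] = TruncatedCorrelationResult(g, math.nan, math.nan, n, False)

    return [out[g] for g in gene_ids]


def truncated_correlation(
    cp: ExpressionCompendium,
    tf_id: str,
    gene_id: str,
    params: TruncationParams = TruncationParams(),
) -> TruncatedCorrelationResult:
    """Truncated correlation between the TF and a single gene.

    Unlike the batch form, a gene id absent from the compendium is an error.
    """
    cp.gene_index(gene_id)  # raises KeyError if absent
    return truncated_abs_correlation_all(cp, tf_id, [gene_id], params)[0]


def correlation_zscore(
    cp: ExpressionCompendium,
    tf_id: str,
    gene_id: str,
    params: TruncationParams = TruncationParams(),
) -> float:
    """Standardize a gene's truncated correlation against the all-gene null.

    The null distribution is the set of truncated correlations (same cutoff)
    between the TF and every valid gene in the compendium, the TF itself
    included; z = (r - mean(null)) / sd(null). Measures how separated the
    candidate is from the bulk of the compendium.
    """
    cp.gene_index(gene_id)
    results = truncated_abs_correlation_all(cp, tf_id, cp.gene_ids, params)
    by_gene = {res.gene_id: res for res in results}
    target = by_gene[gene_id]
    if not target.valid:
        raise ValueError(f"correlation undefined for gene: {gene_id}")
    null = np.array([res.r for res in results if res.valid])
    if null.size < 10:
        raise ValueError("null distribution too small")
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise ValueError("null distribution has zero variance")
    return (target.r - float(null.mean())) / sd


def _strict_quantile_position(dist: np.ndarray, value: float) -> float:
    """Fraction of the distribution strictly below ``value``."""
    return float(np.mean(dist < value))


def tf_diagnostics(cp: ExpressionCompendium, tf_id: str) -> TFExpressionDiagnostics:
    """Warn when the TF's raw expression statistics sit in the low tail of all genes."""
    i = cp.gene_index(tf_id)
    meta = cp.gene_meta
    stats = {
        "mean": ("mu", float(meta["mu"].iloc[i])),
        "variance": ("var", float(meta["var"].iloc[i])),
        "cv": ("cv", float(meta["cv"].iloc[i])),
    }
    qpos: dict[str, float] = {}
    warns: dict[str, str] = {}
    for name, (col, value) in stats.items():
        dist = meta[col].to_numpy(dtype=float)
        q = _strict_quantile_position(dist, value)
        qpos[name] = q
        warns[name] = WARN_STRONG if q < 0.05 else WARN_MILD if q < 0.25 else WARN_NONE
    return TFExpressionDiagnostics(
        tf_id=tf_id,
        mean=stats["mean"][1],
        variance=stats["variance"][1],
        cv=stats["cv"][1],
        quantile_position=qpos,
        warnings=warns,
    )
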