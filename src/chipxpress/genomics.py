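"""Peak-to-gene assignment and the ChIP-only bound-gene ranking.

A gene is called bound when a peak falls within its TSS window: 10 kb
upstream to 5 kb downstream of the transcription start site, oriented by
strand, endpoints inclusive. Bound genes are ranked by their best
(lowest-numbered) associated peak rank, giving the ChIP-only rank P_g.

Coordinates are 0-based half-open internally (BED convention); TSS
positions are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    rank: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")
        if self.rank < 1:
            raise ValueError("peak rank must be >= 1")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnnotation:
    """One TSS record; a gene may have several (alternative TSSs)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand: {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class BoundGene:
    gene_id: str
    P: int
    best_peak_rank: int


@dataclass
class BoundGeneRanking:
    """Bound genes ordered by best peak rank; P is a permutation of 1..G."""

    genes: list[BoundGene]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[BoundGene]:
        return iter(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "P": [g.P for g in self.genes],
                "best_peak_rank": [g.best_peak_rank for g in self.genes],
            }
        )


def tss_window(ann: GeneAnnotation, upstream: int = 10_000, downstream: int = 5_000) -> tuple[int, int]:
    """Strand-oriented inclusive window [lo, hi] around the TSS."""
    if ann.strand == "+":
        lo, hi = ann.tss - upstream, ann.tss + downstream
    else:
        lo, hi = ann.tss - downstream, ann.tss + upstream
    return max(lo, 0), hi


def peaks_to_bound_genes(
    peaks: Sequence[Peak],
    annotation: Iterable[GeneAnnotation],
    upstream: int = 10_000,
    downstream: int = 5_000,
    mode: str = "center",
) -> BoundGeneRanking:
    """Assign ranked peaks to TSS windows and rank the bound genes.

    ``mode='center'`` requires the peak midpoint inside the window;
    ``mode='overlap'`` requires >= 1 bp of interval overlap. A gene bound via
    any of its TSS records takes the minimum peak rank over all of them;
    genes are then sorted by that best rank (ties by gene_id) to give P.
    """
    if mode not in ("center", "overlap"):
        raise ValueError(f"unknown mode: {mode!r}")
    annotation = list(annotation)
    if not annotation:
        raise ValueError("empty annotation")
    ranks = [p.rank for p in peaks]
    if len(set(ranks)) != len(ranks):
        raise ValueError("peak ranks must be unique")

    trees: dict[str, IntervalTree] = {}
    for ann in annotation:
        lo, hi = tss_window(ann, upstream, downstream)
        # inclusive [lo, hi] stored as half-open [lo, hi + 1)
        trees.setdefault(ann.chrom, IntervalTree()).addi(lo, hi + 1, ann.gene_id)

    best: dict[str, int] = {}
    skipped_chroms: set[str] = set()
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            skipped_chroms.add(p.chrom)
            continue
        hits = tree[p.center] if mode == "center" else tree[p.start:p.end]
        for iv in hits:
            g = iv.data
            if p.rank < best.get(g, np.iinfo(np.int64).max):
                best[g] = p.rank
    if skipped_chroms:
        warnings.warn(
            "peaks on chromosomes absent from annotation were skipped: "
            + ", ".join(sorted(skipped_chroms))
        )
    if not best:
        warnings.warn("no peak fell in any TSS window; empty bound-gene ranking")
        return BoundGeneRanking([])
    ordered = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    return BoundGeneRanking(
        [BoundGene(g, P, r) for P, (g, r) in enumerate(ordered, start=1)]
    )


def _data_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a BED-like ranked peak list.

    Ranks come from descending score when every line carries a parseable
    numeric score (column 5), with file order breaking ties; otherwise from
    file order.
    """
    path = Path(path)
    records: list[tuple[int, str, int, int, float | None]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected at least 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer coordinates") from None
        if start >= end:
            raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
        score: float | None = None
        if len(fields) >= 5:
            try:
                score = float(fields[4])
            except ValueError:
                score = None
        records.append((lineno, chrom, start, end, score))
    if not records:
        raise ValueError("no data rows")
    use_scores = all(rec[4] is not None for rec in records)
    if use_scores:
        scores = np.array([rec[4] for rec in records])
        order = np.argsort(-scores, kind="stable")
    else:
        order = np.arange(len(records))
    rank_of = {int(j): i + 1 for i, j in enumerate(order)}
    return [
        Peak(chrom, start, end, rank_of[k], score if use_scores else None)
        for k, (_, chrom, start, end, score) in enumerate(records)
    ]


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read TSS annotation from a 4-column TSV (gene_id, chrom, strand, tss)
    or BED6 gene bodies (TSS = start on '+', end - 1 on '-')."""
    path = Path(path)
    out: list[GeneAnnotation] = []
    for lineno, fields in _data_lines(path):
        if len(fields) == 4:
            if fields[0] == "gene_id":  # header
                continue
            gene_id, chrom, strand, tss_s = fields
            try:
                tss = int(tss_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer tss") from None
        elif len(fields) >= 6:
            chrom, start_s, end_s, gene_id, _, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end")
            tss = start if strand == "+" else end - 1
        else:
            raise ValueError(f"line {lineno}: expected 4 (TSV) or 6 (BED6) columns")
        if strand not in ("+", "-"):
            raise ValueError(f"line {lineno}: unknown strand {strand!r}")
        out.append(GeneAnnotation(gene_id, chrom, strand, tss))
    if not out:
        raise ValueError("no data rows")
    return out


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            name = f"peak_{p.rank}"
            if p.score is None:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\n")
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score!r}\n")


def write_annotation(annotation: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for a in annotation:
            fh.write(f"{a.gene_id}\t{a.chrom}\t{a.strand}\t{a.tss}\n")
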