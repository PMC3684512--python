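"""Standardized gene-expression compendia.

A compendium is a genes x samples matrix of per-gene z-scores built from an
already-normalized (e.g. fRMA log2) expression matrix, together with the
pre-standardization mean, variance and coefficient of variation of every
gene. Probeset-level matrices are first collapsed to one row per gene by
keeping, for each gene, the probeset with the largest sample variance.

Normalization of raw array data is upstream of this package; inputs here are
assumed consistently normalized so that samples are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("mu", "var", "cv", "zero_variance")


def _as_float_matrix(values, n_rows: int, n_cols: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n_rows, n_cols):
        raise ValueError(
            f"{what}: expected shape ({n_rows}, {n_cols}), got {arr.shape}"
        )
    return arr


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i}")
        seen.add(i)
    return ids


@dataclass
class ProbesetMatrix:
    """Normalized probeset x sample expression matrix with a probeset-to-gene map."""

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    probeset_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        self.probeset_ids = _check_unique(self.probeset_ids, "probeset_id")
        self.sample_ids = _check_unique(self.sample_ids, "sample_id")
        self.values = _as_float_matrix(
            self.values, len(self.probeset_ids), len(self.sample_ids), "ProbesetMatrix"
        )
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in probeset matrix")
        known = set(self.probeset_ids)
        for p in self.probeset_to_gene:
            if p not in known:
                raise ValueError(f"mapped probeset not in matrix: {p}")


@dataclass
class GeneMatrix:
    """Gene-level matrix of normalized (not yet standardized) expression."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dropped_probesets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene_id")
        self.sample_ids = _check_unique(self.sample_ids, "sample_id")
        self.values = _as_float_matrix(
            self.values, len(self.gene_ids), len(self.sample_ids), "GeneMatrix"
        )


@dataclass
class ExpressionCompendium:
    """Standardized compendium: per-gene z-scores plus pre-standardization stats.

    ``values[g, i]`` is the standardized expression of gene ``g`` in sample
    ``i``. ``gene_meta`` is indexed by gene_id with columns ``mu`` (raw mean),
    ``var`` (raw sample variance), ``cv`` (sqrt(var)/mu, +inf when mu == 0)
    and ``zero_variance``. Constant genes are kept as all-zero rows so the
    gene universe is stable; they are flagged and treated as uninformative
    downstream.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene_id")
        self.sample_ids = _check_unique(self.sample_ids, "sample_id")
        if len(self.sample_ids) < 2:
            raise ValueError("compendium requires at least 2 samples")
        self.values = _as_float_matrix(
            self.values, len(self.gene_ids), len(self.sample_ids), "ExpressionCompendium"
        )
        missing = [g for g in self.gene_ids if g not in self.gene_meta.index]
        if missing:
            raise ValueError(f"gene_meta missing entry for {missing[0]}")
        self.gene_meta = self.gene_meta.loc[self.gene_ids, list(META_COLUMNS)]
        self._index = {g: k for k, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._index

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene not in compendium: {gene_id}") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def validate(self) -> None:
        """Check the standardization invariant on every non-degenerate row."""
        live = ~self.gene_meta["zero_variance"].to_numpy(dtype=bool)
        if not live.any():
            return
        rows = self.values[live]
        means = rows.mean(axis=1)
        sds = rows.std(axis=1, ddof=1)
        if np.abs(means).max() >= 1e-8:
            raise ValueError("standardization violated: row mean not ~0")
        if np.abs(sds - 1.0).max() >= 1e-6:
            raise ValueError("standardization violated: row sd not ~1")


def collapse_probesets(pm: ProbesetMatrix) -> GeneMatrix:
    """Collapse a probeset matrix to one row per gene.

    For each gene the probeset with the largest sample variance of its raw
    values is retained; ties go to the lexicographically smallest probeset id.
    Probesets without a gene mapping are dropped and listed in
    ``dropped_probesets``.
    """
    if not pm.probeset_to_gene:
        raise ValueError("no probeset-to-gene mapping")
    variances = pm.values.var(axis=1, ddof=1)
    pos = {p: k for k, p in enumerate(pm.probeset_ids)}
    best: dict[str, str] = {}  # gene -> chosen probeset
    for p in sorted(pm.probeset_to_gene):  # lexicographic => deterministic ties
        g = str(pm.probeset_to_gene[p])
        cur = best.get(g)
        if cur is None or variances[pos[p]] > variances[pos[cur]]:
            best[g] = p
    dropped = [p for p in pm.probeset_ids if p not in pm.probeset_to_gene]
    gene_ids = sorted(best)
    rows = np.stack([pm.values[pos[best[g]]] for g in gene_ids])
    return GeneMatrix(gene_ids, list(pm.sample_ids), rows, dropped_probesets=dropped)


def standardize(matrix) -> ExpressionCompendium:
    """Standardize each gene row to zero mean and unit standard deviation.

    Accepts a :class:`GeneMatrix` or anything with ``gene_ids``,
    ``sample_ids`` and ``values``. Uses the sample standard deviation
    (denominator n-1). Constant rows become all zeros with
    ``zero_variance=True``; their ``cv`` is 0. ``cv`` for a zero-mean gene is
    recorded as +inf.
    """
    values = np.asarray(matrix.values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("standardize requires at least 2 samples")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in expression matrix")
    mu = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    sd = np.sqrt(var)
    zero = var == 0.0
    safe_sd = np.where(zero, 1.0, sd)
    z = (values - mu[:, None]) / safe_sd[:, None]
    z[zero] = 0.0
    with np.errstate(divide="ignore"):
        cv = np.where(mu == 0.0, np.inf, sd / np.where(mu == 0.0, 1.0, mu))
    cv = np.where(zero, 0.0, cv)
    meta = pd.DataFrame(
        {"mu": mu, "var": var, "cv": cv, "zero_variance": zero},
        index=pd.Index(list(matrix.gene_ids), name="gene_id"),
    )
    return ExpressionCompendium(
        list(matrix.gene_ids), list(matrix.sample_ids), z, meta
    )


def meta_path(path: str | Path) -> Path:
    """Sidecar metadata path: ``comp.tsv`` -> ``comp.meta.tsv``."""
    path = Path(path)
    return path.with_name(path.stem + ".meta.tsv") if path.suffix else Path(str(path) + ".meta.tsv")


def write_compendium(cp: ExpressionCompendium, path: str | Path) -> None:
    """Write the matrix as TSV (gene_id + sample header) and the sidecar meta table.

    Floats are written with full repr precision so a read round-trips values
    to better than 1e-12.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(cp.sample_ids) + "\n")
        for g, row in zip(cp.gene_ids, cp.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    meta = cp.gene_meta.copy()
    meta["zero_variance"] = meta["zero_variance"].astype(bool)
    with open(meta_path(path), "w", encoding="utf-8") as fh:
        fh.write("gene_id\tmu\tvar\tcv\tzero_variance\n")
        for g in cp.gene_ids:
            m = meta.loc[g]
            fh.write(
                f"{g}\t{float(m['mu'])!r}\t{float(m['var'])!r}\t{float(m['cv'])!r}\t"
                f"{'true' if m['zero_variance'] else 'false'}\n"
            )


def read_compendium(path: str | Path) -> ExpressionCompendium:
    """Read a compendium written by :func:`write_compendium`.

    Raises on duplicate gene ids, ragged rows (with line number) and empty
    files. If the sidecar metadata table is absent, metadata is recomputed
    from the matrix (informative only for unstandardized input).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError("no data rows")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    n = len(sample_ids)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != n + 1:
            raise ValueError(
                f"ragged row at line {lineno}: expected {n + 1} fields, got {len(fields)}"
            )
        g = fields[0]
        if g in seen:
            raise ValueError(f"duplicate gene_id: {g}")
        seen.add(g)
        try:
            rows.append(np.array([float(v) for v in fields[1:]], dtype=float))
        except ValueError as exc:
            raise ValueError(f"non-numeric value at line {lineno}: {exc}") from None
        gene_ids.append(g)
    values = np.stack(rows)
    mp = meta_path(path)
    if mp.exists():
        meta = pd.read_csv(mp, sep="\t", index_col="gene_id",
                           float_precision="round_trip")
        meta["zero_variance"] = meta["zero_variance"].map(
            {"true": True, "false": False, True: True, False: False}
        )
        meta.index = meta.index.astype(str)
    else:
        warnings.warn(f"metadata sidecar not found at {mp}; recomputing from matrix")
        mu = values.mean(axis=1)
        var = values.var(axis=1, ddof=1)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mu == 0.0, np.inf, sd / np.where(mu == 0.0, 1.0, mu))
        meta = pd.DataFrame(
            {"mu": mu, "var": var, "cv": np.where(var == 0, 0.0, cv), "zero_variance": var == 0},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    return ExpressionCompendium(gene_ids, sample_ids, values, meta)
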