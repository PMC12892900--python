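"""Core in-memory containers for the receptivity pipeline.

The pipeline moves four kinds of objects around: sparse single-cell count
matrices with per-cell metadata (:class:`CellMatrix`), named gene sets
(:class:`GeneSet`), per-gene differential-expression tables
(:class:`DETable`), and paired up/down signatures (:class:`SignaturePair`).
Each container validates its own invariants on construction so that format
errors surface at the boundary rather than deep inside a computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError

#: Menstrual-cycle / early-pregnancy stages recognized in cell metadata.
STAGES = (
    "proliferative",
    "early_secretory",
    "mid_secretory",
    "late_secretory",
    "decidua",
)

#: Required columns of a cell-metadata table.
META_COLUMNS = ("sample_id", "stage", "cluster")


def _first_duplicate(values: Iterable[str]) -> Optional[str]:
    seen = set()
    for v in values:
        if v in seen:
            return v
        seen.add(v)
    return None


class CellMatrix:
    """Sparse genes x cells integer count matrix with aligned metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Ordered, duplicate-free identifier lists matching ``counts``.
    cell_meta
        Optional table indexed by cell id with columns ``sample_id``,
        ``stage`` (one of :data:`STAGES` or empty) and ``cluster``.
        When omitted, empty metadata columns are created.
    """

    def __init__(self, counts, gene_ids, cell_ids, cell_meta: Optional[pd.DataFrame] = None):
        counts = sparse.csr_matrix(counts)
        gene_ids = np.asarray(gene_ids, dtype=object)
        cell_ids = np.asarray(cell_ids, dtype=object)
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("counts contain negative values")
        if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
            raise ValidationError("counts contain non-integral values")
        dup = _first_duplicate(gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id: {dup}")
        dup = _first_duplicate(cell_ids)
        if dup is not None:
            raise ValidationError(f"duplicate cell id: {dup}")

        if cell_meta is None:
            cell_meta = pd.DataFrame(
                {c: [""] * len(cell_ids) for c in META_COLUMNS},
                index=pd.Index(cell_ids, name="cell_id"),
            )
        else:
            cell_meta = cell_meta.copy()
            missing = [c for c in META_COLUMNS if c not in cell_meta.columns]
            for c in missing:
                cell_meta[c] = ""
            if set(cell_meta.index) != set(cell_ids) or len(cell_meta) != len(cell_ids):
                raise ValidationError("cell_meta index does not match cell_ids exactly")
            cell_meta = cell_meta.loc[list(cell_ids)]
            cell_meta.index.name = "cell_id"
            bad = set(cell_meta["stage"]) - set(STAGES) - {""}
            if bad:
                raise ValidationError(f"unknown stage values: {sorted(bad)}")

        self.counts = counts.astype(np.int64)
        self.gene_ids = gene_ids
        self.cell_ids = cell_ids
        self.cell_meta = cell_meta

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CellMatrix({self.n_genes} genes x {self.n_cells} cells, nnz={self.counts.nnz})"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (GMT line)."""

    name: str
    description: str
    genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class DETable:
    """Per-gene differential-expression records for one contrast.

    Wraps a DataFrame with columns ``gene_id``, ``log2fc``, ``p``, ``fdr``;
    one row per gene, p and fdr in [0, 1].
    """

    COLUMNS = ("gene_id", "log2fc", "p", "fdr")

    def __init__(self, df: pd.DataFrame, contrast: str):
        df = df.reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"DETable missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        dup = _first_duplicate(df["gene_id"])
        if dup is not None:
            raise ValidationError(f"duplicate gene row: {dup}")
        for col in ("p", "fdr"):
            v = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1:
                raise ValidationError(f"column {col!r} outside [0, 1] or non-finite")
        if not np.all(np.isfinite(df["log2fc"].to_numpy(dtype=float))):
            raise ValidationError("log2fc contains non-finite values")
        self.df = df
        self.contrast = contrast

    @property
    def genes(self) -> np.ndarray:
        return self.df["gene_id"].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.df)

    def significant(self, fdr_max: float) -> pd.DataFrame:
        """Rows with fdr strictly below ``fdr_max``."""
        return self.df[self.df["fdr"] < fdr_max]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DETable({self.contrast!r}, {len(self)} genes)"


@dataclass(frozen=True)
class SignaturePair:
    """Disjoint up/down gene sets with full derivation provenance."""

    name: str
    up: GeneSet
    down: GeneSet
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        shared = self.up.genes & self.down.genes
        if shared:
            raise ValidationError(
                f"signature {self.name!r}: up and down arms share genes {sorted(shared)[:5]}"
            )


@dataclass(frozen=True)
class OverlapStat:
    """Hypergeometric set-overlap statistic (upper tail, at least observed)."""

    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p: float

    def __post_init__(self):
        if self.n_overlap > min(self.n_a, self.n_b) or max(self.n_a, self.n_b) > self.n_universe:
            raise ValidationError("inconsistent overlap counts")
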