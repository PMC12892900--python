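"""Count normalization, pseudobulk aggregation and expression binning.

``lognormalize`` implements the global-scaling LogNormalize convention:
each cell's counts are divided by the cell total, multiplied by a fixed
scale factor (default 10,000) and log1p-transformed with the natural log.
``gene_mean_bins`` provides the equal-frequency expression bins used to
draw matched control genes for panel scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import CellMatrix
from .errors import ValidationError


@dataclass
class NormalizedMatrix:
    """Log-normalized expression (genes x cells), sparsity preserved."""

    values: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    scale_factor: float

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class GeneBins:
    """Equal-frequency mean-expression bin assignment, bins numbered 1..n_bins."""

    assignments: pd.Series  # gene_id -> bin index
    n_bins: int

    def members(self, bin_index: int) -> np.ndarray:
        """Gene ids in ``bin_index``, in lexicographic order."""
        genes = self.assignments.index[self.assignments.to_numpy() == bin_index]
        return np.array(sorted(genes), dtype=object)


def lognormalize(m: CellMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell depth normalization to ``scale_factor`` followed by log1p.

    entry(g, c) = ln(1 + count(g, c) / total(c) * scale_factor)

    Raises
    ------
    ValidationError
        If any cell has zero total counts (offending cell ids listed).
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        ids = [str(c) for c in m.cell_ids[zero][:10]]
        raise ValidationError(f"{int(zero.sum())} cells have zero total counts: {ids}")
    X = m.counts.tocsc().astype(float)
    scale = scale_factor / totals
    # scale each column, then log1p on stored entries only
    X = X.multiply(sparse.csr_matrix(scale))  # broadcasts over columns
    X = sparse.csr_matrix(X)
    np.log1p(X.data, out=X.data)
    return NormalizedMatrix(
        values=X,
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids,
        cell_meta=m.cell_meta,
        scale_factor=float(scale_factor),
    )


def pseudobulk(m: CellMatrix, group_key: str) -> pd.DataFrame:
    """Sum counts over cells per metadata group (genes x groups).

    Group columns are ordered lexicographically. Missing group values are an
    error reporting the number of offending cells.
    """
    if group_key not in m.cell_meta.columns:
        raise ValidationError(f"metadata column not found: {group_key}")
    groups = m.cell_meta[group_key].astype(object).to_numpy()
    missing = pd.isna(groups) | (groups == "")
    if missing.any():
        raise ValidationError(f"{int(missing.sum())} cells have missing {group_key!r} values")
    levels = sorted(set(groups))
    indicator = sparse.csr_matrix(
        (np.ones(len(groups)), (np.arange(len(groups)), [levels.index(g) for g in groups])),
        shape=(len(groups), len(levels)),
    )
    sums = np.asarray((m.counts @ indicator).todense())
    return pd.DataFrame(sums, index=pd.Index(m.gene_ids, name="gene"), columns=levels)


def gene_mean_bins(nm: NormalizedMatrix, n_bins: int = 24) -> GeneBins:
    """Cut genes into ``n_bins`` equal-frequency bins of mean expression.

    Genes are ordered by mean normalized expression with ties broken by
    gene id, then split into contiguous bins whose occupancies differ by at
    most one.
    """
    if n_bins < 1 or n_bins > nm.n_genes:
        raise ValidationError(f"n_bins={n_bins} outside 1..{nm.n_genes}")
    means = np.asarray(nm.values.mean(axis=1)).ravel()
    order = np.lexsort((nm.gene_ids.astype(str), means))
    bins = np.empty(nm.n_genes, dtype=int)
    for i, chunk in enumerate(np.array_split(np.arange(nm.n_genes), n_bins), start=1):
        bins[order[chunk]] = i
    return GeneBins(
        assignments=pd.Series(bins, index=pd.Index(nm.gene_ids, name="gene")),
        n_bins=n_bins,
    )
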