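"""Reference two-group differential expression and multiplicity control.

``wilcoxon_de`` is the single-cell reference test: a two-sided rank-sum
per gene, exact by full label enumeration when both groups have at most
8 observations and a tie/continuity-corrected normal approximation
otherwise. ``ttest_de`` is the matching cohort-level (pseudobulk) test:
Welch's t on log2(CPM + 1), whose continuous p-values remain usable at
the handful-of-donors scale where the exact rank-sum p is floored by
discreteness. Fold changes follow the single-cell convention of a
pseudocounted ratio of de-logged group means; adjustment is
Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DETable
from .errors import ValidationError
from .preprocess import NormalizedMatrix

log = logging.getLogger(__name__)

#: Largest per-group size for which the exact rank-sum enumeration is used.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class ContrastSpec:
    """A two-level comparison over a metadata column (level_a vs level_b)."""

    group_key: str
    level_a: str
    level_b: str
    min_cells: int = 3

    def __post_init__(self):
        if self.level_a == self.level_b:
            raise ValidationError("contrast levels must differ")
        if self.min_cells < 1:
            raise ValidationError("min_cells must be >= 1")


def _group_columns(meta: pd.DataFrame, spec: ContrastSpec):
    if spec.group_key not in meta.columns:
        raise ValidationError(f"metadata column not found: {spec.group_key}")
    g = meta[spec.group_key].to_numpy(dtype=object)
    a_idx = np.flatnonzero(g == spec.level_a)
    b_idx = np.flatnonzero(g == spec.level_b)
    for name, idx in ((spec.level_a, a_idx), (spec.level_b, b_idx)):
        if len(idx) < spec.min_cells:
            raise ValidationError(
                f"group {name!r} has {len(idx)} observations < min_cells={spec.min_cells}"
            )
    return a_idx, b_idx


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, aligned to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_ranksum_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact two-sided rank-sum p per gene by enumerating all label assignments.

    A, B are genes x nA and genes x nB value matrices. The two-sided p is
    the fraction of the C(nA+nB, nA) assignments whose rank-sum deviates
    from its mean by at least the observed deviation (midranks for ties).
    """
    nA, nB = A.shape[1], B.shape[1]
    n = nA + nB
    pooled = np.hstack([A, B])
    ranks = stats.rankdata(pooled, axis=1)
    w_obs = ranks[:, :nA].sum(axis=1)
    mu = nA * (n + 1) / 2.0
    combos = np.array(list(itertools.combinations(range(n), nA)))
    M = np.zeros((combos.shape[0], n))
    M[np.arange(combos.shape[0])[:, None], combos] = 1.0
    w_all = ranks @ M.T  # genes x n_assignments
    dev_obs = np.abs(w_obs - mu)[:, None]
    return (np.abs(w_all - mu) >= dev_obs - 1e-9).mean(axis=1)


def wilcoxon_de(nm: NormalizedMatrix, spec: ContrastSpec) -> DETable:
    """Two-sided rank-sum DE between the two contrast levels.

    Genes expressed in zero cells of both groups are excluded before
    testing (count logged). Fold changes come from
    :func:`log2_fold_change`; FDR from :func:`bh_adjust` over all tested
    genes.
    """
    a_idx, b_idx = _group_columns(nm.cell_meta, spec)
    A = np.asarray(nm.values[:, a_idx].todense())
    B = np.asarray(nm.values[:, b_idx].todense())
    expressed = (A.sum(axis=1) + B.sum(axis=1)) > 0
    n_dropped = int((~expressed).sum())
    if n_dropped:
        log.info("wilcoxon_de: %d genes expressed in no cell of either group excluded", n_dropped)
    if not expressed.any():
        raise ValidationError("zero tested genes after exclusion")
    A, B = A[expressed], B[expressed]
    genes = nm.gene_ids[expressed]

    if A.shape[1] <= EXACT_MAX_N and B.shape[1] <= EXACT_MAX_N:
        p = _exact_ranksum_p(A, B)
    else:
        res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue)
        # constant genes (all ties) yield nan under the approximation
        p = np.where(np.isfinite(p), p, 1.0)
    p = np.clip(p, 0.0, 1.0)

    lfc_map = log2_fold_change(nm, spec)
    lfc = np.array([lfc_map[g] for g in genes])
    fdr = bh_adjust(p)
    df = pd.DataFrame({"gene_id": genes, "log2fc": lfc, "p": p, "fdr": fdr})
    return DETable(df, contrast=f"{spec.level_a}_vs_{spec.level_b}")


def log2_fold_change(
    nm: NormalizedMatrix, spec: ContrastSpec, pseudocount: float = 1.0
) -> Dict[str, float]:
    """Pseudocounted log2 ratio of de-logged group means.

    log2((mean expm1(x) in level_a + pc) / (mean in level_b + pc)); the
    sign is positive for genes higher in ``level_a``.
    """
    a_idx, b_idx = _group_columns(nm.cell_meta, spec)
    A = np.expm1(np.asarray(nm.values[:, a_idx].todense()))
    B = np.expm1(np.asarray(nm.values[:, b_idx].todense()))
    lfc = np.log2((A.mean(axis=1) + pseudocount) / (B.mean(axis=1) + pseudocount))
    return dict(zip(nm.gene_ids.tolist(), lfc))


def ttest_de(
    counts: pd.DataFrame,
    sample_stage: pd.Series,
    spec: ContrastSpec,
    pseudocount: float = 1.0,
) -> DETable:
    """Welch's t DE on log2(CPM + 1) for a genes x samples count table.

    The cohort-arm counterpart of :func:`wilcoxon_de`: with only a few
    samples per group the exact rank-sum p cannot fall below 2/C(n, nA),
    so a continuous-p location test is required for FDR control to have
    any resolution. Fold change is the pseudocounted log2 ratio of group
    mean CPM. Genes with zero counts in all samples are excluded.
    """
    groups = sample_stage.loc[counts.columns]
    a_cols = groups.index[groups == spec.level_a]
    b_cols = groups.index[groups == spec.level_b]
    for name, cols in ((spec.level_a, a_cols), (spec.level_b, b_cols)):
        if len(cols) < spec.min_cells:
            raise ValidationError(
                f"group {name!r} has {len(cols)} samples < min_cells={spec.min_cells}"
            )
    cpm = counts / counts.sum(axis=0) * 1e6
    keep = counts.sum(axis=1) > 0
    cpm = cpm.loc[keep]
    A = np.log2(cpm[a_cols].to_numpy() + 1.0)
    B = np.log2(cpm[b_cols].to_numpy() + 1.0)
    res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    lfc = np.log2(
        (cpm[a_cols].mean(axis=1).to_numpy() + pseudocount)
        / (cpm[b_cols].mean(axis=1).to_numpy() + pseudocount)
    )
    fdr = bh_adjust(p)
    df = pd.DataFrame({"gene_id": cpm.index.to_numpy(dtype=object), "log2fc": lfc, "p": p, "fdr": fdr})
    return DETable(df, contrast=f"{spec.level_a}_vs_{spec.level_b}")
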