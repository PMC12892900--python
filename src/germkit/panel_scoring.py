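"""Per-cell gene-panel scores with expression-matched control genes.

The score of a panel in a cell is the mean normalized expression of the
panel genes minus the mean over a pool of control genes drawn from the
same mean-expression bins, so a random panel scores ~0 by construction.
This is the de-facto standard per-cell module score used for the ERA,
decidualization and senescence panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Set

import numpy as np
import pandas as pd

from .datatypes import GeneSet
from .errors import ValidationError
from .preprocess import GeneBins, NormalizedMatrix, gene_mean_bins

log = logging.getLogger(__name__)


@dataclass
class ModuleScoreResult:
    panel_name: str
    scores: pd.Series  # cell_id -> score
    n_ctrl: int
    n_bins: int
    seed: int
    panel_genes_used: Set[str]
    panel_genes_missing: Set[str]
    control_genes: Set[str] = field(default_factory=set)


def module_score(
    nm: NormalizedMatrix,
    panel: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Bin-matched control-gene panel score per cell.

    For each panel gene present in the matrix, ``n_ctrl`` control genes are
    sampled from that gene's expression bin (without replacement when the
    bin is large enough, with replacement otherwise); a gene never serves
    as its own control. The per-cell score is the mean expression of the
    used panel genes minus the mean over the pooled (unique) control genes.
    Panel genes absent from the matrix are dropped with a warning.
    """
    if n_ctrl < 1:
        raise ValidationError("n_ctrl must be >= 1")
    universe = set(nm.gene_ids.tolist())
    used = sorted(panel.genes & universe)
    missing = set(panel.genes) - universe
    if not used:
        raise ValidationError(f"no gene of panel {panel.name!r} present in the matrix")
    if missing:
        log.warning("panel %s: %d genes absent from matrix, dropped", panel.name, len(missing))

    bins = gene_mean_bins(nm, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    controls: Set[str] = set()
    for gene in used:  # sorted iteration keeps draws deterministic under seed
        b = int(bins.assignments.loc[gene])
        pool = [g for g in bins.members(b) if g != gene]
        if not pool:
            continue
        replace = len(pool) < n_ctrl
        draw = rng.choice(np.array(pool, dtype=object), size=n_ctrl, replace=replace)
        controls.update(draw.tolist())

    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    panel_rows = np.array([gene_index[g] for g in used])
    ctrl_rows = np.array([gene_index[g] for g in sorted(controls)])
    panel_mean = np.asarray(nm.values[panel_rows].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(nm.values[ctrl_rows].mean(axis=0)).ravel()
    scores = pd.Series(panel_mean - ctrl_mean, index=pd.Index(nm.cell_ids, name="cell_id"))
    return ModuleScoreResult(
        panel_name=panel.name,
        scores=scores,
        n_ctrl=n_ctrl,
        n_bins=n_bins,
        seed=seed,
        panel_genes_used=set(used),
        panel_genes_missing=missing,
        control_genes=controls,
    )


def score_summary_by_group(
    res: ModuleScoreResult, meta: pd.DataFrame, keys: Sequence[str]
) -> pd.DataFrame:
    """Mean/median/n of a score per metadata group combination."""
    keys = list(keys)
    missing = [k for k in keys if k not in meta.columns]
    if missing:
        raise ValidationError(f"metadata columns not found: {missing}")
    df = meta.loc[res.scores.index, keys].copy()
    df["score"] = res.scores
    if df.empty:
        raise ValidationError("empty group set")
    out = (
        df.groupby(keys, sort=True)["score"]
        .agg(mean="mean", median="median", n="size")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
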