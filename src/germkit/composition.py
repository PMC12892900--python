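"""Marker-rule stromal subtype classification and cell-composition tables.

Stromal subclusters are labeled from the cross-cluster z-scores of two in
vivo markers — SCARA5 (decidualization) and DIO2 (senescence) — with FOS
and CXCL14 refining the decidualized group. The z-score rule is a
reproducible surrogate for "highest expression" calls made by eye on dot
plots: a cluster is decidualized (DSC) when z(SCARA5) clears the
threshold and z(DIO2) does not, senescent in the mirrored case, and
senescent-decidualized (snDSC) when both clear it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import NormalizedMatrix


@dataclass(frozen=True)
class StromalRuleSet:
    """Marker genes and z threshold for stromal subtype calls."""

    decidual_marker: str = "SCARA5"
    senescent_marker: str = "DIO2"
    fos_marker: str = "FOS"
    cxcl14_marker: str = "CXCL14"
    z_threshold: float = 0.5
    proliferative_passthrough: bool = True
    proliferative_label: str = "proliferative"

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be positive")

    @property
    def markers(self):
        return (self.decidual_marker, self.senescent_marker, self.fos_marker, self.cxcl14_marker)


@dataclass
class CompositionTable:
    """Counts and within-stage / within-group proportions of cell groups."""

    by_stage: pd.DataFrame   # (group, stage, n_cells, proportion); props sum to 1 per stage
    by_group: pd.DataFrame   # transposed normalization: share of each group across stages


def _cluster_marker_means(
    nm: NormalizedMatrix, cluster_labels: pd.Series, markers
) -> pd.DataFrame:
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    missing = [m for m in markers if m not in gene_index]
    if missing:
        raise ValidationError(f"marker genes absent from matrix: {missing}")
    labels = cluster_labels.loc[list(nm.cell_ids)]
    clusters = sorted(set(labels))
    rows = {}
    dense = np.asarray(nm.values[[gene_index[m] for m in markers]].todense())
    for cl in clusters:
        cols = np.flatnonzero(labels.to_numpy() == cl)
        rows[cl] = dense[:, cols].mean(axis=1)
    return pd.DataFrame(rows, index=list(markers)).T  # clusters x markers


def classify_stromal_clusters(
    nm: NormalizedMatrix,
    cluster_labels: pd.Series,
    rules: StromalRuleSet = StromalRuleSet(),
) -> Dict[str, str]:
    """Assign stromal subtype labels per cluster from marker z-scores.

    Per cluster, marker means are z-scored across clusters (sample SD).
    DSC when z(SCARA5) >= tau and z(DIO2) < tau; senescent in the
    mirrored case; snDSC when both >= tau; unclassified otherwise. DSC
    clusters with z(CXCL14) >= tau become DSC_CXCL14hi; the rest split at
    the median cluster-mean FOS into DSC_FOShi / DSC_FOSlo. Senescent
    clusters split at the median cluster-mean DIO2 into senescent_DIO2hi
    / senescent_DIO2lo. Clusters whose name contains the proliferative
    label pass through unchanged.
    """
    cluster_labels = cluster_labels.astype(str)
    all_clusters = sorted(set(cluster_labels.loc[list(nm.cell_ids)]))
    passthrough = []
    if rules.proliferative_passthrough:
        passthrough = [c for c in all_clusters if rules.proliferative_label in c.lower()]
    active = [c for c in all_clusters if c not in passthrough]
    if len(active) < 2:
        raise ValidationError("need at least 2 clusters for cross-cluster z-scores")

    means = _cluster_marker_means(nm, cluster_labels, rules.markers).loc[active]
    sd = means.std(axis=0, ddof=1)
    z = (means - means.mean(axis=0)) / sd.replace(0.0, np.inf)

    tau = rules.z_threshold
    labels: Dict[str, str] = {c: c for c in passthrough}
    base: Dict[str, str] = {}
    for cl in active:
        zd = z.at[cl, rules.decidual_marker]
        zs = z.at[cl, rules.senescent_marker]
        if zd >= tau and zs >= tau:
            base[cl] = "snDSC"
        elif zd >= tau:
            base[cl] = "DSC"
        elif zs >= tau:
            base[cl] = "senescent"
        else:
            base[cl] = "unclassified"

    dsc = [c for c in active if base[c] == "DSC"]
    cxcl14hi = [c for c in dsc if z.at[c, rules.cxcl14_marker] >= tau]
    fos_split = [c for c in dsc if c not in cxcl14hi]
    fos_median = means.loc[fos_split, rules.fos_marker].median() if fos_split else np.nan
    sen = [c for c in active if base[c] == "senescent"]
    dio2_median = means.loc[sen, rules.senescent_marker].median() if sen else np.nan

    for cl in active:
        kind = base[cl]
        if kind == "DSC":
            if cl in cxcl14hi:
                labels[cl] = f"DSC_{rules.cxcl14_marker}hi"
            elif means.at[cl, rules.fos_marker] >= fos_median:
                labels[cl] = f"DSC_{rules.fos_marker}hi"
            else:
                labels[cl] = f"DSC_{rules.fos_marker}lo"
        elif kind == "senescent":
            suffix = "hi" if means.at[cl, rules.senescent_marker] >= dio2_median else "lo"
            labels[cl] = f"senescent_{rules.senescent_marker}{suffix}"
        else:
            labels[cl] = kind
    return labels


def composition_table(
    meta: pd.DataFrame, group_key: str, stage_key: str = "stage"
) -> CompositionTable:
    """Stage-wise composition of cell groups, both normalizations.

    ``by_stage`` holds proportion(group, stage) = n(group, stage) /
    n(stage); ``by_group`` holds the transposed normalization, the share
    of each group's cells falling in each stage.
    """
    for key in (group_key, stage_key):
        if key not in meta.columns:
            raise ValidationError(f"metadata column not found: {key}")
    sub = meta[[group_key, stage_key]].copy()
    if sub.empty:
        raise ValidationError("empty cell set")
    if (sub == "").any().any() or sub.isna().any().any():
        raise ValidationError("missing group/stage values among included cells")
    counts = sub.groupby([group_key, stage_key], sort=True).size().rename("n_cells").reset_index()
    stage_totals = counts.groupby(stage_key)["n_cells"].transform("sum")
    group_totals = counts.groupby(group_key)["n_cells"].transform("sum")
    by_stage = counts.assign(proportion=counts["n_cells"] / stage_totals)
    by_group = counts.assign(proportion=counts["n_cells"] / group_totals)
    return CompositionTable(by_stage=by_stage, by_group=by_group)
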