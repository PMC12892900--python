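"""Derivation of the glandular-epithelium receptivity module (GERM).

The signature is built in two stages: first the genes called significant
in BOTH the bulk and the single-cell contrast with the same fold-change
sign (concordant overlap), then a dual-threshold filter (|log2FC| above a
cutoff and FDR below a cutoff, applied to the single-cell statistics by
default) splits the survivors into up- and down-regulated arms.
Hypergeometric upper-tail overlap statistics support Euler-style set
comparisons (signature vs. reference panels, cistrome gene lists, ...).
"""

from __future__ import annotations

from typing import Iterable, Optional, Set

import numpy as np
from scipy import stats

from .datatypes import DETable, GeneSet, OverlapStat, SignaturePair
from .errors import ValidationError


def concordant_overlap(
    bulk: DETable,
    sc: DETable,
    bulk_fdr_max: float = 0.05,
    sc_fdr_max: float = 0.05,
) -> Set[str]:
    """Genes significant in both tables with the same fold-change sign.

    Genes with a log2 fold-change of exactly zero in either table are
    excluded (no direction to agree on). An empty result is permitted.
    """
    if len(bulk) == 0 or len(sc) == 0:
        raise ValidationError("both DE tables must be non-empty")
    b = bulk.df.set_index("gene_id")
    s = sc.df.set_index("gene_id")
    shared = b.index.intersection(s.index)
    b, s = b.loc[shared], s.loc[shared]
    keep = (
        (b["fdr"] < bulk_fdr_max)
        & (s["fdr"] < sc_fdr_max)
        & (b["log2fc"] != 0)
        & (s["log2fc"] != 0)
        & (np.sign(b["log2fc"]) == np.sign(s["log2fc"]))
    )
    return set(shared[keep.to_numpy()])


def derive_germ(
    bulk: DETable,
    sc: DETable,
    lfc_min: float = 2.0,
    fdr_max: float = 1e-7,
    bulk_fdr_max: float = 0.05,
    sc_fdr_max: float = 0.05,
    filter_on: str = "sc",
    name: str = "GERM",
) -> SignaturePair:
    """Derive an up/down receptivity signature from paired DE tables.

    Starts from :func:`concordant_overlap`, then retains genes with
    ``|log2fc| > lfc_min`` and ``fdr < fdr_max`` (strict inequalities) in
    the single-cell table (``filter_on="sc"``, default — the signature is
    localized to the secretory glandular epithelium) or in both tables
    (``filter_on="both"``). Up = retained genes with positive single-cell
    log2fc (higher in the contrast's first, receptive level); down =
    negative. A signature needs both arms; an empty arm is an error.
    """
    if filter_on not in ("sc", "both"):
        raise ValidationError(f"filter_on must be 'sc' or 'both', got {filter_on!r}")
    overlap = concordant_overlap(bulk, sc, bulk_fdr_max=bulk_fdr_max, sc_fdr_max=sc_fdr_max)
    s = sc.df.set_index("gene_id")
    b = bulk.df.set_index("gene_id")
    up, down = set(), set()
    for g in overlap:
        passes = abs(s.at[g, "log2fc"]) > lfc_min and s.at[g, "fdr"] < fdr_max
        if filter_on == "both":
            passes = passes and abs(b.at[g, "log2fc"]) > lfc_min and b.at[g, "fdr"] < fdr_max
        if not passes:
            continue
        (up if s.at[g, "log2fc"] > 0 else down).add(g)
    if not up or not down:
        raise ValidationError(
            f"degenerate signature: |up|={len(up)}, |down|={len(down)} "
            f"(a usable signature needs both arms)"
        )
    provenance = {
        "lfc_min": lfc_min,
        "fdr_max": fdr_max,
        "bulk_fdr_max": bulk_fdr_max,
        "sc_fdr_max": sc_fdr_max,
        "filter_on": filter_on,
        "bulk_contrast": bulk.contrast,
        "sc_contrast": sc.contrast,
        "n_concordant": len(overlap),
        "orientation": "positive log2fc = higher in the first (receptive) contrast level",
    }
    return SignaturePair(
        name=name,
        up=GeneSet(f"{name}_up", "upregulated arm", frozenset(up)),
        down=GeneSet(f"{name}_down", "downregulated arm", frozenset(down)),
        provenance=provenance,
    )


def hypergeometric_overlap(a: GeneSet, b: GeneSet, universe: Iterable[str]) -> OverlapStat:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    p = P(X >= n_overlap) with X ~ Hypergeometric(population n_universe,
    successes |a|, draws |b|).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    offenders = (a.genes | b.genes) - universe
    if offenders:
        raise ValidationError(f"genes outside universe: {sorted(offenders)[:10]}")
    n_u, n_a, n_b = len(universe), len(a), len(b)
    k = len(a.genes & b.genes)
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b))
    return OverlapStat(n_universe=n_u, n_a=n_a, n_b=n_b, n_overlap=k, p=min(p, 1.0))


def set_overlap(a: Iterable[str], b: Iterable[str], universe: Iterable[str],
                name_a: str = "A", name_b: str = "B") -> OverlapStat:
    """Convenience wrapper for plain gene-list overlaps (e.g. cistrome lists)."""
    return hypergeometric_overlap(
        GeneSet(name_a, "", frozenset(a)), GeneSet(name_b, "", frozenset(b)), universe
    )
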