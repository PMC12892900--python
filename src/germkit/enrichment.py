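"""Preranked gene-set enrichment, the signed GERM score, and Fisher meta-p.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum:
walking a ranked gene list, a set member ("hit") increments the sum by
|stat|^weight normalized by the in-set total, a non-member decrements by
1/(N - N_hit); the enrichment score (ES) is the maximum-magnitude
deviation. Significance comes from a gene-permutation null — random
same-size subsets of the ranked genes — with the (1 + b) / (1 + n)
p-value convention and NES = ES / mean |ES_perm| over same-sign
permutations. Evidence from the up- and down-regulated arms of a
signature is combined into a signed score (NES_up - NES_down) and a
Fisher sum-of-logs combined p-value over the BH-adjusted arm p-values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import List, Mapping, Tuple

import numpy as np
from scipy import stats as spstats

from .datatypes import DETable, GeneSet, SignaturePair
from .diffexpr import bh_adjust
from .errors import ValidationError

log = logging.getLogger(__name__)

#: Floor applied to p-values before logs/ranks to keep arithmetic finite.
P_FLOOR = 1e-300

#: Largest number of subsets enumerated in exhaustive permutation mode.
EXHAUSTIVE_MAX = 100_000


@dataclass
class RankedList:
    """Genes strictly ordered by a ranking statistic, best first."""

    genes: np.ndarray
    stats: np.ndarray
    tie_rule: str = "stat desc, |log2fc| desc, gene id asc"

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ValidationError("genes and stats lengths differ")
        if len(set(self.genes.tolist())) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if np.any(np.diff(self.stats) > 1e-12):
            raise ValidationError("stats are not sorted in descending order")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    n_perm: int
    leading_edge: List[str]
    seed: int
    mode: str = "sample"
    n_same_sign: int = 0


@dataclass
class GermScoreResult:
    """Signed two-arm enrichment summary: score = NES_up - NES_down."""

    up: EnrichmentResult
    down: EnrichmentResult
    score: float
    combined_p: float
    provenance: Mapping = field(default_factory=dict)


def rank_genes(de: DETable, metric: str = "signed_logp") -> RankedList:
    """Build a ranked list from a DE table.

    Metrics: ``signed_logp`` = sign(log2fc) * (-log10 max(p, 1e-300));
    ``lfc`` = log2fc. Ties are broken by |log2fc| descending, then gene id
    ascending.
    """
    if len(de) == 0:
        raise ValidationError("empty DE table")
    lfc = de.df["log2fc"].to_numpy(dtype=float)
    if metric == "signed_logp":
        p = np.maximum(de.df["p"].to_numpy(dtype=float), P_FLOOR)
        stat = np.sign(lfc) * (-np.log10(p))
    elif metric == "lfc":
        stat = lfc.copy()
    else:
        raise ValidationError(f"unknown ranking metric: {metric!r}")
    bad = ~np.isfinite(stat)
    if bad.any():
        raise ValidationError(f"non-finite ranking stats for genes: {de.genes[bad][:10].tolist()}")
    order = np.lexsort((de.genes.astype(str), -np.abs(lfc), -stat))
    return RankedList(genes=de.genes[order], stats=stat[order])


def _hit_mask(r: RankedList, s: GeneSet) -> np.ndarray:
    mask = np.isin(r.genes, list(s.genes))
    n_absent = len(s) - int(mask.sum())
    if n_absent:
        log.warning("set %s: %d genes absent from ranked list, dropped", s.name, n_absent)
    return mask


def enrichment_score(r: RankedList, s: GeneSet, weight: float = 1.0) -> Tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its full running sum.

    Returns ``(es, running_sum)``; the running sum has one entry per
    ranked gene and terminates at 0 (within floating-point error).
    """
    mask = _hit_mask(r, s)
    n = len(r)
    nh = int(mask.sum())
    if nh == 0:
        raise ValidationError(f"set {s.name!r} has empty intersection with the ranked list")
    if nh == n:
        raise ValidationError(f"set {s.name!r} covers the entire ranked list")
    w = np.abs(r.stats) ** weight
    hit_w = np.where(mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set stats are zero: fall back to unweighted hits
        hit_w = mask.astype(float)
        total = float(nh)
    inc = hit_w / total - (~mask) / (n - nh)
    running = np.cumsum(inc)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    # ties in magnitude resolve to the positive deviation (tolerance absorbs
    # float noise so the full and hit-position code paths agree)
    es = running[i_max] if running[i_max] >= -running[i_min] - 1e-12 else running[i_min]
    return float(es), running


def _es_at_positions(absw: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many hit-position sets (rows of ``positions``, sorted).

    Between hits the running sum decreases linearly, so its extrema occur
    immediately after a hit (candidates for the maximum) or immediately
    before one (candidates for the minimum, together with the zero start
    and end points).
    """
    k = positions.shape[1]
    w = absw[positions]
    cum = np.cumsum(w, axis=1)
    total = cum[:, -1:].copy()
    degenerate = total[:, 0] == 0
    if degenerate.any():
        w = np.where(degenerate[:, None], 1.0, w)
        cum = np.cumsum(w, axis=1)
        total = cum[:, -1:]
    miss = 1.0 / (n - k)
    drop = (positions - np.arange(k)) * miss  # misses accumulated before each hit
    after = cum / total - drop
    before = (cum - w) / total - drop
    mx = after.max(axis=1)
    mn = np.minimum(before.min(axis=1), 0.0)
    return np.where(mx >= -mn - 1e-12, mx, mn)


def permutation_test(
    r: RankedList,
    s: GeneSet,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "sample",
    weight: float = 1.0,
) -> EnrichmentResult:
    """Gene-permutation null for the enrichment score.

    ``sample`` mode draws ``n_perm`` random same-size subsets of the
    ranked genes; p = (1 + #{same-sign |ES_perm| >= |ES_obs|}) /
    (1 + #same-sign), NES = ES / mean |ES_perm| over same-sign
    permutations. ``exhaustive`` mode enumerates every subset (allowed
    while C(N, k) <= 10^5) and reports the exact null fraction.
    """
    es_obs, running = enrichment_score(r, s, weight=weight)
    mask = _hit_mask(r, s)
    n, k = len(r), int(mask.sum())
    absw = np.abs(r.stats) ** weight
    rng = np.random.default_rng(seed)

    if mode == "exhaustive":
        n_subsets = math.comb(n, k)
        if n_subsets > EXHAUSTIVE_MAX:
            raise ValidationError(
                f"exhaustive mode needs C({n},{k})={n_subsets} <= {EXHAUSTIVE_MAX}"
            )
        positions = np.array(list(itertools.combinations(range(n), k)))
        es_perm = _es_at_positions(absw, positions, n)
        n_eval = n_subsets
    elif mode == "sample":
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        chunks = []
        remaining = n_perm
        block = max(1, int(2e7) // n)
        while remaining > 0:
            b = min(block, remaining)
            rnd = rng.random((b, n))
            pos = np.argpartition(rnd, k, axis=1)[:, :k]
            pos.sort(axis=1)
            chunks.append(_es_at_positions(absw, pos, n))
            remaining -= b
        es_perm = np.concatenate(chunks)
        n_eval = n_perm
    else:
        raise ValidationError(f"unknown mode: {mode!r}")

    sign = 1.0 if es_obs >= 0 else -1.0
    same = es_perm > 0 if sign > 0 else es_perm < 0
    n_same = int(same.sum())
    if n_same == 0:
        log.warning("set %s: degenerate null (no same-sign permutation ES)", s.name)
        p = 1.0 / (n_eval + 1)
        denom = float(np.abs(es_perm).mean()) or 1.0
    else:
        extreme = int((same & (np.abs(es_perm) >= abs(es_obs) - 1e-15)).sum())
        if mode == "exhaustive":
            p = extreme / n_same
        else:
            p = (1 + extreme) / (1 + n_same)
        denom = float(np.abs(es_perm[same]).mean())
    nes = es_obs / denom

    if es_obs >= 0:
        edge_end = int(np.argmax(running))
        leading = [g for g, m in zip(r.genes[: edge_end + 1], mask[: edge_end + 1]) if m]
    else:
        edge_start = int(np.argmin(running))
        leading = [g for g, m in zip(r.genes[edge_start:], mask[edge_start:]) if m]
    return EnrichmentResult(
        set_name=s.name,
        es=es_obs,
        nes=float(nes),
        p=float(p),
        n_perm=n_eval,
        leading_edge=leading,
        seed=seed,
        mode=mode,
        n_same_sign=n_same,
    )


def fisher_combine(p) -> float:
    """Fisher's sum-of-logs combined p-value.

    X^2 = -2 * sum(ln p_i) referred to a chi-square distribution with 2k
    degrees of freedom. Inputs must lie in (0, 1]; callers must floor
    zero p-values first (the conventional floor is 1e-300).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError(
            "p-values must lie in (0, 1]; floor zero p-values (e.g. at 1e-300) before combining"
        )
    x2 = -2.0 * np.log(p).sum()
    return float(spstats.chi2.sf(x2, df=2 * p.size))


def germ_score(
    r: RankedList,
    sig: SignaturePair,
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
) -> GermScoreResult:
    """Signed two-arm enrichment of a signature in a ranked list.

    Both arms are tested against the gene-permutation null with seeds
    derived deterministically from ``seed``; score = NES_up - NES_down
    (positive for receptive-like profiles); combined_p = Fisher's method
    over the BH-adjusted arm p-values.
    """
    if sig.up.genes & sig.down.genes:
        raise ValidationError("signature arms overlap")
    child = np.random.SeedSequence(seed).generate_state(2)
    up_res = permutation_test(r, sig.up, n_perm=n_perm, seed=int(child[0]), weight=weight)
    down_res = permutation_test(r, sig.down, n_perm=n_perm, seed=int(child[1]), weight=weight)
    adj = bh_adjust([up_res.p, down_res.p])
    combined = fisher_combine(adj)
    return GermScoreResult(
        up=up_res,
        down=down_res,
        score=up_res.nes - down_res.nes,
        combined_p=combined,
        provenance={
            "score_formula": "nes_up - nes_down",
            "combined_p": "fisher_combine(bh_adjust([p_up, p_down]))",
            "n_perm": n_perm,
            "seed": seed,
            "arm_seeds": [int(child[0]), int(child[1])],
            "weight": weight,
        },
    )


def meta_combine(per_dataset_p) -> float:
    """Cross-dataset meta-analysis: Fisher's method over per-dataset combined p."""
    return fisher_combine(per_dataset_p)
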