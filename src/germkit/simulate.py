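"""Synthetic endometrium generator with a planted receptivity program.

The generator emulates the statistical structure the pipeline relies on,
not endometrial biology itself: overdispersed (negative-binomial) counts
over thousands of genes, several cell types including a secretory
glandular epithelium and seven stromal subtypes, secretory-stage
structure, log-normal library sizes, a planted up/down receptivity
program confined to the target epithelial type in the receptive stage,
surrogate SCARA5/DIO2/FOS/CXCL14 marker elevations in the stromal
subtypes, and a matched per-donor pseudobulk cohort.

Counts are NB with mean = libsize(cell) * pi(gene | type, stage) and
variance = m + dispersion * m^2, where pi is a per-(type, stage)
expression profile normalized to sum to one.

Planted program genes are parameterized by their target baseline
expression on the per-10k normalized scale rather than by raw weights,
for two reasons rooted in how the derivation filter behaves. First, the
fold change uses the single-cell convention of a pseudocount of one on
the per-10k scale, which shrinks ratios toward one for weakly expressed
genes: a downregulated gene can only display |log2FC| > 2 if its
baseline mean expression exceeds ~10 per-10k units, so the down arm
defaults to ~22 units (receptivity transcripts are abundant secretory
products, so high baselines are the realistic regime). Second, per-cell
depth normalization makes fold changes compositional: if the planted
program adds net transcript mass in the receptive stage, every ratio is
deflated by the mass gain. The up-arm baseline (~5 units) is chosen so
the expected mass gained by the up arm equals the mass lost by the down
arm (up_mean * (2^e - 1) = down_mean * (1 - 2^-e)), keeping normalized
fold changes centred on the planted effect.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import CellMatrix, SignaturePair
from .errors import ValidationError
from .preprocess import pseudobulk

MARKERS = ("SCARA5", "DIO2", "FOS", "CXCL14")


def _default_cell_types() -> Dict[str, float]:
    return {
        "secretory_glandular_epithelium": 0.45,
        "glandular_epithelium": 0.10,
        "endothelium": 0.05,
        "lymphocyte": 0.05,
        "proliferative_stroma": 0.05,
        "stroma_0": 0.05,
        "stroma_1": 0.05,
        "stroma_2": 0.05,
        "stroma_3": 0.05,
        "stroma_4": 0.05,
        "stroma_5": 0.05,
    }


def _default_marker_plan() -> Dict[str, Dict[str, float]]:
    # log2 elevations of each surrogate marker in stromal subclusters:
    # SCARA5-high = decidualized (stroma_1/3/5 plus the dual stroma_2),
    # DIO2-high = senescent (stroma_0 lo, stroma_4 hi, dual stroma_2),
    # FOS and CXCL14 refine the decidualized group.
    # Elevations are large because the cross-cluster z of a marker high in
    # 4 of 6 clusters is capped near 0.65 regardless of effect size; a wide
    # high/low gap shrinks the sampling jitter of cluster means so the
    # z-threshold rule separates cleanly.
    return {
        "SCARA5": {"stroma_1": 4.5, "stroma_2": 4.5, "stroma_3": 4.5, "stroma_5": 4.5},
        "DIO2": {"stroma_0": 4.2, "stroma_2": 4.4, "stroma_4": 5.2},
        "FOS": {"stroma_3": 4.0},
        "CXCL14": {"stroma_5": 4.5},
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults define the reference study conditions."""

    seed: int
    n_genes: int = 8000
    cell_types: Mapping[str, float] = field(default_factory=_default_cell_types)
    type_sigma: float = 0.5
    stages: Tuple[str, ...] = (
        "early_secretory",
        "mid_secretory",
        "late_secretory",
        "decidua",
    )
    cells_per_stage: int = 750
    n_samples_per_stage: int = 4
    n_up: int = 120
    n_down: int = 120
    effect_log2: float = 2.5
    target_type: str = "secretory_glandular_epithelium"
    target_stages: Tuple[str, ...] = ("mid_secretory",)
    planted_down_scaled_mean: float = 30.0   # baseline per-10k expression, down arm
    planted_gene_sigma: float = 0.25         # log-normal per-gene spread around the target
    marker_plan: Mapping[str, Mapping[str, float]] = field(default_factory=_default_marker_plan)
    marker_log_mean: float = 1.0
    dispersion: float = 0.3
    libsize_log_mean: float = math.log(2500.0)
    libsize_log_sigma: float = 0.35
    donor_log_sigma: float = 0.15

    def validate(self) -> None:
        problems = []
        if self.n_genes < 10:
            problems.append("n_genes must be >= 10")
        if not self.cell_types or abs(sum(self.cell_types.values()) - 1.0) > 1e-6:
            problems.append("cell_types fractions must sum to 1")
        if any(f <= 0 for f in self.cell_types.values()):
            problems.append("cell_types fractions must be positive")
        if self.cells_per_stage < 1 or self.n_samples_per_stage < 1:
            problems.append("cells_per_stage and n_samples_per_stage must be positive")
        if self.n_up < 0 or self.n_down < 0:
            problems.append("planted gene counts must be non-negative")
        if self.n_up + self.n_down + len(MARKERS) > self.n_genes:
            problems.append("planted genes exceed the gene universe")
        if not math.isfinite(self.effect_log2):
            problems.append("effect_log2 must be finite")
        if (self.n_up or self.n_down) and self.target_type not in self.cell_types:
            problems.append(f"target_type {self.target_type!r} not among cell_types")
        if (self.n_up or self.n_down) and not set(self.target_stages) <= set(self.stages):
            problems.append("target_stages must be a subset of stages")
        if self.dispersion < 0:
            problems.append("dispersion must be >= 0")
        if self.planted_down_scaled_mean <= 0 or self.planted_gene_sigma < 0:
            problems.append("planted expression parameters must be positive")
        if self.libsize_log_sigma < 0 or self.donor_log_sigma < 0:
            problems.append("log-normal sigmas must be >= 0")
        for m in self.marker_plan:
            if m not in MARKERS:
                problems.append(f"unknown marker in plan: {m}")
        if problems:
            raise ValidationError("invalid SimConfig: " + "; ".join(problems))

    def null(self) -> "SimConfig":
        """Copy of the configuration with no planted program."""
        return dataclasses.replace(self, n_up=0, n_down=0)


@dataclass
class SyntheticTruth:
    """Ledger of planted genes and effects for recovery evaluation."""

    up_genes: frozenset
    down_genes: frozenset
    effect_log2: float
    target_type: str
    target_stages: Tuple[str, ...]
    marker_plan: Mapping[str, Mapping[str, float]]
    seed: int


def _build_model(cfg: SimConfig):
    """Deterministically derive gene ids, planted indices and expression
    profiles pi(gene | type, stage) from the configuration seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = np.array(list(MARKERS) + [f"g{i:05d}" for i in range(n - len(MARKERS))],
                        dtype=object)
    base = rng.lognormal(0.0, 1.0, n)
    base[: len(MARKERS)] = rng.lognormal(cfg.marker_log_mean, 0.2, len(MARKERS))
    candidates = np.arange(len(MARKERS), n)
    planted = rng.choice(candidates, size=cfg.n_up + cfg.n_down, replace=False)
    up_idx, down_idx = planted[: cfg.n_up], planted[cfg.n_up:]

    # Per-10k baseline targets: the down arm at planted_down_scaled_mean and
    # the up arm scaled by 2^-effect, which balances the transcript mass the
    # program adds and removes in the receptive stage (see module docstring).
    down_mean = cfg.planted_down_scaled_mean
    up_mean = down_mean * 2.0 ** (-cfg.effect_log2)
    mass_fraction = (cfg.n_up * up_mean + cfg.n_down * down_mean) / 1e4
    if mass_fraction >= 0.9:
        raise ValidationError(
            f"planted program would claim {mass_fraction:.0%} of the transcriptome"
        )
    z_rest = base.sum() - base[planted].sum()
    z_total = z_rest / (1.0 - mass_fraction)
    noise = rng.lognormal(0.0, cfg.planted_gene_sigma, len(planted))
    noise /= math.exp(cfg.planted_gene_sigma ** 2 / 2.0)  # mean-one jitter
    targets = np.concatenate([np.full(cfg.n_up, up_mean), np.full(cfg.n_down, down_mean)])
    base[planted] = targets * noise * z_total / 1e4

    types = list(cfg.cell_types)
    type_mult = rng.lognormal(0.0, cfg.type_sigma, (n, len(types)))
    # planted and marker genes are ubiquitously expressed: their cross-type
    # variation is carried entirely by the planted effect / marker plan
    type_mult[planted, :] = 1.0
    type_mult[: len(MARKERS), :] = 1.0
    marker_row = {m: i for i, m in enumerate(MARKERS)}

    profiles: Dict[Tuple[str, str], np.ndarray] = {}
    for t_i, ctype in enumerate(types):
        lam_type = base * type_mult[:, t_i]
        for marker, plan in cfg.marker_plan.items():
            if ctype in plan:
                lam_type = lam_type.copy()
                lam_type[marker_row[marker]] *= 2.0 ** plan[ctype]
        for stage in cfg.stages:
            lam = lam_type
            if ctype == cfg.target_type and stage in cfg.target_stages and len(planted):
                lam = lam.copy()
                lam[up_idx] *= 2.0 ** cfg.effect_log2
                lam[down_idx] *= 2.0 ** (-cfg.effect_log2)
            profiles[(ctype, stage)] = lam / lam.sum()
    truth = SyntheticTruth(
        up_genes=frozenset(gene_ids[up_idx].tolist()),
        down_genes=frozenset(gene_ids[down_idx].tolist()),
        effect_log2=cfg.effect_log2,
        target_type=cfg.target_type,
        target_stages=tuple(cfg.target_stages),
        marker_plan={m: dict(v) for m, v in cfg.marker_plan.items()},
        seed=cfg.seed,
    )
    return gene_ids, profiles, truth, rng


def expected_profiles(cfg: SimConfig):
    """Generative mean fractions pi(gene | type, stage) and the gene ids.

    Recomputed deterministically from the seed; the expected count of
    gene g in cell c of (type, stage) is libsize(c) * pi[(type, stage)][g].
    """
    gene_ids, profiles, _, _ = _build_model(cfg)
    return gene_ids, profiles


def _allocate(total: int, fractions: Mapping[str, float]) -> Dict[str, int]:
    """Largest-remainder apportionment of ``total`` cells across types."""
    names = list(fractions)
    raw = np.array([fractions[k] * total for k in names])
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(names, counts))


def simulate_cells(cfg: SimConfig) -> Tuple[CellMatrix, SyntheticTruth]:
    """Draw a staged multi-lineage count matrix with the planted program."""
    gene_ids, profiles, truth, rng = _build_model(cfg)
    types = list(cfg.cell_types)
    per_donor = cfg.cells_per_stage // cfg.n_samples_per_stage
    leftover = cfg.cells_per_stage - per_donor * cfg.n_samples_per_stage

    cell_ids, samples, stage_col, cluster_col = [], [], [], []
    groups = []  # (type, stage, start, stop) spans over cell columns
    cursor = 0
    for stage in cfg.stages:
        for donor in range(cfg.n_samples_per_stage):
            n_cells = per_donor + (1 if donor < leftover else 0)
            alloc = _allocate(n_cells, cfg.cell_types)
            sample = f"{stage}_d{donor + 1}"
            for ctype in types:
                k = alloc[ctype]
                if k == 0:
                    continue
                for j in range(k):
                    cell_ids.append(f"c{cursor + j:06d}")
                    samples.append(sample)
                    stage_col.append(stage)
                    cluster_col.append(ctype)
                groups.append((ctype, stage, cursor, cursor + k))
                cursor += k
    n_cells_total = cursor
    libsizes = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sigma, n_cells_total)

    counts = np.zeros((cfg.n_genes, n_cells_total), dtype=np.int64)
    r = 1.0 / cfg.dispersion if cfg.dispersion > 0 else None
    for ctype, stage, start, stop in groups:
        lam = np.outer(profiles[(ctype, stage)], libsizes[start:stop])
        if r is None:
            counts[:, start:stop] = rng.poisson(lam)
        else:
            shaped = rng.gamma(r, lam / r)
            counts[:, start:stop] = rng.poisson(shaped)

    meta = pd.DataFrame(
        {"sample_id": samples, "stage": stage_col, "cluster": cluster_col},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CellMatrix(sparse.csr_matrix(counts), gene_ids, cell_ids, meta)
    return cm, truth


def simulate_cohort(
    cfg: SimConfig, cells: Optional[CellMatrix] = None
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-donor pseudobulk cohort with donor-level log-normal scaling.

    Returns a genes x samples integer count table and a sample -> stage
    series. With ``donor_log_sigma = 0`` each sample equals the exact
    pseudobulk of its cells.
    """
    cfg.validate()
    if cells is None:
        cells, _ = simulate_cells(cfg)
    pb = pseudobulk(cells, "sample_id")
    rng = np.random.default_rng([cfg.seed, 1])
    factors = rng.lognormal(0.0, cfg.donor_log_sigma, pb.shape[1])
    scaled = np.rint(pb.to_numpy() * factors).astype(np.int64)
    cohort = pd.DataFrame(scaled, index=pb.index, columns=pb.columns)
    stage_of = (
        cells.cell_meta.groupby("sample_id")["stage"].first().loc[list(pb.columns)]
    )
    stage_of.name = "stage"
    return cohort, stage_of


def truth_eval(
    sig: SignaturePair, truth: SyntheticTruth
) -> Tuple[float, float, float]:
    """(sensitivity, precision, direction_accuracy) of a derived signature.

    Sensitivity and precision are computed over up + down jointly; the
    direction accuracy is the fraction of recovered planted genes placed
    in the correct arm. An empty recovered set reports precision 0; no
    recovered planted genes reports direction accuracy 1 vacuously.
    """
    planted = set(truth.up_genes) | set(truth.down_genes)
    recovered = set(sig.up.genes) | set(sig.down.genes)
    hit = recovered & planted
    sensitivity = len(hit) / len(planted) if planted else 1.0
    precision = len(hit) / len(recovered) if recovered else 0.0
    correct = len(sig.up.genes & truth.up_genes) + len(sig.down.genes & truth.down_genes)
    direction = correct / len(hit) if hit else 1.0
    return sensitivity, precision, direction


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Planted program as a writable table (gene, arm, effect_log2)."""
    rows = [(g, "up", truth.effect_log2) for g in sorted(truth.up_genes)]
    rows += [(g, "down", -truth.effect_log2) for g in sorted(truth.down_genes)]
    return pd.DataFrame(rows, columns=["gene", "arm", "effect_log2"])
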