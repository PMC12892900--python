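"""Readers and writers for the standard formats the pipeline touches.

Supported formats
-----------------
* MatrixMarket count trios in the 10x layout (``matrix.mtx`` +
  ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``, optional
  ``cell_meta.tsv``), gzip-transparent.
* GMT gene-set files.
* TSV differential-expression tables with a configurable column map.
* Two-column ``.rnk`` ranked lists.

Gene identity throughout is the feature symbol string, case-sensitive.
"""

from __future__ import annotations

import gzip
import logging
import os
from pathlib import Path
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import CellMatrix, DETable, GeneSet, _first_duplicate
from .errors import FormatError

log = logging.getLogger(__name__)

#: Default DE-table column-name map (target -> source header).
DEFAULT_DE_COLUMNS = {"gene_id": "gene", "log2fc": "log2fc", "p": "p", "fdr": "fdr"}


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(directory: Path, names: Sequence[str]) -> Optional[Path]:
    for name in names:
        for cand in (directory / name, directory / (name + ".gz")):
            if cand.exists():
                return cand
    return None


def _read_single_column(path: Path) -> List[str]:
    with _open_maybe_gz(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        return []
    # 10x features files carry (id, symbol, type); gene identity is the symbol.
    col = 1 if len(rows[0]) >= 2 else 0
    return [r[col] for r in rows]


def read_counts_mtx(directory) -> CellMatrix:
    """Read a 10x-layout MatrixMarket trio into a :class:`CellMatrix`.

    Expects ``matrix.mtx(.gz)``, a features/genes TSV and a barcodes TSV in
    ``directory``; an optional ``cell_meta.tsv`` supplies sample, stage and
    cluster columns (absent metadata yields empty columns).
    """
    directory = Path(directory)
    mtx_path = _find(directory, ["matrix.mtx"])
    feat_path = _find(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find(directory, ["barcodes.tsv"])
    if mtx_path is None or feat_path is None or bc_path is None:
        raise FormatError(
            f"{directory}: need matrix.mtx(.gz), features.tsv/genes.tsv and barcodes.tsv"
        )
    try:
        with _open_maybe_gz(mtx_path, "rb") as fh:
            mat = spio.mmread(fh)
    except Exception as exc:
        raise FormatError(f"{mtx_path}: invalid MatrixMarket file: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path}: non-integer values in count matrix")

    gene_ids = _read_single_column(feat_path)
    cell_ids = _read_single_column(bc_path)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"{directory}: MTX header declares {mat.shape} but features/barcodes "
            f"list ({len(gene_ids)}, {len(cell_ids)}) entries"
        )
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise FormatError(f"{feat_path}: duplicate gene id: {dup}")

    meta_path = _find(directory, ["cell_meta.tsv"])
    cell_meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
        if "cell_id" not in meta.columns:
            raise FormatError(f"{meta_path}: missing column: cell_id")
        cell_meta = meta.set_index("cell_id")
    return CellMatrix(mat.astype(np.int64), gene_ids, cell_ids, cell_meta)


def write_counts_mtx(m: CellMatrix, directory) -> Path:
    """Write ``m`` as a MatrixMarket trio plus ``cell_meta.tsv``.

    Entries are emitted 1-based, column-major ("coordinate integer
    general"), matching common single-cell GEO deposits.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = m.counts.tocsc().tocoo()  # column-major entry order
    with open(directory / "matrix.mtx", "wb") as fh:
        spio.mmwrite(fh, coo, field="integer", symmetry="general")
    with open(directory / "features.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for c in m.cell_ids:
            fh.write(f"{c}\n")
    m.cell_meta.reset_index().to_csv(directory / "cell_meta.tsv", sep="\t", index=False)
    return directory


def read_gmt(file) -> List[GeneSet]:
    """Parse a GMT file (name, description, genes...) preserving set order."""
    file = Path(file)
    sets: List[GeneSet] = []
    names = set()
    with _open_maybe_gz(file) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{file}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in names:
                raise FormatError(f"{file}:{lineno}: duplicate set name: {name}")
            names.add(name)
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                log.warning("%s:%d: %d duplicate genes removed from set %s",
                            file, lineno, len(genes) - len(uniq), name)
            sets.append(GeneSet(name=name, description=desc, genes=frozenset(uniq)))
    if not sets:
        log.warning("%s: empty GMT file", file)
    return sets


def write_gmt(sets: Sequence[GeneSet], file) -> Path:
    file = Path(file)
    with open(file, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + sorted(s.genes)) + "\n")
    return file


def read_de_table(file, contrast: str, columns: Optional[Mapping[str, str]] = None) -> DETable:
    """Read a TSV differential-expression table.

    ``columns`` maps internal names (gene_id, log2fc, p, fdr) to the file's
    header names; defaults absorb the common edgeR/DESeq2/Seurat dialects via
    :data:`DEFAULT_DE_COLUMNS`. Rows with unparseable numerics are dropped
    and counted in the log.
    """
    file = Path(file)
    colmap = dict(DEFAULT_DE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(file, sep="\t")
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise FormatError(f"{file}: missing column: {missing[0]}")
    out = pd.DataFrame({tgt: df[src] for tgt, src in colmap.items()})
    for col in ("log2fc", "p", "fdr"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad = out[["log2fc", "p", "fdr"]].isna().any(axis=1)
    if bad.any():
        log.warning("%s: dropped %d rows with unparseable numerics", file, int(bad.sum()))
        out = out[~bad]
    dup = _first_duplicate(out["gene_id"])
    if dup is not None:
        raise FormatError(f"{file}: duplicate gene row: {dup}")
    return DETable(out, contrast=contrast)


def write_de_table(de: DETable, file) -> Path:
    file = Path(file)
    out = de.df.rename(columns={"gene_id": "gene"})
    out.to_csv(file, sep="\t", index=False)
    return file


def read_rnk(file) -> pd.DataFrame:
    """Read a two-column .rnk file into a (gene, stat) DataFrame."""
    file = Path(file)
    df = pd.read_csv(file, sep="\t", header=None, names=["gene", "stat"], comment="#")
    df["stat"] = pd.to_numeric(df["stat"], errors="coerce")
    if df["stat"].isna().any():
        raise FormatError(f"{file}: non-numeric stat values")
    dup = _first_duplicate(df["gene"])
    if dup is not None:
        raise FormatError(f"{file}: duplicate gene: {dup}")
    return df


def write_rnk(genes: Sequence[str], stats: Sequence[float], file) -> Path:
    file = Path(file)
    with open(file, "w") as fh:
        for g, s in zip(genes, stats):
            fh.write(f"{g}\t{s:.10g}\n")
    return file


def write_tsv(df: pd.DataFrame, file, index: bool = False) -> Path:
    """Write any tabular output deterministically as TSV."""
    file = Path(file)
    os.makedirs(file.parent, exist_ok=True)
    df.to_csv(file, sep="\t", index=index)
    return file
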