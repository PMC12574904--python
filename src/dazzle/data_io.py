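"""Reading, writing, normalizing and filtering single-cell expression data.

The in-memory container is :class:`ExpressionMatrix` — a cells x genes
nonnegative matrix with unique gene and cell identifiers. Two on-disk
formats are supported: delimited text (comma or tab, header row of gene
names, one row per cell) and MatrixMarket coordinate triplets with
plain-text gene/cell sidecar files. Ground-truth networks follow the common
benchmark convention of a two-column (regulator, target) edge list plus a
transcription-factor list, one name per line.

Quality-control filters mirror standard droplet scRNA-seq practice: cells
are kept when their number of detected genes, total UMI count and
mitochondrial read fraction all fall inside configurable bounds; genes can
be dropped when entirely zero or when their name matches a predicate (gene
models, mitochondrial or ribosomal genes). Normalization is the natural-log
transform ln(x + 1) and nothing else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GroundTruthNetwork",
    "DataError",
    "load_expression",
    "write_expression",
    "log_transform",
    "filter_cells",
    "filter_genes",
    "load_ground_truth",
    "default_mito_predicate",
]


class DataError(ValueError):
    """Raised for malformed or contract-violating input data."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers.

    Parameters
    ----------
    values
        Nonnegative float matrix, one row per cell, one column per gene.
    gene_names
        Unique gene identifiers, one per column.
    cell_ids
        Unique cell identifiers, one per row.
    is_log_transformed
        Whether values are already on the ln(x + 1) scale.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    is_log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.gene_names) != m:
            raise DataError(f"{len(self.gene_names)} gene names for {m} columns")
        if len(self.cell_ids) != n:
            raise DataError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(set(self.gene_names)) != m:
            dupes = sorted({g for g in self.gene_names if self.gene_names.count(g) > 1})
            raise DataError(f"duplicate gene names: {dupes[:5]}")
        if len(set(self.cell_ids)) != n:
            raise DataError("duplicate cell ids")
        if not np.isfinite(self.values).all():
            raise DataError("expression matrix contains non-finite values")
        if (self.values < 0).any():
            raise DataError("expression matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruthNetwork:
    """Directed reference network restricted to a gene universe."""

    edges: set[tuple[str, str]]
    tf_names: set[str]
    gene_universe: set[str]
    n_dropped_edges: int = 0

    def __post_init__(self) -> None:
        for reg, tgt in self.edges:
            if reg not in self.gene_universe or tgt not in self.gene_universe:
                raise DataError(f"edge ({reg}, {tgt}) outside gene universe")


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def load_expression(path: str | Path, fmt: str = "delimited", *,
                    gene_file: str | Path | None = None,
                    cell_file: str | Path | None = None,
                    transpose: bool = False) -> ExpressionMatrix:
    """Load an expression matrix from disk.

    ``fmt="delimited"``: header row of gene names, one row of values per
    cell (comma or tab separated, auto-detected). ``fmt="mtx"``:
    MatrixMarket coordinate file with gene and cell sidecar files (defaults:
    ``<stem>_genes.txt`` / ``<stem>_cells.txt`` next to the matrix).

    Set ``transpose=True`` for files stored genes-in-rows; orientation is
    never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if fmt == "delimited":
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise DataError(f"{path}: empty file")
        sep = _sniff_delimiter(header)
        tokens = [t.strip() for t in header.rstrip("\n").split(sep)]
        if len(set(tokens)) != len(tokens):
            raise DataError(f"{path}: duplicate gene names in header (line 1)")
        try:
            df = pd.read_csv(path, sep=sep, header=0)
        except Exception as exc:  # pandas reports the offending line
            raise DataError(f"{path}: parse error: {exc}") from exc
        if df.shape[0] == 0:
            raise DataError(f"{path}: no data rows below header")
        values = df.to_numpy(dtype=np.float64)
        gene_names = [str(c) for c in df.columns]
        cell_ids = [f"cell_{i}" for i in range(values.shape[0])]
    elif fmt == "mtx":
        gene_file = Path(gene_file) if gene_file else path.with_name(path.stem + "_genes.txt")
        cell_file = Path(cell_file) if cell_file else path.with_name(path.stem + "_cells.txt")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise DataError(f"{path}: MatrixMarket parse error: {exc}") from exc
        values = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=np.float64)
        cell_ids = [ln.strip() for ln in Path(cell_file).read_text().splitlines() if ln.strip()]
        gene_names = [ln.strip() for ln in Path(gene_file).read_text().splitlines() if ln.strip()]
    else:
        raise DataError(f"unknown format {fmt!r}; expected 'delimited' or 'mtx'")
    if transpose:
        values = values.T
        if fmt == "delimited":
            gene_names, cell_ids = cell_ids, gene_names
    return ExpressionMatrix(values, gene_names, cell_ids, is_log_transformed=False)


def write_expression(x: ExpressionMatrix, path: str | Path, fmt: str = "delimited") -> None:
    """Write a matrix in a format :func:`load_expression` reads back."""
    path = Path(path)
    if fmt == "delimited":
        pd.DataFrame(x.values, columns=x.gene_names).to_csv(path, index=False)
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(x.values))
        path.with_name(path.stem + "_genes.txt").write_text("\n".join(x.gene_names) + "\n")
        path.with_name(path.stem + "_cells.txt").write_text("\n".join(x.cell_ids) + "\n")
    else:
        raise DataError(f"unknown format {fmt!r}")


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by ln(v + 1); zeros map to zero."""
    if x.is_log_transformed:
        raise DataError("matrix is already log-transformed")
    return replace(x, values=np.log1p(x.values), is_log_transformed=True)


def default_mito_predicate(name: str) -> bool:
    """Mitochondrial genes by the conventional 'mt-' prefix (any case)."""
    return name.lower().startswith("mt-")


def filter_cells(x: ExpressionMatrix, min_genes: int = 400, max_genes: int = 3000,
                 max_umi: float = 10_000, max_mito_frac: float = 0.03,
                 mito_gene_predicate: Callable[[str], bool] = default_mito_predicate,
                 ) -> ExpressionMatrix:
    """Droplet QC: keep cells inside all three bounds (inclusive).

    A cell is kept when its number of detected genes (raw count > 0) lies in
    ``[min_genes, max_genes]``, its total UMI count is at most ``max_umi``,
    and the fraction of counts from mitochondrial genes is at most
    ``max_mito_frac``.
    """
    if x.is_log_transformed:
        raise DataError("cell QC operates on raw counts, not log-transformed data")
    detected = (x.values > 0).sum(axis=1)
    totals = x.values.sum(axis=1)
    mito_cols = np.array([mito_gene_predicate(g) for g in x.gene_names], dtype=bool)
    with np.errstate(invalid="ignore"):
        mito_frac = np.divide(x.values[:, mito_cols].sum(axis=1), totals,
                              out=np.zeros_like(totals), where=totals > 0)
    ok_genes = (detected >= min_genes) & (detected <= max_genes)
    ok_umi = totals <= max_umi
    ok_mito = mito_frac <= max_mito_frac
    keep = ok_genes & ok_umi & ok_mito
    if not keep.any():
        raise DataError(
            "all cells removed by QC "
            f"(gene-count bound removed {int((~ok_genes).sum())}, "
            f"UMI bound removed {int((~ok_umi).sum())}, "
            f"mito bound removed {int((~ok_mito).sum())})")
    return replace(x, values=x.values[keep],
                   cell_ids=[c for c, k in zip(x.cell_ids, keep) if k])


def filter_genes(x: ExpressionMatrix, drop_all_zero: bool = True,
                 drop_name_patterns: Sequence[Callable[[str], bool]] = (),
                 ) -> ExpressionMatrix:
    """Drop all-zero columns and genes matching any name predicate.

    Column order of the surviving genes is preserved.
    """
    keep = np.ones(x.n_genes, dtype=bool)
    if drop_all_zero:
        keep &= (x.values != 0).any(axis=0)
    for pred in drop_name_patterns:
        keep &= ~np.array([pred(g) for g in x.gene_names], dtype=bool)
    if not keep.any():
        raise DataError("all genes removed by filtering")
    return replace(x, values=x.values[:, keep],
                   gene_names=[g for g, k in zip(x.gene_names, keep) if k])


def load_ground_truth(edge_path: str | Path, tf_path: str | Path,
                      gene_universe: Iterable[str]) -> GroundTruthNetwork:
    """Read a two-column edge list and TF list, restricted to a gene universe.

    Gene names are matched case-insensitively (benchmark collections mix
    cases across species); edges with an endpoint outside the universe are
    dropped and counted. A regulator missing from the TF list produces a
    warning but the edge is kept — the TF list may be the looser set.
    """
    edge_path, tf_path = Path(edge_path), Path(tf_path)
    universe_map = {g.casefold(): g for g in gene_universe}
    with open(edge_path) as fh:
        first = fh.readline()
    if not first.strip():
        raise DataError(f"{edge_path}: empty edge file")
    sep = _sniff_delimiter(first)
    df = pd.read_csv(edge_path, sep=sep, header=None, dtype=str,
                     names=["regulator", "target"], usecols=[0, 1])
    tfs_raw = [ln.strip() for ln in tf_path.read_text().splitlines() if ln.strip()]
    tf_set = {t.casefold() for t in tfs_raw}

    edges: set[tuple[str, str]] = set()
    dropped = 0
    missing_tf = 0
    for reg, tgt in zip(df["regulator"], df["target"]):
        reg_key, tgt_key = str(reg).casefold(), str(tgt).casefold()
        if reg_key not in universe_map or tgt_key not in universe_map:
            dropped += 1
            continue
        if reg_key not in tf_set:
            missing_tf += 1
        edges.add((universe_map[reg_key], universe_map[tgt_key]))
    if missing_tf:
        logger.warning("%d edges have regulators absent from the TF list (kept)", missing_tf)
    logger.info("ground truth: kept %d edges, dropped %d outside universe", len(edges), dropped)
    if not edges:
        raise DataError("no ground-truth edges overlap the gene universe")
    tf_names = {universe_map[t] for t in tf_set if t in universe_map}
    # regulators observed in kept edges are TF-eligible even if unlisted
    tf_names |= {reg for reg, _ in edges}
    return GroundTruthNetwork(edges=edges, tf_names=tf_names,
                              gene_universe=set(universe_map.values()),
                              n_dropped_edges=dropped)
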