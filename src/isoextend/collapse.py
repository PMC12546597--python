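"""Collapse per-variant gene counts back to per-gene counts.

Quantification against the augmented annotation yields count-matrix
columns named after gene variants: the base gene (``G``), its merged form
(``G-iso``), and its downstream extension (``G-ext3kb`` or
``G-iso-ext3kb``). Final per-gene counts are the sum over all variant
columns sharing a base identifier.

Suffix stripping is end-anchored and restricted: only a terminal
``-ext<x>kb`` with x in 1..10 and a terminal ``-iso`` are recognised,
``-ext<x>kb`` stripped before ``-iso``, so ordinary gene symbols are never
mangled.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

_EXT_RE = re.compile(r"^(?P<rest>.+)-ext(?P<x>[1-9]|10)kb$")
_ISO_RE = re.compile(r"^(?P<rest>.+)-iso$")


@dataclass(frozen=True)
class GeneKey:
    """A matrix column identifier decomposed into base gene and variant."""

    raw: str
    base: str
    variant: str  # one of {"base", "iso", "ext"}
    ext_step: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.variant == "ext") != (self.ext_step is not None):
            raise ValueError("ext_step must be set iff variant == 'ext'")


def parse_gene_key(raw: str) -> GeneKey:
    """Decompose a column identifier into (base, variant, ext step).

    ``"G1-iso"`` -> base G1, iso; ``"G1-iso-ext10kb"`` -> base G1, ext,
    step 10; anything without a recognised terminal suffix is variant
    ``base`` with itself as base. Never fails.
    """
    if not raw:
        raise ValueError("empty gene identifier")
    m = _EXT_RE.match(raw)
    if m:
        rest = m.group("rest")
        step = int(m.group("x"))
        m2 = _ISO_RE.match(rest)
        base = m2.group("rest") if m2 else rest
        return GeneKey(raw=raw, base=base, variant="ext", ext_step=step)
    m = _ISO_RE.match(raw)
    if m:
        return GeneKey(raw=raw, base=m.group("rest"), variant="iso")
    return GeneKey(raw=raw, base=raw, variant="base")


def format_gene_key(key: GeneKey) -> str:
    """Inverse of :func:`parse_gene_key` for keys it produced."""
    if key.variant == "base":
        return key.base
    if key.variant == "iso":
        return key.base + "-iso"
    return key.raw  # ext: raw may or may not carry -iso before -ext


@dataclass
class CountMatrix:
    """Sparse cells x gene-variant count matrix.

    ``values`` is CSC with non-negative integer entries; ``column_keys``
    maps each column to its :class:`GeneKey`.
    """

    values: sp.spmatrix
    cell_ids: List[str]
    column_keys: List[GeneKey]

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        n_cells, n_cols = self.values.shape
        if n_cells != len(self.cell_ids) or n_cols != len(self.column_keys):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells / {len(self.column_keys)} columns"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def column_names(self) -> List[str]:
        return [k.raw for k in self.column_keys]

    def total(self) -> int:
        return int(self.values.sum())


def collapse_counts(m: CountMatrix) -> CountMatrix:
    """Sum variant columns per base gene.

    Output columns are the distinct base identifiers in first-appearance
    order; cell order is preserved; the total count is conserved exactly
    (pure integer addition). Idempotent: collapsing an already-collapsed
    matrix is the identity.
    """
    base_order: List[str] = []
    base_index: Dict[str, int] = {}
    col_to_base = np.empty(len(m.column_keys), dtype=np.int64)
    groups: Dict[str, List[GeneKey]] = {}
    for j, key in enumerate(m.column_keys):
        if key.base not in base_index:
            base_index[key.base] = len(base_order)
            base_order.append(key.base)
        col_to_base[j] = base_index[key.base]
        groups.setdefault(key.base, []).append(key)

    for base, keys in groups.items():
        variants = {k.variant for k in keys}
        if "base" in variants and "iso" in variants:
            log.warning(
                "columns %r and %r collapse onto the same base gene %r; "
                "their counts are summed",
                base,
                base + "-iso",
                base,
            )

    n_cols = len(m.column_keys)
    n_bases = len(base_order)
    # Column-grouping indicator matrix: out = values @ G, all-integer.
    grouping = sp.csc_matrix(
        (np.ones(n_cols, dtype=m.values.dtype), (np.arange(n_cols), col_to_base)),
        shape=(n_cols, n_bases),
    )
    collapsed = (m.values @ grouping).tocsc()
    return CountMatrix(
        values=collapsed,
        cell_ids=list(m.cell_ids),
        column_keys=[GeneKey(raw=b, base=b, variant="base") for b in base_order],
    )


# ---------------------------------------------------------------------------
# CellRanger-style triplet I/O (matrix.mtx + features/genes.tsv + barcodes.tsv)
# ---------------------------------------------------------------------------

def _find(dirpath: Path, names: Tuple[str, ...]) -> Path:
    for n in names:
        p = dirpath / n
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {dirpath}")


def read_triplet(dirpath) -> CountMatrix:
    """Read a CellRanger triplet directory into a CountMatrix.

    On disk the matrix is features x barcodes (CellRanger convention);
    internally it is transposed to cells x columns. The first column of
    the features table is the gene identifier.
    """
    dirpath = Path(dirpath)
    mtx = _find(dirpath, ("matrix.mtx", "matrix.mtx.gz"))
    features = _find(dirpath, ("features.tsv", "genes.tsv"))
    barcodes = dirpath / "barcodes.tsv"
    mat = sp.csc_matrix(scipy.io.mmread(mtx))
    feature_ids = [line.split("\t")[0].strip() for line in _read_lines(features)]
    cell_ids = _read_lines(barcodes)
    if mat.shape != (len(feature_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(feature_ids)} features "
            f"x {len(cell_ids)} barcodes"
        )
    if mat.nnz and not np.issubdtype(mat.dtype, np.integer):
        if not np.all(mat.data == np.round(mat.data)):
            raise ValueError("matrix contains non-integer counts")
        mat = mat.astype(np.int64)
    return CountMatrix(
        values=mat.T.tocsc().astype(np.int64),
        cell_ids=cell_ids,
        column_keys=[parse_gene_key(f) for f in feature_ids],
    )


def write_triplet(m: CountMatrix, dirpath) -> None:
    """Write a CountMatrix as an uncompressed CellRanger triplet."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    coo = m.values.T.tocoo().astype(np.int64)
    order = np.lexsort((coo.row, coo.col))  # canonical column-major entry order
    coo = sp.coo_matrix(
        (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
    )
    scipy.io.mmwrite(dirpath / "matrix.mtx", coo, field="integer")
    (dirpath / "features.tsv").write_text(
        "".join(f"{k.raw}\t{k.raw}\tGene Expression\n" for k in m.column_keys)
    )
    (dirpath / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))


def _read_lines(path: Path) -> List[str]:
    return [line.rstrip("\n") for line in path.read_text().splitlines()]
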