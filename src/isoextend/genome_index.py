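"""Strand-aware interval index over gene spans.

The production index keys an :class:`intervaltree.IntervalTree` per
(chromosome, strand); ``intervaltree`` shares our half-open convention, so
touching intervals do not overlap. Two exhaustive linear-scan
implementations (:func:`naive_overlaps` and :class:`NaiveScanOracle`) serve
as independent oracles in tests and in ground-truth computation — they
never consult the tree.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .model import Annotation, Gene, GenomicInterval


class IntervalIndex:
    """Overlap index over gene spans, separated by (chrom, strand)."""

    def __init__(self) -> None:
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self.n_entries = 0

    def add(self, iv: GenomicInterval, gene_id: str) -> None:
        key = (iv.chrom, iv.strand)
        if key not in self._trees:
            self._trees[key] = IntervalTree()
        self._trees[key].addi(iv.start, iv.end, gene_id)
        self.n_entries += 1

    def overlapping(self, iv: GenomicInterval) -> Set[str]:
        tree = self._trees.get((iv.chrom, iv.strand))
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(iv.start, iv.end)}


def build_index(ann: Annotation) -> IntervalIndex:
    """Index every gene span of ``ann`` (one entry per gene).

    The index is a snapshot: rebuild it after mutating the annotation.
    """
    idx = IntervalIndex()
    for gene in ann.genes.values():
        idx.add(gene.span, gene.id)
    return idx


def query_overlaps(
    idx: IntervalIndex, iv: GenomicInterval, exclude: Optional[str] = None
) -> Set[str]:
    """Ids of same-strand genes sharing >=1 bp with ``iv``, minus ``exclude``.

    Half-open semantics: ``[a, b)`` and ``[b, c)`` do not overlap.
    """
    hits = idx.overlapping(iv)
    hits.discard(exclude)
    return hits


def naive_overlaps(
    genes: Iterable[Gene], iv: GenomicInterval, exclude: Optional[str] = None
) -> Set[str]:
    """Reference implementation: plain linear scan over gene spans."""
    hits = set()
    for g in genes:
        s = g.span
        if (
            g.id != exclude
            and s.chrom == iv.chrom
            and s.strand == iv.strand
            and s.start < iv.end
            and iv.start < s.end
        ):
            hits.add(g.id)
    return hits


class NaiveScanOracle:
    """Exhaustive-scan oracle over a fixed gene set, vectorised with numpy.

    Semantically identical to :func:`naive_overlaps` — every entry on the
    query's (chrom, strand) is tested with the half-open overlap predicate;
    there is no sorting, tree or early exit. Used where the oracle is
    evaluated many thousands of times (ground-truth extension steps,
    large-scale agreement checks).
    """

    def __init__(self, genes: Iterable[Gene]) -> None:
        buckets: Dict[Tuple[str, str], List[Gene]] = {}
        for g in genes:
            buckets.setdefault((g.span.chrom, g.span.strand), []).append(g)
        self._arrays: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, List[str]]] = {}
        for key, gs in buckets.items():
            self._arrays[key] = (
                np.array([g.span.start for g in gs], dtype=np.int64),
                np.array([g.span.end for g in gs], dtype=np.int64),
                [g.id for g in gs],
            )

    def query(self, iv: GenomicInterval, exclude: Optional[str] = None) -> Set[str]:
        entry = self._arrays.get((iv.chrom, iv.strand))
        if entry is None:
            return set()
        starts, ends, ids = entry
        mask = (starts < iv.end) & (ends > iv.start)
        hits = {ids[i] for i in np.flatnonzero(mask)}
        hits.discard(exclude)
        return hits

    def any_overlap(self, iv: GenomicInterval, exclude: Optional[str] = None) -> bool:
        entry = self._arrays.get((iv.chrom, iv.strand))
        if entry is None:
            return False
        starts, ends, ids = entry
        mask = (starts < iv.end) & (ends > iv.start)
        if exclude is not None:
            for i in np.flatnonzero(mask):
                if ids[i] != exclude:
                    return True
            return False
        return bool(mask.any())
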