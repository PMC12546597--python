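"""Core data model: intervals, exons, transcripts, genes, annotations.

All coordinates are internal 0-based half-open ``[start, end)``. The GTF
layer (:mod:`isoextend.gtf_io`) converts to and from the on-disk 1-based
inclusive convention. Half-open intervals make adjacency arithmetic
unambiguous: ``[a, b)`` and ``[b, c)`` touch but do not overlap, which the
1 kb extension stepping relies on.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start : int
        0-based inclusive start (bp).
    end : int
        0-based exclusive end (bp); must be strictly greater than ``start``.
    strand : str
        ``"+"`` or ``"-"``. Unstranded features are rejected upstream
        because the whole method (downstream extension, same-strand
        association) is strand-dependent.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-aware half-open overlap: touching intervals do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        """Shared bases with ``other`` (0 if different chrom or strand)."""
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def envelope(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering both (requires same chrom and strand)."""
        if self.chrom != other.chrom or self.strand != other.strand:
            raise ValueError("cannot take envelope across chrom or strand")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end), self.strand
        )


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    transcript_id: str


@dataclass
class Transcript:
    """A transcript: an ordered, merge-normalised list of exons.

    ``source`` records provenance: ``"reference"`` for the base annotation,
    ``"novel"`` for long-read (iso-seq) transcripts merged in later.
    """

    id: str
    gene_id: str
    exons: List[Exon]
    source: str = "reference"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.interval.chrom for e in self.exons}
        strands = {e.interval.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id} mixes chromosomes or strands")
        self.exons = merge_exons(self.exons, self.id)

    @property
    def span(self) -> GenomicInterval:
        """Envelope of all exons."""
        first = self.exons[0].interval
        return GenomicInterval(
            first.chrom,
            min(e.interval.start for e in self.exons),
            max(e.interval.end for e in self.exons),
            first.strand,
        )

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    def exon_chain(self) -> tuple:
        """Hashable (start, end) chain, for exact structure comparison."""
        return tuple((e.interval.start, e.interval.end) for e in self.exons)


def merge_exons(exons: List[Exon], transcript_id: str) -> List[Exon]:
    """Sort exons by start and merge any that overlap or duplicate.

    GTFs occasionally carry duplicated or overlapping exon records; after
    normalisation the exons of one transcript are pairwise disjoint and
    sorted, so exonic-overlap arithmetic can treat them as a disjoint union.
    """
    ordered = sorted(exons, key=lambda e: (e.interval.start, e.interval.end))
    merged: List[Exon] = [ordered[0]]
    for ex in ordered[1:]:
        last = merged[-1].interval
        cur = ex.interval
        if cur.start <= last.end:  # overlap or abutting duplicate segment
            if cur.end > last.end:
                merged[-1] = Exon(
                    GenomicInterval(last.chrom, last.start, cur.end, last.strand),
                    transcript_id,
                )
        else:
            merged.append(ex)
    return merged


@dataclass
class Gene:
    """A gene: a span plus member transcripts.

    ``augmented`` flips to True once a novel transcript has been merged in
    (the gene then carries the ``-iso`` id suffix). ``parent_id`` is set
    only on downstream extension genes and points at the gene they extend.
    """

    id: str
    name: str
    biotype: str
    span: GenomicInterval
    transcripts: List[Transcript] = field(default_factory=list)
    augmented: bool = False
    parent_id: Optional[str] = None

    def transcript_envelope(self) -> Optional[GenomicInterval]:
        if not self.transcripts:
            return None
        env = self.transcripts[0].span
        for t in self.transcripts[1:]:
            env = env.envelope(t.span)
        return env

    def exonic_intervals(self) -> List[GenomicInterval]:
        """Disjoint union of exonic bases over all member transcripts."""
        ivs = sorted(
            (e.interval for t in self.transcripts for e in t.exons),
            key=lambda iv: iv.start,
        )
        if not ivs:
            return []
        out = [ivs[0]]
        for iv in ivs[1:]:
            if iv.start <= out[-1].end:
                if iv.end > out[-1].end:
                    out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, iv.strand)
            else:
                out.append(iv)
        return out


@dataclass
class Annotation:
    """A collection of genes keyed by id, with optional chromosome sizes.

    ``provenance`` is a free-text log of the operations applied, written
    into run summaries so outputs are traceable.
    """

    genes: Dict[str, Gene] = field(default_factory=dict)
    chrom_sizes: Optional[Dict[str, int]] = None
    provenance: List[str] = field(default_factory=list)

    def add_gene(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise ValueError(f"duplicate gene id {gene.id!r}")
        self.genes[gene.id] = gene

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts

    def copy(self) -> "Annotation":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        for gid, gene in self.genes.items():
            if gene.id != gid:
                raise ValueError(f"gene keyed {gid!r} carries id {gene.id!r}")
            env = gene.transcript_envelope()
            if env is not None:
                s = gene.span
                if not (s.start <= env.start and s.end >= env.end):
                    raise ValueError(f"gene {gid} span does not cover its transcripts")
            for t in gene.transcripts:
                if t.gene_id != gid:
                    raise ValueError(
                        f"transcript {t.id} references {t.gene_id!r}, member of {gid!r}"
                    )

    def __len__(self) -> int:
        return len(self.genes)
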