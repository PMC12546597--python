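"""Associate novel (iso-seq) transcripts with reference genes.

Each novel transcript is assigned to at most one reference gene on the
same strand, chosen by maximal exonic overlap (shared bases between the
transcript's exon union and the gene's exon union). This replaces a full
transcript-classification run with the single decision the merge step
needs: which same-strand gene, if any, does this transcript belong to.
Class codes are deliberately coarse:

- ``equal``: exon chain identical to some transcript of the target gene
- ``contained``: transcript span lies within the target gene span
- ``extends``: transcript span exceeds the gene span on either side
- ``novel_isoform``: overlapping, none of the above
- ``antisense``: exonic overlap only with opposite-strand genes (no target)
- ``intergenic``: no exonic overlap with any gene (no target)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional

from .genome_index import IntervalIndex, query_overlaps
from .model import Annotation, Gene, GenomicInterval, Transcript

log = logging.getLogger(__name__)


class ClassCode(str, Enum):
    EQUAL = "equal"
    CONTAINED = "contained"
    EXTENDS = "extends"
    NOVEL_ISOFORM = "novel_isoform"
    ANTISENSE = "antisense"
    INTERGENIC = "intergenic"

    #: codes that associate the transcript with a gene
    @property
    def associated(self) -> bool:
        return self in (
            ClassCode.EQUAL,
            ClassCode.CONTAINED,
            ClassCode.EXTENDS,
            ClassCode.NOVEL_ISOFORM,
        )


@dataclass
class ClassifiedTranscript:
    transcript: Transcript
    gene_id: Optional[str]
    code: ClassCode
    exonic_overlap: int

    def __post_init__(self) -> None:
        if (self.gene_id is not None) != self.code.associated:
            raise ValueError("gene_id must be set iff the class code associates")
        if self.gene_id is not None and self.exonic_overlap <= 0:
            raise ValueError("associated transcripts require exonic_overlap > 0")


def exonic_overlap(t: Transcript, g: Gene) -> int:
    """Bases shared between t's exon union and g's exonic bases.

    Returns 0 when strands (or chromosomes) differ. Both exon sets are
    merge-normalised and sorted, so a linear sweep suffices.
    """
    if t.strand != g.span.strand or t.chrom != g.span.chrom:
        return 0
    g_ivs = g.exonic_intervals()
    total = 0
    j = 0
    for ex in t.exons:
        a = ex.interval
        while j < len(g_ivs) and g_ivs[j].end <= a.start:
            j += 1
        k = j
        while k < len(g_ivs) and g_ivs[k].start < a.end:
            total += min(a.end, g_ivs[k].end) - max(a.start, g_ivs[k].start)
            k += 1
    return total


def _exonic_overlap_any_strand(t: Transcript, g: Gene) -> int:
    """Exonic overlap ignoring strand, for antisense detection."""
    total = 0
    for ex in t.exons:
        a = ex.interval
        for b in g.exonic_intervals():
            total += max(0, min(a.end, b.end) - max(a.start, b.start))
    return total


def _span_overlap(t: Transcript, g: Gene) -> int:
    return t.span.intersection_length(g.span)


def classify_transcripts(
    novel: Annotation,
    ref: Annotation,
    min_overlap_bp: int = 1,
) -> List[ClassifiedTranscript]:
    """Classify every novel transcript against the (filtered) reference.

    Parameters
    ----------
    novel, ref
        Novel and reference annotations; ``ref`` should already be
        biotype-filtered, since filtered-out genes must not attract
        transcripts.
    min_overlap_bp
        Minimum same-strand exonic overlap (bp) required to associate;
        default 1 bp.

    Returns
    -------
    list of ClassifiedTranscript, in the novel annotation's input order.

    Notes
    -----
    Candidate genes are found by span overlap on both strands; the winning
    gene is the same-strand candidate with maximal exonic overlap, ties
    broken by larger span overlap then lexicographically smallest gene id.
    Transcripts on chromosomes absent from the reference are classified
    intergenic with a logged warning.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")

    # Unstranded span index over both strands: register each gene under
    # both strand keys so antisense candidates are found too.
    idx = IntervalIndex()
    ref_chroms = set()
    for gene in ref.genes.values():
        s = gene.span
        ref_chroms.add(s.chrom)
        for strand in ("+", "-"):
            idx.add(GenomicInterval(s.chrom, s.start, s.end, strand), gene.id)

    missing_chroms = set()
    out: List[ClassifiedTranscript] = []
    for t in novel.transcripts():
        if t.chrom not in ref_chroms:
            missing_chroms.add(t.chrom)
            out.append(ClassifiedTranscript(t, None, ClassCode.INTERGENIC, 0))
            continue
        span = t.span
        candidates = query_overlaps(idx, span)
        best: Optional[Gene] = None
        best_key = None
        antisense_hit = False
        for gid in sorted(candidates):
            g = ref.genes[gid]
            if g.span.strand == t.strand:
                ov = exonic_overlap(t, g)
                if ov >= min_overlap_bp:
                    key = (-ov, -_span_overlap(t, g), gid)
                    if best_key is None or key < best_key:
                        best, best_key = g, key
            elif not antisense_hit and _exonic_overlap_any_strand(t, g) > 0:
                antisense_hit = True
        if best is not None:
            out.append(
                ClassifiedTranscript(t, best.id, _code_for(t, best), -best_key[0])
            )
        elif antisense_hit:
            out.append(ClassifiedTranscript(t, None, ClassCode.ANTISENSE, 0))
        else:
            out.append(ClassifiedTranscript(t, None, ClassCode.INTERGENIC, 0))

    for chrom in sorted(missing_chroms):
        log.warning(
            "chromosome %r present in novel annotation but absent from reference; "
            "its transcripts were classified intergenic",
            chrom,
        )
    return out


def _code_for(t: Transcript, g: Gene) -> ClassCode:
    chain = t.exon_chain()
    if any(chain == rt.exon_chain() for rt in g.transcripts):
        return ClassCode.EQUAL
    if t.span.start >= g.span.start and t.span.end <= g.span.end:
        return ClassCode.CONTAINED
    if t.span.start < g.span.start or t.span.end > g.span.end:
        return ClassCode.EXTENDS
    return ClassCode.NOVEL_ISOFORM
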