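"""Merge associated transcripts, rename genes, and add extension genes.

The augmentation pipeline, in order:

1. :func:`merge_transcripts` appends each associated novel transcript to
   its target gene, widens the gene body to the envelope of old span and
   transcript span, and suffixes the ids of genes that received at least
   one transcript with ``-iso`` (applied once, never stacked).
2. :func:`add_extension_genes` appends, downstream of each merged gene
   body (3' side: increasing coordinates on ``+``, decreasing on ``-``),
   a synthetic single-exon "extension gene" covering the largest region of
   1-10 kb, in whole 1 kb steps, that intersects no other same-strand gene
   body. Extension genes capture 3'-biased reads that pile up past
   annotated gene ends in poly(A)-primed droplet chemistry; their counts
   are later summed back into the parent (:mod:`isoextend.collapse`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .association import ClassifiedTranscript
from .genome_index import IntervalIndex, build_index, query_overlaps
from .model import Annotation, Exon, Gene, GenomicInterval, Transcript

log = logging.getLogger(__name__)

ISO_SUFFIX = "-iso"
EXTENSION_BIOTYPE = "extension"


@dataclass
class ExtensionGene:
    """A downstream extension candidate for one parent gene.

    ``region`` has length exactly ``step_kb * 1000`` bp, abuts the parent's
    strand-downstream edge, and intersects no other same-strand gene.
    """

    id: str
    name: str
    parent_id: str
    step_kb: int
    region: GenomicInterval


@dataclass
class MergeReport:
    """Bookkeeping for one augmentation run."""

    n_transcripts_added: int = 0
    n_transcripts_dropped: int = 0
    n_genes_augmented: int = 0
    n_genes_body_extended: int = 0
    n_extension_genes: int = 0
    per_gene: List[Dict] = field(default_factory=list)

    def rows(self) -> List[Dict]:
        return self.per_gene


def merge_transcripts(
    ref: Annotation, classified: List[ClassifiedTranscript]
) -> Tuple[Annotation, MergeReport]:
    """Merge associated transcripts into a copy of the reference.

    Unassociated transcripts (antisense / intergenic) are dropped and
    counted in the report. Gene ids of augmented genes gain the ``-iso``
    suffix; gene names are left unchanged.
    """
    out = ref.copy()
    report = MergeReport()
    added_per_gene: Dict[str, List[str]] = {}

    for ct in classified:
        if ct.gene_id is None:
            report.n_transcripts_dropped += 1
            continue
        gene = out.genes.get(ct.gene_id)
        if gene is None:
            raise ValueError(
                f"classified transcript {ct.transcript.id!r} references gene "
                f"{ct.gene_id!r} absent from the reference"
            )
        t = ct.transcript
        merged_t = Transcript(id=t.id, gene_id=gene.id, exons=list(t.exons), source="novel")
        gene.transcripts.append(merged_t)
        gene.span = gene.span.envelope(merged_t.span)
        gene.augmented = True
        report.n_transcripts_added += 1
        added_per_gene.setdefault(gene.id, []).append(t.id)

    # Rename augmented genes (id only, applied once), preserving dict order.
    old_spans = {gid: ref.genes[gid].span for gid in added_per_gene}
    renamed: Dict[str, Gene] = {}
    for gid, gene in out.genes.items():
        if gene.augmented and not gene.id.endswith(ISO_SUFFIX):
            new_id = gene.id + ISO_SUFFIX
            if new_id in out.genes or new_id in renamed:
                raise ValueError(f"renaming {gid!r} collides with existing {new_id!r}")
            gene.id = new_id
            for t in gene.transcripts:
                t.gene_id = new_id
        renamed[gene.id] = gene
    out.genes = renamed

    report.n_genes_augmented = len(added_per_gene)
    for gid, tids in added_per_gene.items():
        gene = out.genes[gid + ISO_SUFFIX]
        extended = gene.span != old_spans[gid]
        if extended:
            report.n_genes_body_extended += 1
        report.per_gene.append(
            {
                "gene_id": gene.id,
                "original_id": gid,
                "transcripts_added": ",".join(tids),
                "new_span": f"{gene.span.chrom}:{gene.span.start}-{gene.span.end}",
                "body_extended": extended,
            }
        )
    out.provenance.append(
        f"merge_transcripts(added={report.n_transcripts_added}, "
        f"dropped={report.n_transcripts_dropped}, genes={report.n_genes_augmented})"
    )
    out.validate()
    return out, report


def downstream_region(span: GenomicInterval, length: int) -> Optional[GenomicInterval]:
    """The ``length``-bp region abutting the 3' edge of ``span``.

    Returns None when the region would run off the chromosome start
    (negative coordinates on the minus strand).
    """
    if span.strand == "+":
        return GenomicInterval(span.chrom, span.end, span.end + length, "+")
    if span.start - length < 0:
        return None
    return GenomicInterval(span.chrom, span.start - length, span.start, "-")


def extension_name(parent: str, step_kb: int) -> str:
    return f"{parent}-ext{step_kb}kb"


def compute_extension(
    gene_id: str,
    ann: Annotation,
    idx: IntervalIndex,
    max_kb: int = 10,
    step_kb: int = 1,
) -> Optional[ExtensionGene]:
    """Largest valid downstream extension for one gene, or None.

    Candidate regions are ``x * 1000`` bp for ``x = step_kb, 2*step_kb, ...
    <= max_kb``, abutting the parent's downstream edge. A candidate is
    valid when it (a) overlaps no same-strand gene other than the parent
    (half-open semantics, so abutting the next gene exactly is allowed)
    and (b) stays within ``[0, chromosome length)`` — the upper bound only
    when ``ann.chrom_sizes`` knows the chromosome. Only whole steps are
    emitted: a 2,999 bp gap yields x = 2, never a partial region.
    """
    gene = ann.genes.get(gene_id)
    if gene is None:
        raise KeyError(f"unknown gene id {gene_id!r}")
    if gene.parent_id is not None:
        raise ValueError(f"{gene_id!r} is itself an extension gene")
    if max_kb < 1 or step_kb < 1:
        raise ValueError("max_kb and step_kb must be >= 1")

    chrom_len = (ann.chrom_sizes or {}).get(gene.span.chrom)
    top = (max_kb // step_kb) * step_kb  # largest whole step within max_kb
    for x in range(top, 0, -step_kb):
        region = downstream_region(gene.span, x * 1000)
        if region is None:
            continue
        if chrom_len is not None and region.end > chrom_len:
            continue
        if query_overlaps(idx, region, exclude=gene.id):
            continue
        return ExtensionGene(
            id=extension_name(gene.id, x),
            name=extension_name(gene.name, x),
            parent_id=gene.id,
            step_kb=x,
            region=region,
        )
    return None


def add_extension_genes(
    ann: Annotation,
    chrom_sizes: Optional[Dict[str, int]] = None,
    max_kb: int = 10,
    step_kb: int = 1,
    strict_extension_obstacles: bool = False,
) -> Tuple[Annotation, MergeReport]:
    """Add one extension gene per gene of the post-merge annotation.

    Extensions are evaluated against post-merge gene BODIES only; by
    default previously added extension genes are not obstacles to one
    another (set ``strict_extension_obstacles`` for the stricter reading,
    where extensions are placed in (chrom, start) gene order and each
    placed extension blocks later ones). Each resulting extension gene is
    materialised with one single-exon transcript covering its region and
    biotype ``"extension"``; original genes are not modified.
    """
    out = ann.copy()
    if chrom_sizes is not None:
        out.chrom_sizes = dict(chrom_sizes)
    if out.chrom_sizes is None:
        log.warning(
            "no chromosome sizes provided; extension regions are not checked "
            "against chromosome ends"
        )
    idx = build_index(out)

    report = MergeReport()
    parents = [
        g for g in out.genes.values() if g.parent_id is None and g.biotype != EXTENSION_BIOTYPE
    ]
    parents.sort(key=lambda g: (g.span.chrom, g.span.start, g.id))
    new_genes: List[Gene] = []
    for gene in parents:
        ext = compute_extension(gene.id, out, idx, max_kb=max_kb, step_kb=step_kb)
        if ext is None:
            report.per_gene.append(
                {"gene_id": gene.id, "extension_step_kb": 0, "extension_id": ""}
            )
            continue
        tid = ext.id + "-t1"
        gene_obj = Gene(
            id=ext.id,
            name=ext.name,
            biotype=EXTENSION_BIOTYPE,
            span=ext.region,
            transcripts=[Transcript(tid, ext.id, [Exon(ext.region, tid)], source="novel")],
            parent_id=ext.parent_id,
        )
        new_genes.append(gene_obj)
        if strict_extension_obstacles:
            idx.add(ext.region, ext.id)
        report.n_extension_genes += 1
        report.per_gene.append(
            {"gene_id": gene.id, "extension_step_kb": ext.step_kb, "extension_id": ext.id}
        )
    for g in new_genes:
        out.add_gene(g)
    out.provenance.append(
        f"add_extension_genes(n={report.n_extension_genes}, max_kb={max_kb}, "
        f"step_kb={step_kb}, strict={strict_extension_obstacles})"
    )
    out.validate()
    return out, report


def augment_annotation(
    ref: Annotation,
    classified: List[ClassifiedTranscript],
    chrom_sizes: Optional[Dict[str, int]] = None,
    max_kb: int = 10,
    step_kb: int = 1,
    strict_extension_obstacles: bool = False,
) -> Tuple[Annotation, MergeReport]:
    """Full augmentation: merge, rename, then add extension genes."""
    merged, merge_report = merge_transcripts(ref, classified)
    extended, ext_report = add_extension_genes(
        merged,
        chrom_sizes=chrom_sizes,
        max_kb=max_kb,
        step_kb=step_kb,
        strict_extension_obstacles=strict_extension_obstacles,
    )
    report = MergeReport(
        n_transcripts_added=merge_report.n_transcripts_added,
        n_transcripts_dropped=merge_report.n_transcripts_dropped,
        n_genes_augmented=merge_report.n_genes_augmented,
        n_genes_body_extended=merge_report.n_genes_body_extended,
        n_extension_genes=ext_report.n_extension_genes,
        per_gene=merge_report.per_gene + ext_report.per_gene,
    )
    return extended, report
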