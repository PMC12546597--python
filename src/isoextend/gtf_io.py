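"""GTF reading and writing, plus biotype filtering.

On disk GTF is 1-based inclusive; internally everything is 0-based
half-open, so a GTF feature ``start..end`` becomes ``[start-1, end)``.
The parser accepts the Ensembl attribute dialect (``key "value";``) and,
leniently, unquoted values. Gene lines are optional: long-read GTFs often
carry only transcripts and exons, in which case genes are synthesised from
transcript envelopes.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .model import Annotation, Exon, Gene, GenomicInterval, Transcript

log = logging.getLogger(__name__)

#: Biotypes removed from the reference before merging, per the method's
#: filtering rule.
DEFAULT_EXCLUDED_BIOTYPES = frozenset({"pseudogene", "processed_pseudogene"})

_ATTR_RE = re.compile(r'(\w+)\s+(?:"([^"]*)"|([^;\s]+))\s*;?')


class GtfParseError(ValueError):
    """Malformed GTF content; message names the offending line."""


def _parse_attributes(field: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for m in _ATTR_RE.finditer(field):
        key = m.group(1)
        if key not in attrs:  # first occurrence wins (exon_number etc. repeat)
            attrs[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return attrs


def read_gtf(path, source_label: str = "reference") -> Annotation:
    """Read a GTF file into an :class:`~isoextend.model.Annotation`.

    Parameters
    ----------
    path : path-like
        GTF file (1-based inclusive coordinates; attributes must include
        ``gene_id`` on gene lines and ``gene_id``/``transcript_id`` on
        transcript and exon lines).
    source_label : {"reference", "novel"}
        Provenance stamped onto every transcript.

    Notes
    -----
    Genes and transcripts with strand ``.`` are rejected: downstream
    extension and same-strand association are meaningless without strand.
    Duplicated exon lines are de-duplicated with a warning; a gene id
    appearing on more than one chromosome is a hard error.
    """
    if source_label not in ("reference", "novel"):
        raise ValueError(f"source_label must be 'reference' or 'novel', got {source_label!r}")
    path = Path(path)

    gene_rows: Dict[str, Tuple[GenomicInterval, str, str]] = {}  # id -> (span, name, biotype)
    tx_rows: Dict[str, Tuple[str, Optional[GenomicInterval]]] = {}  # id -> (gene_id, span)
    tx_order: List[str] = []
    exon_rows: Dict[str, List[GenomicInterval]] = {}
    tx_attr_names: Dict[str, Tuple[str, str]] = {}  # gene_id -> (gene_name, biotype) fallback
    seen_exons: Set[Tuple[str, int, int]] = set()
    n_dup_exons = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = cols
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from None
            start, end = start1 - 1, end1  # to 0-based half-open
            if start < 0 or start >= end:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid coordinates {start1}..{end1}"
                )
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path}:{lineno}: unstranded {feature} records are not supported"
                )
            attrs = _parse_attributes(attr_field)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start, end, strand)

            if feature == "gene":
                if gene_id in gene_rows:
                    prev = gene_rows[gene_id][0]
                    if prev.chrom != chrom:
                        raise GtfParseError(
                            f"{path}:{lineno}: gene {gene_id!r} appears on both "
                            f"{prev.chrom!r} and {chrom!r}"
                        )
                gene_rows[gene_id] = (
                    iv,
                    attrs.get("gene_name", gene_id),
                    attrs.get("gene_biotype", ""),
                )
            else:
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise GtfParseError(f"{path}:{lineno}: missing transcript_id attribute")
                if gene_id not in tx_attr_names:
                    tx_attr_names[gene_id] = (
                        attrs.get("gene_name", gene_id),
                        attrs.get("gene_biotype", ""),
                    )
                if feature == "transcript":
                    tx_rows[tid] = (gene_id, iv)
                    if tid not in exon_rows:
                        exon_rows[tid] = []
                        tx_order.append(tid)
                else:  # exon
                    key = (tid, start, end)
                    if key in seen_exons:
                        n_dup_exons += 1
                        continue
                    seen_exons.add(key)
                    if tid not in tx_rows and tid not in exon_rows:
                        tx_rows[tid] = (gene_id, None)
                    if tid not in exon_rows:
                        exon_rows[tid] = []
                        tx_order.append(tid)
                    exon_rows[tid].append(iv)

    if n_dup_exons:
        log.warning("%s: de-duplicated %d repeated exon lines", path, n_dup_exons)

    ann = Annotation(chrom_sizes=None, provenance=[f"read_gtf({path.name}, {source_label})"])

    # Build transcripts in file order, grouped under their genes.
    genes: Dict[str, Gene] = {}
    for tid in tx_order:
        gene_id, tspan = tx_rows[tid]
        exons = exon_rows.get(tid, [])
        if not exons:
            if tspan is None:
                raise GtfParseError(f"{path}: transcript {tid!r} has no exons")
            exons = [tspan]  # exonless transcript line: treat span as one exon
        transcript = Transcript(
            id=tid,
            gene_id=gene_id,
            exons=[Exon(iv, tid) for iv in exons],
            source=source_label,
        )
        if gene_id not in genes:
            if gene_id in gene_rows:
                span, name, biotype = gene_rows[gene_id]
            else:
                name, biotype = tx_attr_names.get(gene_id, (gene_id, ""))
                span = transcript.span
            genes[gene_id] = Gene(gene_id, name, biotype, span)
        gene = genes[gene_id]
        if transcript.strand != gene.span.strand or transcript.chrom != gene.span.chrom:
            raise GtfParseError(
                f"{path}: transcript {tid!r} disagrees with gene {gene_id!r} "
                "on chromosome or strand"
            )
        gene.transcripts.append(transcript)
        gene.span = gene.span.envelope(transcript.span)

    # Gene lines with no transcripts still count (rare but legal).
    for gid, (span, name, biotype) in gene_rows.items():
        if gid not in genes:
            genes[gid] = Gene(gid, name, biotype, span)

    for gene in genes.values():
        ann.add_gene(gene)
    ann.validate()
    return ann


def write_gtf(ann: Annotation, path) -> None:
    """Write an Annotation as GTF (1-based inclusive), deterministically.

    Genes are emitted sorted by (chrom, start, id); within a gene the gene
    line precedes its transcripts (sorted by start, id), each followed by
    its exons in coordinate order. Two calls on the same annotation produce
    byte-identical files.
    """
    lines: List[str] = []
    for gene in sorted(ann.genes.values(), key=lambda g: (g.span.chrom, g.span.start, g.id)):
        g_attrs = (
            f'gene_id "{gene.id}"; gene_name "{gene.name}"; '
            f'gene_biotype "{gene.biotype}";'
        )
        lines.append(_gtf_line(gene.span, "gene", g_attrs))
        for t in sorted(gene.transcripts, key=lambda t: (t.span.start, t.id)):
            t_attrs = g_attrs + f' transcript_id "{t.id}";'
            lines.append(_gtf_line(t.span, "transcript", t_attrs))
            for i, exon in enumerate(t.exons, start=1):
                e_attrs = t_attrs + f' exon_number "{i}";'
                lines.append(_gtf_line(exon.interval, "exon", e_attrs))
    Path(path).write_text("".join(lines))


def _gtf_line(iv: GenomicInterval, feature: str, attrs: str) -> str:
    return (
        f"{iv.chrom}\tisoextend\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
        f"{iv.strand}\t.\t{attrs}\n"
    )


def filter_biotypes(ann: Annotation, excluded: Optional[Iterable[str]] = None) -> Annotation:
    """Return a copy of ``ann`` with genes of the excluded biotypes removed.

    The default excluded set is exactly ``{"pseudogene",
    "processed_pseudogene"}``; surviving genes are untouched (deep copies).
    """
    excluded_set = DEFAULT_EXCLUDED_BIOTYPES if excluded is None else set(excluded)
    out = ann.copy()
    removed = [gid for gid, g in out.genes.items() if g.biotype in excluded_set]
    for gid in removed:
        del out.genes[gid]
    out.provenance.append(
        f"filter_biotypes(excluded={sorted(excluded_set)}, removed={len(removed)})"
    )
    return out


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a headerless two-column TSV of (chromosome, length in bp)."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sizes[parts[0]] = int(parts[1])
    return sizes
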