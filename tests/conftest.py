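"""Shared builders for hand-constructed annotations."""

from typing import List, Optional, Tuple

import pytest

from isoextend.model import Annotation, Exon, Gene, GenomicInterval, Transcript


def make_gene(
    gid: str,
    start: int,
    end: int,
    strand: str = "+",
    chrom: str = "chr1",
    biotype: str = "protein_coding",
    exons: Optional[List[Tuple[int, int]]] = None,
    name: Optional[str] = None,
    source: str = "reference",
) -> Gene:
    """One gene with a single transcript; exons default to the full span."""
    exons = exons or [(start, end)]
    tid = f"{gid}.T1"
    t = Transcript(
        tid,
        gid,
        [Exon(GenomicInterval(chrom, s, e, strand), tid) for s, e in exons],
        source=source,
    )
    return Gene(gid, name or gid, biotype, GenomicInterval(chrom, start, end, strand), [t])


def make_annotation(*genes: Gene, chrom_sizes=None) -> Annotation:
    ann = Annotation(chrom_sizes=chrom_sizes)
    for g in genes:
        ann.add_gene(g)
    return ann


@pytest.fixture
def tandem_plus_layout() -> Annotation:
    """Three tandem + strand genes: A [0,2000), B [2500,4000), C [20000,21000)."""
    return make_annotation(
        make_gene("A", 0, 2000),
        make_gene("B", 2500, 4000),
        make_gene("C", 20000, 21000),
    )
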