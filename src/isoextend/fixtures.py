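"""Deterministic synthetic annotations and count matrices with ground truth.

The generator emulates the inputs of the augmentation pipeline: a
reference annotation (genes placed left-to-right with sampled inter-gene
gaps, mixed strands, a fraction of pseudogenes) and a novel long-read
annotation (transcripts that copy a reference transcript's exons and run
past its 3' end, plus antisense and intergenic decoys). Every stage's
expected outcome is recorded in a :class:`GroundTruth` computed by
exhaustive naive checks, independent of the production interval index.

Gap sampling deliberately covers the regimes the 1 kb stepping is
sensitive to: a configurable fraction of gaps are placed exactly at
``k * 1000`` or ``k * 1000 +/- 1`` bp (k = 1..10), where half-open
adjacency decides whether step k fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .augment import ISO_SUFFIX, extension_name
from .collapse import CountMatrix, GeneKey, parse_gene_key
from .genome_index import NaiveScanOracle
from .model import Annotation, Exon, Gene, GenomicInterval, Transcript

CHROM = "chr1"


@dataclass
class SimulationParams:
    """Knobs for :func:`simulate_annotation`.

    Defaults give ~500 genes over a 10 Mb chromosome with gaps spanning
    well under 1 kb to well over 10 kb, half the genes on the minus
    strand, and roughly a third of retained genes receiving a novel
    3'-extended transcript.
    """

    n_genes: int = 500
    chrom_length: int = 10_000_000
    gap_distribution: Tuple[int, int] = (100, 15_000)
    boundary_gap_prob: float = 0.2  # gap drawn at exactly k*1000 or k*1000 +/- 1
    minus_strand_prob: float = 0.5
    novel_transcript_prob: float = 0.35
    novel_3prime_extension: Tuple[int, int] = (200, 3_000)
    pseudogene_prob: float = 0.1
    antisense_decoy_prob: float = 0.05
    intergenic_decoy_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.boundary_gap_prob,
            self.minus_strand_prob,
            self.novel_transcript_prob,
            self.pseudogene_prob,
            self.antisense_decoy_prob,
            self.intergenic_decoy_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.gap_distribution, self.novel_3prime_extension):
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) has min > max")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class GroundTruth:
    """Expected outcomes for a simulated instance.

    ``extension_steps`` maps each retained (non-pseudogene) gene's
    ORIGINAL id to the expected downstream extension step in kb (0 when
    even 1 kb does not fit), computed by exhaustively testing x = 10..1
    against the expected post-merge gene bodies with a naive linear scan.
    """

    novel_parent: Dict[str, Optional[str]] = field(default_factory=dict)
    decoy_class: Dict[str, str] = field(default_factory=dict)
    iso_flags: Dict[str, bool] = field(default_factory=dict)
    merged_spans: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    extension_steps: Dict[str, int] = field(default_factory=dict)
    expected_extension_ids: Dict[str, Optional[str]] = field(default_factory=dict)
    collapsed_totals: Optional[pd.DataFrame] = None


def simulate_annotation(
    p: SimulationParams,
) -> Tuple[Annotation, Annotation, GroundTruth]:
    """Generate a (reference, novel, ground-truth) triple.

    Genes are non-overlapping and strictly ordered along the chromosome;
    novel transcripts share their parent's full exon chain and extend the
    3'-terminal exon by a sampled amount, clipped so they never intrude
    into the next same-strand gene body. Identical parameters (including
    the seed) reproduce byte-identical output.
    """
    rng = np.random.default_rng(p.seed)
    ref = Annotation(chrom_sizes={CHROM: p.chrom_length})
    novel = Annotation(chrom_sizes={CHROM: p.chrom_length})
    truth = GroundTruth()

    cursor = int(rng.integers(0, 5_000))
    genes: List[Gene] = []
    gaps_after: List[int] = []
    for i in range(p.n_genes):
        strand = "-" if rng.random() < p.minus_strand_prob else "+"
        n_exons = int(rng.integers(1, 4))
        exon_lens = rng.integers(200, 801, size=n_exons)
        intron_lens = rng.integers(100, 1001, size=max(0, n_exons - 1))
        gid, tid = f"GENE{i:05d}", f"GENE{i:05d}.T1"
        pos = cursor
        exon_ivs = []
        for j in range(n_exons):
            exon_ivs.append(GenomicInterval(CHROM, pos, pos + int(exon_lens[j]), strand))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        if pos > p.chrom_length:
            raise ValueError(
                f"generated genes exceed chrom_length={p.chrom_length}; "
                "reduce n_genes or gaps"
            )
        if rng.random() < p.pseudogene_prob:
            biotype = "pseudogene" if rng.random() < 0.5 else "processed_pseudogene"
        else:
            biotype = "protein_coding"
        t = Transcript(tid, gid, [Exon(iv, tid) for iv in exon_ivs], source="reference")
        genes.append(Gene(gid, gid, biotype, t.span, [t]))
        if rng.random() < p.boundary_gap_prob:
            gap = int(rng.integers(1, 11)) * 1000 + int(rng.integers(-1, 2))
        else:
            gap = int(rng.integers(p.gap_distribution[0], p.gap_distribution[1] + 1))
        gaps_after.append(gap)
        cursor = pos + gap
    for g in genes:
        ref.add_gene(g)

    retained = [g for g in genes if g.biotype == "protein_coding"]
    retained_ids = {g.id for g in retained}

    # Novel transcripts: copy the parent's exon chain, extend the 3' end.
    merged_spans: Dict[str, Tuple[int, int]] = {
        g.id: (g.span.start, g.span.end) for g in retained
    }
    novel_count = 0
    for gi, g in enumerate(genes):
        if g.biotype != "protein_coding" or rng.random() >= p.novel_transcript_prob:
            continue
        delta = int(rng.integers(p.novel_3prime_extension[0], p.novel_3prime_extension[1] + 1))
        strand = g.span.strand
        # 3' limit: never intrude into the next same-strand gene body.
        if strand == "+":
            limit = p.chrom_length
            for other in genes[gi + 1 :]:
                if other.span.strand == strand:
                    limit = other.span.start
                    break
            new_end = min(g.span.end + delta, limit)
            new_start = g.span.start
        else:
            limit = 0
            for other in reversed(genes[:gi]):
                if other.span.strand == strand:
                    limit = other.span.end
                    break
            new_start = max(g.span.start - delta, limit)
            new_end = g.span.end
        tid = f"NOVEL{novel_count:05d}"
        novel_count += 1
        exon_ivs = [e.interval for e in g.transcripts[0].exons]
        if strand == "+":
            last = exon_ivs[-1]
            exon_ivs[-1] = GenomicInterval(CHROM, last.start, new_end, strand)
        else:
            first = exon_ivs[0]
            exon_ivs[0] = GenomicInterval(CHROM, new_start, first.end, strand)
        t = Transcript(tid, f"NOVG_{tid}", [Exon(iv, tid) for iv in exon_ivs], source="novel")
        novel.add_gene(Gene(f"NOVG_{tid}", f"NOVG_{tid}", "", t.span, [t]))
        truth.novel_parent[tid] = g.id
        merged_spans[g.id] = (
            min(merged_spans[g.id][0], new_start),
            max(merged_spans[g.id][1], new_end),
        )

    # Antisense decoys: one exon of a gene, on the opposite strand.
    decoy_count = 0
    for g in genes:
        if rng.random() >= p.antisense_decoy_prob:
            continue
        if g.id not in retained_ids:
            continue
        src = g.transcripts[0].exons[0].interval
        flipped = "-" if src.strand == "+" else "+"
        # skip if a same-('flipped')-strand gene overlaps this exon: the
        # decoy would then legitimately associate with that gene
        if any(
            o.span.strand == flipped
            and o.span.start < src.end
            and src.start < o.span.end
            for o in genes
        ):
            continue
        tid = f"DECOY_AS{decoy_count:05d}"
        decoy_count += 1
        iv = GenomicInterval(CHROM, src.start, src.end, flipped)
        t = Transcript(tid, f"NOVG_{tid}", [Exon(iv, tid)], source="novel")
        novel.add_gene(Gene(f"NOVG_{tid}", f"NOVG_{tid}", "", t.span, [t]))
        truth.decoy_class[tid] = "antisense"

    # Intergenic decoys: short single-exon transcripts inside wide gaps.
    for gi, g in enumerate(genes[:-1]):
        if rng.random() >= p.intergenic_decoy_prob:
            continue
        gap_start = g.span.end
        gap_end = genes[gi + 1].span.start
        if gap_end - gap_start < 300:
            continue
        start = gap_start + 100
        end = min(start + 150, gap_end - 50)
        tid = f"DECOY_IG{gi:05d}"
        strand = "-" if rng.random() < 0.5 else "+"
        iv = GenomicInterval(CHROM, start, end, strand)
        t = Transcript(tid, f"NOVG_{tid}", [Exon(iv, tid)], source="novel")
        novel.add_gene(Gene(f"NOVG_{tid}", f"NOVG_{tid}", "", t.span, [t]))
        truth.decoy_class[tid] = "intergenic"

    # Ground truth: iso flags, post-merge spans, extension steps (naive).
    flagged = set(truth.novel_parent.values())
    for g in retained:
        truth.iso_flags[g.id] = g.id in flagged
        truth.merged_spans[g.id] = merged_spans[g.id]
    oracle_genes = [
        Gene(
            g.id,
            g.name,
            g.biotype,
            GenomicInterval(CHROM, merged_spans[g.id][0], merged_spans[g.id][1], g.span.strand),
        )
        for g in retained
    ]
    oracle = NaiveScanOracle(oracle_genes)
    for g in oracle_genes:
        step = _naive_extension_step(g, oracle, p.chrom_length)
        truth.extension_steps[g.id] = step
        final_id = g.id + ISO_SUFFIX if truth.iso_flags[g.id] else g.id
        truth.expected_extension_ids[g.id] = (
            extension_name(final_id, step) if step else None
        )
    return ref, novel, truth


def _naive_extension_step(gene: Gene, oracle: NaiveScanOracle, chrom_length: int) -> int:
    """Largest x in 10..1 whose downstream region fits, by exhaustive check."""
    span = gene.span
    for x in range(10, 0, -1):
        length = x * 1000
        if span.strand == "+":
            start, end = span.end, span.end + length
        else:
            start, end = span.start - length, span.start
        if start < 0 or end > chrom_length:
            continue
        region = GenomicInterval(span.chrom, start, end, span.strand)
        if not oracle.any_overlap(region, exclude=gene.id):
            return x
    return 0


def simulate_counts(
    ann: Annotation, n_cells: int, mean_count: float, seed: int
) -> Tuple[CountMatrix, GroundTruth]:
    """Simulate a cells x gene-variant count matrix over ``ann``'s genes.

    Per cell and base gene a Poisson total is drawn and split
    multinomially (uniform) across that gene's variant columns, so the
    generator-side totals are an exact oracle for count collapsing.
    """
    rng = np.random.default_rng(seed)
    col_ids = list(ann.genes.keys())
    keys = [parse_gene_key(c) for c in col_ids]
    base_order: List[str] = []
    groups: Dict[str, List[int]] = {}
    for j, k in enumerate(keys):
        if k.base not in groups:
            groups[k.base] = []
            base_order.append(k.base)
        groups[k.base].append(j)

    cell_ids = [f"CELL{i:05d}" for i in range(n_cells)]
    totals = rng.poisson(mean_count, size=(n_cells, len(base_order))).astype(np.int64)
    dense = np.zeros((n_cells, len(col_ids)), dtype=np.int64)
    for b, base in enumerate(base_order):
        cols = groups[base]
        k = len(cols)
        if k == 1:
            dense[:, cols[0]] = totals[:, b]
        else:
            split = rng.multinomial(totals[:, b], [1.0 / k] * k)
            for local, j in enumerate(cols):
                dense[:, j] = split[:, local]
    truth = GroundTruth(
        collapsed_totals=pd.DataFrame(totals, index=cell_ids, columns=base_order)
    )
    matrix = CountMatrix(values=dense, cell_ids=cell_ids, column_keys=keys)
    return matrix, truth
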