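"""Transcript merging, -iso renaming, and downstream extension genes."""

import pytest

from isoextend.association import ClassCode, ClassifiedTranscript, classify_transcripts
from isoextend.augment import (
    add_extension_genes,
    augment_annotation,
    compute_extension,
    merge_transcripts,
)
from isoextend.fixtures import SimulationParams, simulate_annotation
from isoextend.genome_index import NaiveScanOracle, build_index
from isoextend.gtf_io import filter_biotypes
from isoextend.model import Annotation, Exon, GenomicInterval, Transcript

from conftest import make_annotation, make_gene


def associated(tid, exons, gene_id, strand="+", chrom="chr1"):
    t = Transcript(
        tid,
        "whatever",
        [Exon(GenomicInterval(chrom, s, e, strand), tid) for s, e in exons],
        source="novel",
    )
    return ClassifiedTranscript(t, gene_id, ClassCode.EXTENDS, 1)


class TestMergeTranscripts:
    def test_gene_renamed_and_span_extended(self):
        ref = make_annotation(make_gene("G1", 1000, 5000))
        merged, report = merge_transcripts(ref, [associated("N1", [(1200, 6200)], "G1")])
        assert "G1" not in merged.genes
        g = merged.genes["G1-iso"]
        assert (g.span.start, g.span.end) == (1000, 6200)
        assert g.name == "G1"  # names keep their original form
        assert {t.gene_id for t in g.transcripts} == {"G1-iso"}
        assert report.n_genes_augmented == 1
        assert report.n_genes_body_extended == 1

    def test_no_associated_transcripts_is_identity(self):
        ref = make_annotation(make_gene("G1", 1000, 5000))
        t = associated("N1", [(1200, 6200)], "G1")
        dropped = ClassifiedTranscript(t.transcript, None, ClassCode.ANTISENSE, 0)
        merged, report = merge_transcripts(ref, [dropped])
        assert set(merged.genes) == {"G1"}
        assert merged.genes["G1"].span == ref.genes["G1"].span
        assert report.n_transcripts_added == 0
        assert report.n_transcripts_dropped == 1

    def test_iso_suffix_applied_once_for_two_transcripts(self):
        ref = make_annotation(make_gene("G1", 1000, 5000))
        merged, _ = merge_transcripts(
            ref,
            [
                associated("N1", [(800, 4000)], "G1"),
                associated("N2", [(1200, 6200)], "G1"),
            ],
        )
        g = merged.genes["G1-iso"]
        assert (g.span.start, g.span.end) == (800, 6200)
        assert not g.id.endswith("-iso-iso")
        assert len(g.transcripts) == 3

    def test_unknown_target_gene_raises(self):
        ref = make_annotation(make_gene("G1", 1000, 5000))
        with pytest.raises(ValueError, match="absent"):
            merge_transcripts(ref, [associated("N1", [(1200, 6200)], "NOPE")])


class TestComputeExtension:
    def test_plus_strand_blocked_at_step_four(self):
        ann = make_annotation(
            make_gene("G", 10_000, 15_000), make_gene("H", 18_500, 20_000)
        )
        ext = compute_extension("G", ann, build_index(ann))
        assert ext is not None
        assert ext.step_kb == 3
        assert (ext.region.start, ext.region.end) == (15_000, 18_000)
        assert ext.id == "G-ext3kb" and ext.name == "G-ext3kb"

    def test_minus_strand_blocked_at_first_step(self):
        ann = make_annotation(
            make_gene("G", 50_000, 60_000, "-"), make_gene("H", 49_000, 49_700, "-")
        )
        assert compute_extension("G", ann, build_index(ann)) is None

    def test_isolated_gene_reaches_cap(self):
        ann = make_annotation(make_gene("G", 10_000, 15_000))
        ext = compute_extension("G", ann, build_index(ann))
        assert ext.step_kb == 10
        assert (ext.region.start, ext.region.end) == (15_000, 25_000)

    def test_opposite_strand_neighbor_is_not_an_obstacle(self):
        ann = make_annotation(
            make_gene("G", 10_000, 15_000, "+"), make_gene("H", 15_500, 16_000, "-")
        )
        assert compute_extension("G", ann, build_index(ann)).step_kb == 10

    def test_exact_boundary_gap_half_open(self):
        # gap of exactly 3000: the 3 kb region ends where the neighbor starts
        ann = make_annotation(make_gene("G", 0, 5_000), make_gene("H", 8_000, 9_000))
        assert compute_extension("G", ann, build_index(ann)).step_kb == 3
        # one bp less: only 2 whole steps fit
        ann2 = make_annotation(make_gene("G", 0, 5_000), make_gene("H", 7_999, 9_000))
        assert compute_extension("G", ann2, build_index(ann2)).step_kb == 2

    def test_chromosome_end_limits_step(self):
        ann = make_annotation(make_gene("G", 0, 5_000), chrom_sizes={"chr1": 9_500})
        assert compute_extension("G", ann, build_index(ann)).step_kb == 4

    def test_minus_strand_chromosome_start_limits_step(self):
        ann = make_annotation(make_gene("G", 2_500, 5_000, "-"))
        assert compute_extension("G", ann, build_index(ann)).step_kb == 2

    def test_downstream_edge_inside_other_gene_yields_none(self):
        ann = make_annotation(make_gene("G", 0, 5_000), make_gene("H", 4_000, 9_000))
        assert compute_extension("G", ann, build_index(ann)) is None

    def test_unknown_gene_raises(self):
        ann = make_annotation(make_gene("G", 0, 5_000))
        with pytest.raises(KeyError):
            compute_extension("NOPE", ann, build_index(ann))


class TestAddExtensionGenes:
    def test_tandem_layout_extension_set(self, tandem_plus_layout):
        out, report = add_extension_genes(tandem_plus_layout)
        ext = {g.parent_id: g for g in out.genes.values() if g.biotype == "extension"}
        # A's 1 kb region [2000,3000) hits B; B and C are clear for 10 kb
        assert set(ext) == {"B", "C"}
        assert ext["B"].span.start == 4_000 and ext["B"].span.end == 14_000
        assert ext["C"].id == "C-ext10kb"
        assert report.n_extension_genes == 2
        # originals untouched
        assert tandem_plus_layout.genes["A"].span.end == 2_000
        assert set(out.genes) >= {"A", "B", "C"}

    def test_single_isolated_gene_gets_cap_extension(self):
        out, _ = add_extension_genes(make_annotation(make_gene("G", 0, 2_000)))
        ext = out.genes["G-ext10kb"]
        assert ext.biotype == "extension" and ext.parent_id == "G"
        assert len(ext.transcripts) == 1
        assert ext.transcripts[0].exon_chain() == ((2_000, 12_000),)

    def test_extension_regions_are_not_mutual_obstacles_by_default(self):
        # two + genes sharing a downstream edge: both extensions start at
        # 5000 and overlap each other, which the default mode permits
        ann = make_annotation(make_gene("A", 0, 5_000), make_gene("B", 3_000, 5_000))
        out, _ = add_extension_genes(ann)
        assert out.genes["A-ext10kb"].span.start == 5_000
        assert out.genes["B-ext10kb"].span.start == 5_000

    def test_strict_mode_blocks_on_prior_extensions(self):
        ann = make_annotation(make_gene("A", 0, 5_000), make_gene("B", 3_000, 5_000))
        out, _ = add_extension_genes(ann, strict_extension_obstacles=True)
        # A is processed first (smaller start) and claims [5000, 15000);
        # every candidate region for B then collides with it
        assert out.genes["A-ext10kb"].span == GenomicInterval("chr1", 5_000, 15_000, "+")
        assert not any(g.parent_id == "B" for g in out.genes.values())

    def test_iso_gene_extension_name_stacks_suffixes(self):
        ref = make_annotation(make_gene("G1", 1_000, 5_000))
        extended, _ = augment_annotation(ref, [associated("N1", [(1_200, 6_200)], "G1")])
        names = set(extended.genes)
        assert "G1-iso" in names
        assert "G1-iso-ext10kb" in names


@pytest.mark.parametrize("seed", range(8))
def test_extension_invariants_on_simulated_annotations(seed):
    """Length, adjacency, non-intersection and maximality, vs the naive scan."""
    ref, novel, truth = simulate_annotation(SimulationParams(n_genes=80, seed=100 + seed))
    filtered = filter_biotypes(ref)
    classified = classify_transcripts(novel, filtered)
    extended, _ = augment_annotation(filtered, classified, chrom_sizes=ref.chrom_sizes)
    bodies = [g for g in extended.genes.values() if g.biotype != "extension"]
    oracle = NaiveScanOracle(bodies)
    chrom_len = ref.chrom_sizes["chr1"]
    ext_genes = [g for g in extended.genes.values() if g.biotype == "extension"]
    assert ext_genes, "simulation should yield at least one extension gene"
    for g in ext_genes:
        parent = extended.genes[g.parent_id]
        x = g.span.length // 1000
        assert g.span.length == x * 1000 and 1 <= x <= 10
        if parent.span.strand == "+":
            assert g.span.start == parent.span.end
        else:
            assert g.span.end == parent.span.start
        assert not oracle.any_overlap(g.span, exclude=parent.id)
        if x < 10:
            # one more step must violate bounds or hit a same-strand body
            if parent.span.strand == "+":
                nxt_start, nxt_end = parent.span.end, parent.span.end + (x + 1) * 1000
            else:
                nxt_start, nxt_end = parent.span.start - (x + 1) * 1000, parent.span.start
            out_of_bounds = nxt_start < 0 or nxt_end > chrom_len
            if not out_of_bounds:
                nxt = GenomicInterval("chr1", nxt_start, nxt_end, parent.span.strand)
                assert oracle.any_overlap(nxt, exclude=parent.id)


def test_removing_a_gene_never_decreases_extension_steps():
    ref, novel, _ = simulate_annotation(SimulationParams(n_genes=40, seed=5))
    filtered = filter_biotypes(ref)
    base, _ = add_extension_genes(filtered, chrom_sizes=ref.chrom_sizes)
    steps = {
        g.parent_id: g.span.length // 1000
        for g in base.genes.values()
        if g.biotype == "extension"
    }
    victim = next(iter(filtered.genes))
    smaller = filtered.copy()
    del smaller.genes[victim]
    after, _ = add_extension_genes(smaller, chrom_sizes=ref.chrom_sizes)
    steps_after = {
        g.parent_id: g.span.length // 1000
        for g in after.genes.values()
        if g.biotype == "extension"
    }
    for gid, step in steps.items():
        if gid == victim:
            continue
        assert steps_after.get(gid, 0) >= step
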