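# Methods

## Pipeline

Inputs are a reference annotation (Ensembl-style GTF with `gene_id`,
`transcript_id`, `gene_name`, `gene_biotype`) and a novel annotation of
long-read transcript models (transcripts + exons; gene lines optional).
The stages, in order:

1. **Biotype filter.** Genes whose `gene_biotype` is in the excluded set —
   by default exactly `{pseudogene, processed_pseudogene}` — are removed
   with their transcripts. Other pseudogene subtypes (e.g.
   `transcribed_pseudogene`) are retained unless excluded explicitly; the
   filter matches literal strings, not substrings.
2. **Association.** Each novel transcript is assigned to at most one
   same-strand reference gene: the one sharing the most exonic bases
   (intersection of merge-normalised exon unions), requiring at least
   `min_overlap_bp` (default 1). Ties are broken by larger span overlap,
   then lexicographically smallest gene id, making the output
   deterministic. Transcripts whose only exonic overlap is on the opposite
   strand are `antisense`; transcripts overlapping nothing exonically are
   `intergenic`; neither associates. Associated transcripts get a coarse
   code (`equal`, `contained`, `extends`, `novel_isoform`) for reporting;
   the merge treats all four identically, since any same-strand transcript
   can carry the 3' evidence the method is after. `novel_isoform` is a
   defensive fallback: with `contained`/`extends` defined on spans it is
   not reachable, but it keeps the enum total.
3. **Merge and rename.** Associated transcripts are appended to their
   target gene (their `gene_id` rewritten); the gene body becomes the
   envelope of the old span and all added transcript spans — extension on
   either side is permitted, though 3' extension is the motivating case.
   Genes that received at least one transcript have `-iso` appended to
   their id, exactly once; the gene *name* is left unchanged (the naming
   rule is stated for the id; keeping names stable preserves downstream
   symbol lookups). Unassociated transcripts are dropped and counted.
4. **Extension genes.** For each gene of the post-merge annotation, the
   candidate region at step x is the x·1000 bp window abutting the gene's
   strand-downstream edge. The largest x in {1..max_kb} (default 10, step
   1 kb) is chosen such that the region (a) overlaps no same-strand gene
   body other than the parent and (b) lies within `[0, chrom length)` —
   the upper bound only when a chromosome-sizes table is supplied,
   otherwise a warning is logged and only the ≥ 0 bound applies. Only
   whole steps are emitted: a 2,999 bp gap yields x = 2. The extension is
   materialised as a single-exon gene, biotype `extension`, id and name
   `<parent>-ext<x>kb` (so an augmented parent yields
   `<gene>-iso-ext<x>kb`: renaming precedes extension).
5. **Count collapse.** Matrix columns are parsed into (base, variant) by
   stripping a terminal `-ext<x>kb` (x restricted to 1..10) and then a
   terminal `-iso`; counts are summed per base in first-appearance column
   order. The operation is pure integer addition: per-cell and global
   totals are conserved exactly, and it is idempotent.

## Conventions and numerical choices

- **Coordinates** are 0-based half-open internally; GTF I/O converts
  to/from 1-based inclusive (`internal = (gtf_start − 1, gtf_end)`).
  Half-open intervals make the step arithmetic exact: a gap of exactly
  k·1000 bp admits step k (regions may abut), k·1000 − 1 admits k − 1.
- **Strand is mandatory.** Gene or transcript records with strand `.` are
  rejected at parse time rather than guessed — downstream direction and
  same-strand association are undefined without it.
- **Overlap granularity.** Gene-level obstacles (extension placement) use
  gene *spans*; transcript association uses *exonic* bases. The former
  matches the "does not intersect with any other same strand gene" rule;
  the latter favours genuinely shared exon structure over incidental span
  overlap with a neighbouring gene's intron.
- **Obstacle set.** Extensions are checked against post-merge gene bodies
  only; extension regions are not obstacles to one another. Geometrically
  the two readings differ only when same-strand genes share a downstream
  edge (both extensions then start at the same coordinate); a strict mode
  (`--strict-extension-obstacles`) is provided in which extensions are
  placed in (chrom, start) order and each placed region blocks later
  candidates.
- **Determinism.** GTF output is sorted by (chrom, start, id) with a fixed
  attribute layout; Matrix Market output uses canonical column-major entry
  order; classification output preserves input order. Identical inputs and
  config produce byte-identical outputs.
- **Index.** Overlap queries run on an interval tree per (chromosome,
  strand); an exhaustive linear-scan implementation with identical
  semantics serves as the independent oracle in tests and ground-truth
  computation and is never used in the production path (nor vice versa).
- **Collisions.** If a matrix contains both a bare base column and an
  `-iso` column of the same base (e.g. `G1` and `G1-iso`), they are summed
  with a logged warning — the augmented annotation never emits both, so
  their co-occurrence suggests mixed inputs. A base co-occurring with its
  `-ext<x>kb` column is the normal layout for a non-augmented gene and
  warrants no warning.

## Synthetic data

`isoextend.fixtures` generates the study conditions for every stage, with
ground truth bookkept at generation time:

- ~500 genes (1–3 exons of 200–800 bp, introns 100–1000 bp) placed
  left-to-right without overlap on a 10 Mb chromosome; strands Bernoulli
  (p = 0.5 minus); 10% pseudogenes (split between the two filtered
  subtypes).
- Inter-gene gaps uniform on 100–15,000 bp, except that 20% of gaps are
  drawn exactly at k·1000 or k·1000 ± 1 bp (k = 1..10) — the boundary
  regime where half-open adjacency decides whether step k fits.
- 35% of retained genes receive a novel transcript that copies the
  parent's exon chain and extends the 3'-terminal exon by 200–3,000 bp,
  clipped at the next same-strand gene body. Decoys: antisense copies of
  an exon on the flipped strand (5%) and short intergenic transcripts in
  wide gaps (5%), which must never associate.
- Expected extension steps are computed by exhaustively testing x = 10..1
  against the expected post-merge gene bodies with the naive linear scan —
  never with the production index.
- Count matrices: per cell and base gene a Poisson total (default mean 2)
  split uniformly-multinomially across the gene's variant columns, so
  collapsed output must equal the drawn totals exactly.

What the generator does *not* emulate: multi-chromosome layouts (tested
separately at the index level), overlapping or nested reference genes,
novel transcripts with unannotated splice junctions, UMI/ambient noise, or
any read-level process. Passing tests therefore demonstrate the interval
logic, naming and conservation contracts, not robustness to structurally
messy real annotations — on real data the association step inherits
whatever ambiguity the gene models have.

Problem sizes in the test suite and acceptance script (100 and 50
simulated annotations of 500 genes; a 1,000-cell × ~2,000-column matrix)
were chosen to exercise every regime at interactive runtimes.

## Limitations

- Association is exon-overlap-based and deliberately coarser than a full
  transcript-classification taxonomy; intron-contained (`i`-type)
  transcripts do not associate, which is the conservative reading of a
  same-strand-association rule.
- GFF3, CDS/UTR features and FASTA extraction are out of scope; the GTF
  writer emits gene/transcript/exon lines only.
- Extension genes assume quantification treats each GTF gene
  independently; overlapping extension regions (default mode) are handled
  by the quantifier's own multi-mapping policy, not here.
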