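# Methods

## Scope and model

`chimerasim` simulates fusion transcripts at the *transcript* level: a
fusion is an ordered join of exonic sequence runs, not a DNA-level
rearrangement with intronic breakpoints. It therefore emits spliced
chimeric RNA (plus its annotation) and leaves read simulation,
expression assignment and alignment to downstream tools.

All coordinates are 0-based half-open internally (genePred native).
GTF/GFF3 input is converted at the boundary via gffutils; both the
plain genePred (10-column) and refFlat (11-column) dialects are read
and written, auto-detected by column count.

## Gene selection

*Random mode* draws genes uniformly (weight 1/n each). *Background
mode* computes per-gene RPKM from a BAM of alignments:

    rpkm = 1e9 · count / (total_mapped_reads · exon_length)

- **Counting rule.** A mapped, primary, non-duplicate alignment whose
  aligned blocks overlap ≥ 1 exonic base of a gene counts once for that
  gene; a read overlapping two genes counts for both. This is the
  simplest defensible rule; fragment-level (paired-end) semantics are
  not modelled. `total_mapped_reads` is the number of mapped primary
  alignments in the file.
- **Exon model.** For a gene with several transcripts, the exon model
  is the union of exons across its transcripts; `exon_length` is the
  union length.
- **Cutoff.** Genes with RPKM strictly below the cutoff (default 0.2)
  are ignored; the boundary value passes.
- **Empirical sampler.** A histogram estimator over the retained RPKM
  values: equal-width bins spanning [min, max], bin probability
  proportional to membership; a bin is drawn by probability, then a
  member gene uniformly. The default bin count is k = n (one bin per
  gene), taken literally as the package's default smoothing rule;
  Sturges' k = ⌊log₂ n⌋ + 1 is available as `bin_rule="sturges"`. With
  all values identical the histogram degenerates to one bin of mass 1.
- **Binned sampler.** Genes sorted by RPKM are partitioned into m
  rank-contiguous near-equal strata (m = number of fusions, via
  `numpy.array_split`), one gene drawn uniformly per stratum; this
  covers the dynamic range by construction and requires m ≤ n. Only
  fusion slot 1 consumes the stratum schedule; partner slots are drawn
  uniformly from the retained profile, a choice made here since the
  stratification has no natural meaning for partners.
- **Threads.** The thread option parallelizes BAM decompression only;
  profiles are bit-identical for any thread count.

Per-slot filters (gene1/gene2/gene3) match a string against gene id,
transcript id or chromosome; a fully pinned fusion is deterministic
regardless of seed. Genes within one multi-gene fusion are kept
distinct by rejection sampling with a retry cap of 1000.

## Fusion construction

Arity classes: self (1 gene, two non-overlapping runs of one
transcript, joined 5'-run-then-3'-run), hybrid (2 genes), complex
(3 genes, parts ordered 5'/internal/3'). When a selected gene has
several transcripts one is chosen uniformly at random; frame-constrained
or CDS-only modes restrict the choice to coding transcripts.

- **Exon runs.** The 5' part takes the first n effective exons from the
  transcript's 5' end (strand-aware: genomically last exons on the
  minus strand); the 3' part the last n; internal parts any contiguous
  run. n is uniform on the feasible range.
- **Breakpoints.** By default the junction-side terminal exon of each
  run is split at a uniform internal position (offset ∈ [1, width−1],
  both fragments non-empty); width-1 exons cannot split and keep the
  boundary with a warning. `keep_exon_boundary` suppresses splitting
  entirely; it wins if both flags are set. Internal parts of complex
  fusions may split at both ends.
- **CDS-only.** Exons are first intersected with [cds_start, cds_end);
  non-coding transcripts are rejected for this mode.
- **Reading frame.** The frame congruence at a junction compares the
  translated length upstream of the junction — the 5' part's donated
  bases inside its CDS (5' UTR excluded), plus the full donated length
  of any intermediate part and all junction inserts — with the
  downstream part's codon-grid offset (its transcript's coding bases 5'
  of the junction), mod 3. `in_frame` (default) makes the congruence
  hold at every junction by adjusting split offsets by ≤ 2 bp,
  recomputing after each candidate adjustment (so an adjustment landing
  in non-coding sequence is detected rather than assumed);
  `out_of_frame` makes it fail at the first junction; `unconstrained`
  skips the check and is the only mode accepting non-coding partners.
  In boundary mode offsets cannot be adjusted, so runs are re-drawn
  until a frame-compatible boundary pair appears (retry cap 1000, then
  an error — never silent degradation). For complex fusions junctions
  are enforced left to right; each junction's adjustment touches only
  offsets that no earlier junction depends on.
- **Event classes.** Two-gene geometry: different chromosomes → CTX;
  same chromosome, opposite strands → ITX; same strand → DEL when the
  5' partner is transcriptionally upstream of the 3' partner, DUP
  otherwise; a DEL with no annotated same-strand gene strictly between
  the partners is refined to readthrough (adjacency in the sense of
  "nothing same-strand in between"; opposite-strand genes do not
  block it). DEL vs DUP follows the cytogenetic meaning of the labels:
  upstream→downstream fusion implies interstitial loss, the reverse a
  tandem duplication. Requested event mixtures are honored by
  rejection-sampling gene tuples until the pair classifies to the
  drawn class (readthrough is accepted where DEL was drawn, being its
  special case). Self fusions bypass classification.
- **Orientation.** Each part's sequence is the plus-strand
  concatenation of its fragments; with `auto_correct_orientation`,
  parts whose strand differs from part 1 are reverse-complemented so
  the chimera reads in the first gene's orientation. Without the flag
  the genomic-sense sequence is emitted unchanged, mirroring the
  annotation rows exactly.
- **Foreign inserts.** Optional i.i.d. uniform ACGT sequence of fixed
  length at each junction (default off). Insert length counts toward
  the frame congruence, since inserted bases are translated in the
  fused product.

## Output

The text table has one row per part (schema fixed in a `#` header
line, version 1): fusion id, arity class, event class, part order,
gene/transcript ids, chromosome, strand, split-adjusted fragment
coordinate lists in the UCSC comma-terminated dialect, a
reverse-complement flag, the option set, and the junction insert
(inserts have no genomic coordinates, so they are serialized verbatim).
The FASTA output (70-column wrap) is generated independently from the
in-memory objects; consistency between the two — re-extracting each
part from the reference by walking the text rows reproduces the FASTA
byte-for-byte — is asserted over 1,000 random fusions in the test
suite, which internalizes the alignment-based output validation one
would otherwise do by hand.

## Synthetic data

The fixture generators produce an faidx-indexed random genome
(uniform ACGT), a non-overlapping gene model (alternating strands, CDS
from inside the first to inside the last exon, exon widths 80–100 bp,
including a single-exon gene, a non-coding gene and a same-strand
adjacent pair as readthrough substrate), and a coordinate-sorted BAM
whose per-gene read counts are specified exactly (single-end 50 bp,
MAPQ 60, no secondaries, each read wholly inside one exon). Ground
truth — counts, lengths, adjacency, hence every RPKM — is therefore
known in closed form. The fixtures deliberately do not model
sequencing error, fragment-length distributions, multi-mapping,
overlapping genes or isoform complexity, so passing tests demonstrate
correctness of the simulator's bookkeeping, not robustness to those
features of real data.

Default problem sizes used by the tests and the acceptance script —
three 12 kb chromosomes, 24 genes, 10,000-draw sampler checks, 1,000-
fusion property batches — were chosen as the smallest sizes at which
the stochastic assertions (3σ multinomial bands) are meaningful.

## Numerical and degenerate-input choices

- Histogram probabilities must sum to 1 within 1e-9; mixtures supplied
  by users must sum to 1 within 1e-6 (no silent renormalization beyond
  floating-point dust).
- Empty inputs fail loudly: an empty BAM (RPKM undefined), a filter
  eliminating all genes, a cutoff above the maximum RPKM.
- All randomness flows through one `numpy.random.Generator`; a fixed
  seed yields a byte-identical output corpus across runs.
- Retry caps (1000) bound every rejection loop; exceeding one raises
  an error naming the stage.

## Known limitations

No DNA-level breakpoints or intronic junctions; no expression levels
assigned to the simulated fusions; no read simulation or FASTQ output;
no paired-end fragment counting subtleties in the expression module;
no joint modelling of partner co-expression; GTF attribute handling
covers the common gene_id/transcript_id and ID/Parent conventions, not
every annotation dialect.
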