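# chimerasim

Simulation of chimeric (fusion) transcripts for benchmarking
fusion-discovery tools.

Gene fusions — chimeric RNAs joining exonic sequence from two (or one,
or three) genes after chromosomal rearrangement, trans-splicing or
transcriptional readthrough — are central biomarkers in cancer
genomics, and fusion-calling pipelines for RNA-Seq need realistic
positive controls with known truth. `chimerasim` produces such
controls: it selects genes from a gene model, constructs fusion
transcripts under configurable breakpoint rules, and emits them as a
refFlat-style annotation table plus spliced FASTA sequence, ready for a
read simulator.

## What it does

**Gene selection.** Genes are drawn either uniformly from the gene
model (each gene has weight 1/n), or weighted by expression computed
from a background BAM of RNA-Seq alignments. Expression is summarized
per gene as RPKM,

```
RPKM = 10^9 · C / (N · L)
```

with C the reads overlapping the gene's exon model, N the total mapped
reads and L the exonic length in bp. Genes below a cutoff (default
0.2 RPKM) are discarded; the survivors feed one of three samplers —
*uniform*, *empirical* (a histogram estimator over RPKM values, with
k = n bins by default or Sturges' k = ⌊log₂ n⌋ + 1), or *binned*
(genes ranked by RPKM and partitioned into m strata, one pick per
stratum, covering the full dynamic range).

**Fusion construction.** A fusion joins contiguous exon runs from each
partner. Breakpoints fall at random positions inside the junction exons
(*split exons*, the default) or exactly on annotated exon boundaries;
junctions preserve the downstream partner's reading frame by default
(offsets congruent mod 3), or deliberately disrupt it. Optional extras:
restricting donated sequence to the CDS, inserting random non-templated
sequence at junctions, and reverse-complementing partners on the
opposite strand of the first gene. Two-gene events are classified by
geometry as CTX (inter-chromosomal), ITX (same chromosome, opposite
strands), DUP (tandem duplication) or DEL (deletion), with readthrough
as the special adjacent-gene case of DEL; event classes can be drawn
from a user mixture, e.g. the proportions observed in cancer fusion
catalogs (88.3 / 4.8 / 5.5 / 1.4 % for CTX/ITX/DUP/DEL).

## Worked example

Generate a toy genome and gene model, then simulate five fusions:

```sh
python - <<'EOF'
from chimerasim import make_toy_genome, make_toy_models
make_toy_genome("toy.fa", 3, 12000, seed=1)
make_toy_models("toy.refflat", {f"chr{i}": 12000 for i in (1,2,3)}, seed=1)
EOF
chimerasim -g toy.refflat -r toy.fa -n 5 \
    --text-output fusions.txt --fasta-output fusions.fa --seed 3
```

stderr reports the pipeline stages:

```
INFO gene model: 24 transcripts, 24 genes
INFO built 5 fusions
INFO wrote fusions.txt and fusions.fa
```

`fusions.txt` holds one row per fusion part (a hybrid spans two rows
sharing a fusion id); the first fusion here is an ITX hybrid — two
chr1 genes on opposite strands:

```
fusion1  hybrid  ITX  1  chr1.g4  chr1.t4  chr1  +  1  1874,           1958,           0  ...  .
fusion1  hybrid  ITX  2  chr1.g5  chr1.t5  chr1  -  4  2417,2548,...   2508,2629,...   0  ...  .
```

The exon lists are split-adjusted: the part-1 fragment 1874–1958 ends
at a randomly drawn in-exon breakpoint chosen so the junction is
in-frame. `fusions.fa` holds the corresponding spliced sequences; the
header `fusion1|chr1.g4-chr1.g5|ITX|0-84;84-377` gives each part's
offsets within the 377 bp fused sequence.

With a background BAM, selection follows expression instead:

```sh
chimerasim -g toy.refflat -r toy.fa -n 20 -b background.bam \
    -m empirical -k 0.2 --text-output f.txt --fasta-output f.fa --seed 3
```

## Layout

- `src/chimerasim/gene_models.py` — genePred/refFlat parsing, GTF/GFF3
  conversion, model filtering and interval queries
- `src/chimerasim/reference_io.py` — faidx-backed FASTA access, reverse
  complement, transcript splicing
- `src/chimerasim/expression.py` — read counting, RPKM, the three samplers
- `src/chimerasim/selection.py` — per-fusion gene selection and filters
- `src/chimerasim/fusion_engine.py` — breakpoints, frame control, event
  taxonomy, sequence assembly
- `src/chimerasim/output_io.py` — fusion table and FASTA writers
- `src/chimerasim/fixtures.py` — synthetic genome / models / alignments
- `src/chimerasim/cli.py` — the `chimerasim` command and simulation driver

See `docs/methods.md` for the model, parameter and design notes.
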