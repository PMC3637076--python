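"""Synthetic input generators: toy genome, gene models and alignments.

These exist so every pipeline stage can be exercised without any
download, with ground truth known exactly by construction: gene
placement is non-overlapping, read counts per gene are specified up
front, and therefore every RPKM is known in closed form. They are not a
sequencing-error or fragment-length model.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from .gene_models import GeneModelSet, TranscriptModel, write_genepred

READ_LENGTH = 50  # single-end fixture reads, MAPQ 60, no secondaries

_EXON_WIDTH = 80
_INTRON_WIDTH = 40
_GENE_GAP = 60


def make_toy_genome(
    path: str | Path, n_chroms: int, length_bp: int, seed: int = 0
) -> Path:
    """Write ``n_chroms`` random ACGT sequences of ``length_bp`` each as
    an faidx-indexed FASTA (chr1..chrN). Deterministic under seed."""
    if length_bp < 1:
        raise ValueError("chromosome length must be >= 1")
    path = Path(path)
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for c in range(1, n_chroms + 1):
            fh.write(f">chr{c}\n")
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length_bp))
            for i in range(0, length_bp, 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(path))
    return path


def make_toy_models(
    path: str | Path,
    chrom_lengths: dict[str, int],
    genes_per_chrom: int = 8,
    exons_per_gene: int = 4,
    seed: int = 0,
) -> GeneModelSet:
    """Write a non-overlapping toy gene model as a refFlat table.

    Strands alternate; CDS spans from inside the first exon to inside
    the last. The first chromosome additionally carries one single-exon
    gene, one non-coding gene, and a consecutive same-strand gene pair
    (readthrough substrate). Raises if the genes do not fit.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    transcripts = []
    for ci, (chrom, length) in enumerate(sorted(chrom_lengths.items())):
        cursor = 100
        for gi in range(genes_per_chrom):
            gid = f"{chrom}.g{gi}"
            tid = f"{chrom}.t{gi}"
            special = ci == 0
            n_exons = 1 if (special and gi == 0) else exons_per_gene
            if special and gi in (2, 3):
                strand = "+"  # adjacent same-strand pair
            else:
                strand = "+" if (gi + ci) % 2 == 0 else "-"
            widths = [
                _EXON_WIDTH + int(rng.integers(0, 21)) for _ in range(n_exons)
            ]
            starts, ends = [], []
            pos = cursor
            for w in widths:
                starts.append(pos)
                ends.append(pos + w)
                pos += w + _INTRON_WIDTH
            tx_start, tx_end = starts[0], ends[-1]
            if special and gi == 1:
                cds_start = cds_end = tx_start  # non-coding
            else:
                cds_start = starts[0] + 20
                cds_end = ends[-1] - 20
            if tx_end + _GENE_GAP > length:
                raise ValueError(
                    f"{chrom}: {genes_per_chrom} genes x {exons_per_gene} exons "
                    f"do not fit in {length} bp"
                )
            transcripts.append(
                TranscriptModel(
                    gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                    tx_start=tx_start, tx_end=tx_end,
                    cds_start=cds_start, cds_end=cds_end,
                    exon_starts=tuple(starts), exon_ends=tuple(ends),
                )
            )
            cursor = tx_end + _GENE_GAP
    models = GeneModelSet(transcripts)
    write_genepred(models, path)
    return models


def make_toy_alignments(
    path: str | Path,
    models: GeneModelSet,
    per_gene_counts: dict[str, int],
    chrom_lengths: dict[str, int],
    seed: int = 0,
) -> Path:
    """Write a coordinate-sorted, indexed BAM with exactly the requested
    number of primary mapped reads per gene, each placed wholly inside
    one exon of that gene. Every gene's RPKM is then known exactly."""
    path = Path(path)
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    tid_of = {c: i for i, c in enumerate(chroms)}

    reads: list[tuple[int, int, str]] = []  # (tid, pos, qname)
    serial = 0
    for gid, count in per_gene_counts.items():
        transcripts = models.by_gene.get(gid)
        if not transcripts:
            raise ValueError(f"gene {gid!r} not in model set")
        t = transcripts[0]
        wide = [(s, e) for s, e in t.exons if e - s >= READ_LENGTH]
        if count > 0 and not wide:
            raise ValueError(f"gene {gid}: no exon can hold a {READ_LENGTH} bp read")
        for _ in range(count):
            s, e = wide[int(rng.integers(len(wide)))]
            pos = int(rng.integers(s, e - READ_LENGTH + 1))
            reads.append((tid_of[t.chrom], pos, f"read{serial}.{gid}"))
            serial += 1
    reads.sort()

    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for tid, pos, qname in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.query_sequence = "A" * READ_LENGTH
            a.flag = 0
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [(0, READ_LENGTH)]
            a.query_qualities = pysam.qualitystring_to_array("I" * READ_LENGTH)
            bam.write(a)
    pysam.index(str(path))
    return path
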