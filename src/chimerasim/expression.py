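"""Per-gene expression from background RNA-Seq alignments, and the
expression-aware gene samplers.

Expression is summarized as RPKM (reads per kilobase of exon model per
million mapped reads):

    rpkm = 1e9 * read_count / (total_mapped_reads * exon_length)

where the exon model of a gene is the union of exons over its
transcripts. A mapped, primary, non-duplicate alignment that overlaps at
least one exonic base of a gene counts once for that gene; a read
spanning two overlapping genes counts for both. Three samplers consume
the resulting profile: uniform over retained genes, empirical (histogram
of RPKM values), and binned (rank strata covering the dynamic range).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from intervaltree import IntervalTree

from .gene_models import GeneModelSet, merged_exon_intervals

logger = logging.getLogger(__name__)

DEFAULT_RPKM_CUTOFF = 0.2


class ExpressionError(ValueError):
    pass


@dataclass
class GeneExpression:
    read_count: int
    exon_length: int
    rpkm: float


@dataclass
class ExpressionProfile:
    """Per-gene read counts, exon-model lengths and RPKM values."""

    genes: dict[str, GeneExpression]
    total_mapped_reads: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def rpkm(self, gene_id: str) -> float:
        return self.genes[gene_id].rpkm

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_mapped_reads={self.total_mapped_reads}\n")
            fh.write("gene_id\tread_count\texon_length\trpkm\n")
            for gid, g in self.genes.items():
                fh.write(f"{gid}\t{g.read_count}\t{g.exon_length}\t{g.rpkm:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionProfile":
        genes: dict[str, GeneExpression] = {}
        total = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#total_mapped_reads="):
                    total = int(line.split("=", 1)[1])
                    continue
                if not line or line.startswith("gene_id"):
                    continue
                gid, count, length, rpkm = line.split("\t")
                genes[gid] = GeneExpression(int(count), int(length), float(rpkm))
        return cls(genes=genes, total_mapped_reads=total)


def compute_rpkm(count: int, total: int, length_bp: int) -> float:
    """RPKM = 1e9 * count / (total * length)."""
    if total <= 0:
        raise ExpressionError("total mapped reads must be positive for RPKM")
    if length_bp <= 0:
        raise ExpressionError("exon-model length must be positive for RPKM")
    return 1e9 * count / (total * length_bp)


def count_reads_per_gene(
    alignments: str | Path, models: GeneModelSet, threads: int = 1
) -> ExpressionProfile:
    """Count background reads per gene and compute RPKM.

    Each mapped, primary (non-secondary, non-supplementary),
    non-duplicate alignment whose aligned blocks overlap >= 1 exonic base
    of a gene increments that gene's count once; overlap with several
    genes increments each. ``total_mapped_reads`` is the number of mapped
    primary alignments in the file. ``threads`` only parallelizes BAM
    decompression; the resulting profile is identical for any value.
    """
    if len(models) == 0:
        raise ExpressionError("gene model set is empty")

    # gene exon models: union of exons per gene, indexed per chromosome
    trees: dict[str, IntervalTree] = {}
    lengths: dict[str, int] = {}
    for gid, transcripts in models.by_gene.items():
        lengths[gid] = 0
        by_chrom: dict[str, list] = {}
        for t in transcripts:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            ivs = merged_exon_intervals(ts)
            lengths[gid] += sum(e - s for s, e in ivs)
            for s, e in ivs:
                trees.setdefault(chrom, IntervalTree()).addi(s, e, gid)

    counts = {gid: 0 for gid in models.by_gene}
    total = 0
    try:
        bam = pysam.AlignmentFile(str(alignments), "rb", threads=max(1, threads))
    except (OSError, ValueError) as exc:
        raise ExpressionError(f"cannot read BAM {alignments}: {exc}") from exc
    with bam:
        header_chroms = set(bam.references)
        for chrom in set(trees) - header_chroms:
            warnings.warn(
                f"gene model chromosome {chrom} absent from BAM header; "
                "its genes get zero counts",
                stacklevel=2,
            )
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
            if read.is_duplicate:
                continue
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            hit: set[str] = set()
            for bs, be in read.get_blocks():
                for iv in tree.overlap(bs, be):
                    hit.add(iv.data)
            for gid in hit:
                counts[gid] += 1

    if total == 0:
        raise ExpressionError("no mapped reads in BAM: RPKM undefined")

    genes = {
        gid: GeneExpression(
            read_count=counts[gid],
            exon_length=lengths[gid],
            rpkm=compute_rpkm(counts[gid], total, lengths[gid]),
        )
        for gid in models.by_gene
    }
    return ExpressionProfile(genes=genes, total_mapped_reads=total)


def filter_by_rpkm(
    profile: ExpressionProfile, cutoff: float = DEFAULT_RPKM_CUTOFF
) -> ExpressionProfile:
    """Retain genes with rpkm >= cutoff; genes strictly below are ignored."""
    kept = {gid: g for gid, g in profile.genes.items() if g.rpkm >= cutoff}
    if not kept:
        raise ExpressionError(f"no genes pass RPKM cutoff {cutoff}")
    return ExpressionProfile(genes=kept, total_mapped_reads=profile.total_mapped_reads)


@dataclass
class EmpiricalDistribution:
    """Histogram estimator over RPKM values.

    Equal-width bins span [min rpkm, max rpkm]; each bin's probability is
    proportional to its gene membership. With all values identical the
    distribution degenerates to a single bin of probability 1.
    """

    bin_edges: np.ndarray
    bin_probability: np.ndarray
    bin_members: list[list[str]]

    def __post_init__(self) -> None:
        total = float(self.bin_probability.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ExpressionError(f"bin probabilities sum to {total}, not 1")


def build_empirical_distribution(
    profile: ExpressionProfile, bin_rule: str = "k_equals_n"
) -> EmpiricalDistribution:
    """Build the RPKM histogram used by the empirical sampler.

    ``bin_rule`` selects the bin count k: ``k_equals_n`` (default) uses
    one bin per gene, k = n; ``sturges`` uses k = floor(log2 n) + 1.
    """
    n = len(profile)
    if n < 1:
        raise ExpressionError("empty profile")
    gids = list(profile.genes)
    values = np.array([profile.genes[g].rpkm for g in gids], dtype=float)
    lo, hi = float(values.min()), float(values.max())

    if bin_rule == "k_equals_n":
        k = n
    elif bin_rule == "sturges":
        k = int(math.floor(math.log2(n))) + 1
    else:
        raise ExpressionError(f"unknown bin rule {bin_rule!r}")

    if lo == hi:
        # degenerate but valid: one bin holding everything
        return EmpiricalDistribution(
            bin_edges=np.array([lo, hi]),
            bin_probability=np.array([1.0]),
            bin_members=[list(gids)],
        )

    edges = np.linspace(lo, hi, k + 1)
    # right-closed top bin so the max value belongs to bin k-1
    idx = np.minimum(np.searchsorted(edges, values, side="right") - 1, k - 1)
    members: list[list[str]] = [[] for _ in range(k)]
    for gid, b in zip(gids, idx):
        members[int(b)].append(gid)
    probs = np.array([len(m) for m in members], dtype=float) / n
    return EmpiricalDistribution(bin_edges=edges, bin_probability=probs, bin_members=members)


def sample_gene_empirical(dist: EmpiricalDistribution, rng: np.random.Generator) -> str:
    """Draw a bin by its probability, then a member gene uniformly."""
    b = int(rng.choice(len(dist.bin_probability), p=dist.bin_probability))
    members = dist.bin_members[b]
    return members[int(rng.integers(len(members)))]


def select_binned(
    profile: ExpressionProfile, m: int, rng: np.random.Generator
) -> list[str]:
    """Select m genes, one per rank-contiguous RPKM stratum.

    Genes are sorted by RPKM and partitioned into m near-equal
    rank-contiguous bins; one gene is drawn uniformly from each, so the
    selection covers the full dynamic range of expression.
    """
    gids = sorted(profile.genes, key=lambda g: (profile.genes[g].rpkm, g))
    if m < 1 or m > len(gids):
        raise ExpressionError(
            f"cannot form {m} expression bins from {len(gids)} genes"
        )
    out = []
    for stratum in np.array_split(np.array(gids, dtype=object), m):
        out.append(str(stratum[int(rng.integers(len(stratum)))]))
    return out


def select_uniform_expressed(
    profile: ExpressionProfile, rng: np.random.Generator
) -> str:
    """Uniform draw over the retained (post-cutoff) genes."""
    gids = list(profile.genes)
    if not gids:
        raise ExpressionError("empty profile")
    return gids[int(rng.integers(len(gids)))]
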