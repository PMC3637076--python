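"""Transcript gene models in UCSC genePred semantics.

All coordinates are 0-based half-open throughout the package; GTF/GFF
input (1-based closed) is converted at the boundary. Two table dialects
are read and written: plain genePred (10 columns, the transcript name
doubles as the gene id) and refFlat (11 columns with a leading geneName).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

logger = logging.getLogger(__name__)


class GeneModelError(ValueError):
    """Raised for malformed gene-model input or unusable model queries."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's genomic structure.

    Coordinates are 0-based half-open. ``cds_start == cds_end`` encodes a
    non-coding transcript. ``exon_starts``/``exon_ends`` are parallel,
    ascending and non-overlapping, with ``tx_start == exon_starts[0]`` and
    ``tx_end == exon_ends[-1]``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        ns, ne = len(self.exon_starts), len(self.exon_ends)
        if ns != ne or ns < 1:
            raise GeneModelError(
                f"{self.transcript_id}: exon start/end lists of lengths {ns}/{ne}"
            )
        for i in range(ns):
            if self.exon_starts[i] >= self.exon_ends[i]:
                raise GeneModelError(
                    f"{self.transcript_id}: empty or inverted exon {i}"
                )
            if i and self.exon_ends[i - 1] > self.exon_starts[i]:
                raise GeneModelError(
                    f"{self.transcript_id}: exons {i - 1} and {i} overlap or are unsorted"
                )
        if self.tx_start != self.exon_starts[0] or self.tx_end != self.exon_ends[-1]:
            raise GeneModelError(
                f"{self.transcript_id}: tx bounds do not match exon span"
            )
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise GeneModelError(
                f"{self.transcript_id}: CDS bounds outside transcript span"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exon_starts)

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Exon intervals in genomic order."""
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end


@dataclass
class GeneModelSet:
    """A collection of transcripts indexed by gene, transcript and chrom."""

    transcripts: list[TranscriptModel] = field(default_factory=list)
    by_gene: dict[str, list[TranscriptModel]] = field(init=False)
    by_transcript: dict[str, TranscriptModel] = field(init=False)
    by_chrom: dict[str, list[TranscriptModel]] = field(init=False)

    def __post_init__(self) -> None:
        self.by_gene = {}
        self.by_transcript = {}
        self.by_chrom = {}
        for t in self.transcripts:
            if t.transcript_id in self.by_transcript:
                raise GeneModelError(f"duplicate transcript_id {t.transcript_id}")
            self.by_transcript[t.transcript_id] = t
            self.by_gene.setdefault(t.gene_id, []).append(t)
            self.by_chrom.setdefault(t.chrom, []).append(t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.by_gene)


def _parse_exon_list(text: str, line_no: int) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")
    except ValueError as exc:
        raise GeneModelError(f"line {line_no}: non-numeric exon coordinate") from exc


def read_genepred(path: str | Path) -> GeneModelSet:
    """Read a genePred or refFlat table into a :class:`GeneModelSet`.

    The dialect is auto-detected per line from the column count: 11
    columns means refFlat (leading geneName), 10 means plain genePred
    where the gene id equals the transcript name. Lines starting with
    ``#`` are skipped. Raises :class:`GeneModelError` naming the line
    number for malformed rows.
    """
    transcripts = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 11:
                gene_id, cols = cols[0], cols[1:]
            elif len(cols) == 10:
                gene_id = cols[0]
            else:
                raise GeneModelError(
                    f"line {line_no}: expected 10 or 11 tab-separated columns, got {len(cols)}"
                )
            name, chrom, strand = cols[0], cols[1], cols[2]
            try:
                tx_start, tx_end = int(cols[3]), int(cols[4])
                cds_start, cds_end = int(cols[5]), int(cols[6])
                exon_count = int(cols[7])
            except ValueError as exc:
                raise GeneModelError(f"line {line_no}: non-numeric coordinate") from exc
            starts = _parse_exon_list(cols[8], line_no)
            ends = _parse_exon_list(cols[9], line_no)
            if len(starts) != len(ends) or len(starts) != exon_count:
                raise GeneModelError(
                    f"line {line_no}: exon list lengths {len(starts)}/{len(ends)} "
                    f"do not match exonCount {exon_count}"
                )
            try:
                transcripts.append(
                    TranscriptModel(
                        gene_id=gene_id,
                        transcript_id=name,
                        chrom=chrom,
                        strand=strand,
                        tx_start=tx_start,
                        tx_end=tx_end,
                        cds_start=cds_start,
                        cds_end=cds_end,
                        exon_starts=starts,
                        exon_ends=ends,
                    )
                )
            except GeneModelError as exc:
                raise GeneModelError(f"line {line_no}: {exc}") from exc
    return GeneModelSet(transcripts)


def write_genepred(models: GeneModelSet, path: str | Path, refflat: bool = True) -> None:
    """Write a :class:`GeneModelSet` as a refFlat (default) or genePred table.

    Exon lists use the UCSC comma-terminated dialect, so the output
    round-trips through :func:`read_genepred` field-for-field.
    """
    with open(path, "w") as fh:
        for t in models:
            cols = [
                t.transcript_id,
                t.chrom,
                t.strand,
                str(t.tx_start),
                str(t.tx_end),
                str(t.cds_start),
                str(t.cds_end),
                str(t.exon_count),
                "".join(f"{s}," for s in t.exon_starts),
                "".join(f"{e}," for e in t.exon_ends),
            ]
            if refflat:
                cols.insert(0, t.gene_id)
            fh.write("\t".join(cols) + "\n")


def _feature_ids(feature) -> tuple[str | None, str | None]:
    """Extract (transcript_id, gene_id) from a GTF or GFF3 feature."""
    attrs = feature.attributes
    tid = None
    for key in ("transcript_id", "Parent", "ID"):
        if key in attrs and attrs[key]:
            tid = attrs[key][0]
            break
    gene = None
    for key in ("gene_id", "gene", "gene_name"):
        if key in attrs and attrs[key]:
            gene = attrs[key][0]
            break
    return tid, gene


def convert_gtf(path: str | Path) -> GeneModelSet:
    """Convert a GTF (or GFF3) annotation into genePred semantics.

    Features are parsed with :mod:`gffutils`; exon features are grouped
    by transcript identifier (GTF ``transcript_id`` or GFF3
    ``Parent``/``ID``), and 1-based closed coordinates become 0-based
    half-open. CDS bounds come from CDS features of the same transcript;
    transcripts with no CDS feature are marked non-coding
    (``cds_start == cds_end == tx_start``). Transcripts carrying no exon
    feature are skipped with a warning.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise GeneModelError(f"cannot parse annotation {path}: {exc}") from exc

    exon_map: dict[str, list[tuple[int, int]]] = {}
    cds_map: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    seen_tids: list[str] = []
    declared: set[str] = set()  # transcripts declared by transcript/mRNA rows

    for feature in db.all_features(order_by=("seqid", "start")):
        ftype = feature.featuretype
        if ftype in ("transcript", "mRNA"):
            tid = feature.attributes.get("transcript_id", [None])[0] or feature.id
            _, gene = _feature_ids(feature)
            declared.add(tid)
            meta.setdefault(tid, (gene or tid, feature.seqid, feature.strand))
            continue
        if ftype not in ("exon", "CDS"):
            continue
        tid, gene = _feature_ids(feature)
        if tid is None:
            raise GeneModelError(
                f"{ftype} feature at {feature.seqid}:{feature.start} has no "
                "transcript identifier"
            )
        iv = (feature.start - 1, feature.end)  # 1-based closed -> 0-based half-open
        if tid not in meta:
            meta[tid] = (gene or tid, feature.seqid, feature.strand)
        if tid not in seen_tids:
            seen_tids.append(tid)
        (exon_map if ftype == "exon" else cds_map).setdefault(tid, []).append(iv)

    for tid in sorted(declared - set(exon_map)):
        warnings.warn(f"transcript {tid} has no exon features; skipped", stacklevel=2)

    transcripts = []
    for tid in seen_tids:
        if tid not in exon_map:
            warnings.warn(f"transcript {tid} has no exon features; skipped", stacklevel=2)
            continue
        gene, chrom, strand = meta[tid]
        exons = sorted(exon_map[tid])
        starts = tuple(s for s, _ in exons)
        ends = tuple(e for _, e in exons)
        if tid in cds_map:
            cds_start = min(s for s, _ in cds_map[tid])
            cds_end = max(e for _, e in cds_map[tid])
        else:
            cds_start = cds_end = starts[0]
        transcripts.append(
            TranscriptModel(
                gene_id=gene,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                tx_start=starts[0],
                tx_end=ends[-1],
                cds_start=cds_start,
                cds_end=cds_end,
                exon_starts=starts,
                exon_ends=ends,
            )
        )
    return GeneModelSet(transcripts)


def filter_models(
    models: GeneModelSet, limit: str | None = None,
    predicate: Callable[[TranscriptModel], bool] | None = None,
) -> GeneModelSet:
    """Restrict a model set to transcripts matching ``limit`` or ``predicate``.

    The ``limit`` string is tried against gene_id, transcript_id and
    chrom; a transcript matching any of the three is retained. Raises
    :class:`GeneModelError` if the filter eliminates all genes.
    """
    if limit is None and predicate is None:
        return models
    kept = []
    for t in models:
        if limit is not None and limit not in (t.gene_id, t.transcript_id, t.chrom):
            continue
        if predicate is not None and not predicate(t):
            continue
        kept.append(t)
    if not kept:
        raise GeneModelError(
            f"filter eliminated all genes (limit={limit!r})"
        )
    return GeneModelSet(kept)


def coding_exon_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    """Exon intervals intersected with the CDS, for CDS-only fusion mode.

    Returns the non-empty intersections of each exon with
    ``[cds_start, cds_end)``, ascending and disjoint. Raises
    :class:`GeneModelError` for a non-coding transcript.
    """
    if not t.is_coding:
        raise GeneModelError(
            f"{t.transcript_id} is non-coding: CDS-only mode is unusable"
        )
    out = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo < hi:
            out.append((lo, hi))
    return out


def exonic_length(t: TranscriptModel) -> int:
    """Total exonic width in bp (the RPKM exon-model length L)."""
    return sum(e - s for s, e in t.exons)


def merged_exon_intervals(transcripts: Iterable[TranscriptModel]) -> list[tuple[int, int]]:
    """Union of exon intervals across transcripts (a gene's exon model)."""
    ivs = sorted(iv for t in transcripts for iv in t.exons)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
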