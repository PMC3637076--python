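"""Serialization of fusion transcripts: refFlat-style text and FASTA.

The text table carries one row per fusion *part*, so a hybrid emits two
contiguous rows sharing a fusion id; exon coordinate lists are
split-adjusted (they are the donated fragments) and use the UCSC
comma-terminated dialect. Junction inserts have no genomic coordinates
and are serialized verbatim in a per-row ``insert_after`` column. The
rows carry everything needed to re-extract the fusion sequence from the
reference, which is exactly how the FASTA output is cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .fusion_engine import FusionTranscript
from .reference_io import ReferenceGenome, reverse_complement

TABLE_VERSION = 1
_COLUMNS = [
    "fusion_id", "arity_class", "event_class", "part_order",
    "gene_id", "transcript_id", "chrom", "strand",
    "exon_count", "exon_starts", "exon_ends",
    "reverse_complemented", "options", "insert_after",
]
FASTA_WRAP = 70


def _options_field(f: FusionTranscript) -> str:
    o = f.options
    return ";".join(
        [
            f"split_exons={int(o.split_exons)}",
            f"keep_exon_boundary={int(o.keep_exon_boundary)}",
            f"cds_only={int(o.cds_only)}",
            f"foreign_insert_length={o.foreign_insert_length}",
            f"auto_correct_orientation={int(o.auto_correct_orientation)}",
            f"frame_mode={o.frame_mode}",
        ]
    )


def write_fusion_text(fusions: Iterable[FusionTranscript], path: str | Path) -> None:
    """Write the refFlat-style fusion table.

    One row per part; rows of one fusion are contiguous and ordered by
    ``part_order``. A ``#``-prefixed header line fixes the schema.
    """
    with open(path, "w") as fh:
        fh.write(f"#fusion_table_v{TABLE_VERSION}\t" + "\t".join(_COLUMNS) + "\n")
        for f in fusions:
            opts = _options_field(f)
            for i, part in enumerate(f.parts):
                frags = part.fragments
                insert = f.inserts[i] if i < len(f.inserts) else ""
                row = [
                    f.fusion_id,
                    f.arity_class,
                    f.event_class or "NA",
                    str(i + 1),
                    part.transcript.gene_id,
                    part.transcript.transcript_id,
                    part.transcript.chrom,
                    part.transcript.strand,
                    str(len(frags)),
                    "".join(f"{s}," for s, _ in frags),
                    "".join(f"{e}," for _, e in frags),
                    str(int(part.reverse_complemented)),
                    opts,
                    insert if insert else ".",
                ]
                fh.write("\t".join(row) + "\n")


@dataclass
class FusionRow:
    """One parsed row of the fusion table."""

    fusion_id: str
    arity_class: str
    event_class: str
    part_order: int
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    fragments: list[tuple[int, int]]
    reverse_complemented: bool
    options: str
    insert_after: str  # "" when absent


def read_fusion_text(path: str | Path) -> list[list[FusionRow]]:
    """Parse the fusion table back into grouped per-fusion row lists."""
    groups: dict[str, list[FusionRow]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(_COLUMNS):
                raise ValueError(
                    f"fusion table row has {len(cols)} columns, "
                    f"expected {len(_COLUMNS)}"
                )
            starts = [int(x) for x in cols[9].rstrip(",").split(",")]
            ends = [int(x) for x in cols[10].rstrip(",").split(",")]
            row = FusionRow(
                fusion_id=cols[0],
                arity_class=cols[1],
                event_class=cols[2],
                part_order=int(cols[3]),
                gene_id=cols[4],
                transcript_id=cols[5],
                chrom=cols[6],
                strand=cols[7],
                fragments=list(zip(starts, ends)),
                reverse_complemented=bool(int(cols[11])),
                options=cols[12],
                insert_after="" if cols[13] == "." else cols[13],
            )
            if row.fusion_id not in groups:
                groups[row.fusion_id] = []
                order.append(row.fusion_id)
            groups[row.fusion_id].append(row)
    for rows in groups.values():
        rows.sort(key=lambda r: r.part_order)
    return [groups[fid] for fid in order]


def reconstruct_sequence(rows: list[FusionRow], ref: ReferenceGenome) -> str:
    """Rebuild a fusion's sequence from its text rows alone.

    Walks the split-adjusted coordinates, re-extracts from the
    reference, applies per-part reverse complement and junction
    inserts. Serves as the independent check that text and FASTA
    outputs are mutually consistent.
    """
    chunks = []
    for i, row in enumerate(rows):
        seq = "".join(ref.fetch(row.chrom, s, e) for s, e in row.fragments)
        if row.reverse_complemented:
            seq = reverse_complement(seq)
        chunks.append(seq)
        if i < len(rows) - 1 and row.insert_after:
            chunks.append(row.insert_after)
    return "".join(chunks)


def fasta_header(f: FusionTranscript) -> str:
    genes = "-".join(p.transcript.gene_id for p in f.parts)
    spans = []
    pos = 0
    for i, part in enumerate(f.parts):
        ln = part.donated_length
        spans.append(f"{pos}-{pos + ln}")
        pos += ln
        if i < len(f.parts) - 1:
            pos += len(f.inserts[i])
    return f"{f.fusion_id}|{genes}|{f.event_class or 'NA'}|{';'.join(spans)}"


def write_fusion_fasta(
    fusions: Iterable[FusionTranscript], ref: ReferenceGenome, path: str | Path
) -> None:
    """Write one FASTA record per fusion, sequence wrapped at 70 columns.

    Headers read ``fusion_id|geneA-geneB[-geneC]|event_class|spans``
    where the spans are each part's half-open offsets within the fused
    sequence (junction inserts occupy the gaps between spans).
    """
    from .fusion_engine import assemble_sequence

    with open(path, "w") as fh:
        for f in fusions:
            seq = assemble_sequence(f, ref)
            fh.write(f">{fasta_header(f)}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")
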