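"""Random-access reference sequence retrieval and strand-aware splicing.

Backed by pysam's faidx machinery; a missing ``.fai`` index is built on
first open (same semantics as ``samtools faidx``). All sequence returned
is uppercase; ``N`` is permitted and propagated.
"""

from __future__ import annotations

import os
from pathlib import Path

import pysam

from .gene_models import TranscriptModel, exonic_length

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class ReferenceError(ValueError):
    """Raised for unknown sequences, out-of-range fetches or bad alphabets."""


class ReferenceGenome:
    """An faidx-indexed FASTA reference with bounds-checked fetches."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise ReferenceError(f"reference FASTA not found: {self.path}")
        fai = Path(str(self.path) + ".fai")
        if not fai.exists():
            pysam.faidx(str(self.path))
        self._fasta = pysam.FastaFile(str(self.path))
        self.lengths = dict(zip(self._fasta.references, self._fasta.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return exactly ``end - start`` uppercase plus-strand bases."""
        if chrom not in self.lengths:
            raise ReferenceError(f"unknown sequence {chrom!r} in {self.path.name}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise ReferenceError(
                f"interval {chrom}:{start}-{end} out of range "
                f"(length {self.lengths[chrom]})"
            )
        return self._fasta.fetch(chrom, start, end).upper()

    def close(self) -> None:
        self._fasta.close()

    def __enter__(self) -> "ReferenceGenome":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def fetch_sequence(ref: ReferenceGenome, chrom: str, start: int, end: int) -> str:
    """Functional alias for :meth:`ReferenceGenome.fetch`."""
    return ref.fetch(chrom, start, end)


def reverse_complement(seq: str, lenient: bool = False) -> str:
    """Reverse complement over {A,C,G,T,N}, case-insensitive.

    Non-IUPAC characters raise unless ``lenient`` is set, in which case
    they are replaced by ``N``. The operation is an involution:
    ``reverse_complement(reverse_complement(s)) == s``.
    """
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        if not lenient:
            raise ReferenceError(
                f"non-IUPAC characters {sorted(bad)} in sequence"
            )
        s = "".join(c if c in _VALID else "N" for c in s)
    return s.translate(_COMPLEMENT)[::-1]


def splice_transcript(ref: ReferenceGenome, t: TranscriptModel) -> str:
    """Spliced transcript sequence: exon concatenation, minus-strand
    transcripts reverse complemented. Length equals the exonic length."""
    seq = "".join(ref.fetch(t.chrom, s, e) for s, e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    assert len(seq) == exonic_length(t)
    return seq
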