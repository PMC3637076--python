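"""Shared fixtures: a toy genome, gene model set and background BAM,
generated once per session with ground truth known by construction."""

from __future__ import annotations

import numpy as np
import pytest

from chimerasim import (
    GeneModelSet,
    ReferenceGenome,
    make_toy_alignments,
    make_toy_genome,
    make_toy_models,
    read_genepred,
)

CHROM_LENGTHS = {"chr1": 12000, "chr2": 12000, "chr3": 12000}
GENES_PER_CHROM = 8
EXONS_PER_GENE = 4


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("toy")


@pytest.fixture(scope="session")
def genome_path(toy_dir):
    return make_toy_genome(toy_dir / "toy.fa", len(CHROM_LENGTHS), 12000, seed=11)


@pytest.fixture(scope="session")
def ref(genome_path):
    return ReferenceGenome(genome_path)


@pytest.fixture(scope="session")
def models_path(toy_dir):
    make_toy_models(
        toy_dir / "toy.refflat",
        CHROM_LENGTHS,
        genes_per_chrom=GENES_PER_CHROM,
        exons_per_gene=EXONS_PER_GENE,
        seed=11,
    )
    return toy_dir / "toy.refflat"


@pytest.fixture(scope="session")
def models(models_path) -> GeneModelSet:
    return read_genepred(models_path)


#: designed read counts per gene: a decade spread plus a silent gene
@pytest.fixture(scope="session")
def designed_counts(models):
    counts = {}
    for i, gid in enumerate(sorted(models.by_gene)):
        counts[gid] = [0, 5, 20, 100][i % 4]
    return counts


@pytest.fixture(scope="session")
def bam_path(toy_dir, models, designed_counts):
    return make_toy_alignments(
        toy_dir / "toy.bam", models, designed_counts, CHROM_LENGTHS, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class FakeRNG:
    """Deterministic stand-in for a Generator: pops queued draw values.

    ``integers(lo, hi)`` and ``choice`` return the next queued value,
    letting tests pin 'random' choices to enumerate specific cases.
    """

    def __init__(self, values):
        self.values = list(values)

    def _pop(self):
        if not self.values:
            raise AssertionError("FakeRNG exhausted")
        return self.values.pop(0)

    def integers(self, lo, hi=None, size=None):
        if size is not None:
            return np.array([self._pop() for _ in range(size)])
        return self._pop()

    def choice(self, n, p=None):
        return self._pop()


@pytest.fixture()
def fake_rng_factory():
    return FakeRNG
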