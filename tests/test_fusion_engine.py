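"""Breakpoint selection, frame control, event taxonomy and assembly."""

import math

import numpy as np
import pytest

from chimerasim import (
    ExonSelection,
    FusionOptions,
    TranscriptModel,
    TypeMixture,
    apply_split,
    assemble_sequence,
    build_fusion,
    choose_exon_run,
    classify_fusion,
    enforce_frame,
    generate_foreign_insert,
    junction_frame_shift,
    reverse_complement,
    sample_event_class,
)
from chimerasim.fusion_engine import FrameError, FusionBuildError
from chimerasim.gene_models import GeneModelSet


def mk_t(gene="G", tid="T", chrom="chr1", strand="+",
         exons=((0, 100), (200, 300), (400, 500)), cds="all"):
    starts = tuple(s for s, _ in exons)
    ends = tuple(e for _, e in exons)
    if cds == "all":
        cds = (starts[0], ends[-1])
    elif cds is None:
        cds = (starts[0], starts[0])
    return TranscriptModel(gene, tid, chrom, strand, starts[0], ends[-1],
                          cds[0], cds[1], starts, ends)


class TestChooseExonRun:
    @pytest.mark.parametrize(
        "strand,role,n,expected",
        [
            ("+", "five_prime", 2, (0, 1)),
            ("-", "five_prime", 2, (1, 2)),   # genomically LAST exons
            ("+", "three_prime", 2, (1, 2)),
            ("-", "three_prime", 2, (0, 1)),
            ("+", "five_prime", 3, (0, 2)),
        ],
    )
    def test_role_and_strand_enumeration(self, fake_rng_factory, strand, role, n, expected):
        t = mk_t(strand=strand)
        sel = choose_exon_run(t, role, FusionOptions(), fake_rng_factory([n]))
        assert (sel.first, sel.last) == expected

    def test_single_exon_run_is_that_exon(self, fake_rng_factory):
        t = mk_t(exons=((10, 90),))
        sel = choose_exon_run(t, "five_prime", FusionOptions(), fake_rng_factory([1]))
        assert sel.run_intervals == [(10, 90)]

    def test_internal_run_contiguous(self, fake_rng_factory):
        t = mk_t()
        sel = choose_exon_run(t, "internal", FusionOptions(), fake_rng_factory([2, 1]))
        assert (sel.first, sel.last) == (1, 2)

    def test_cds_only_uses_coding_intervals(self, fake_rng_factory):
        t = mk_t(cds=(50, 450))
        sel = choose_exon_run(
            t, "five_prime", FusionOptions(cds_only=True), fake_rng_factory([3])
        )
        assert sel.intervals == [(50, 100), (200, 300), (400, 450)]

    def test_cds_only_noncoding_errors(self, fake_rng_factory):
        t = mk_t(cds=None)
        with pytest.raises(Exception, match="non-coding"):
            choose_exon_run(t, "five_prime", FusionOptions(cds_only=True),
                            fake_rng_factory([1]))


class TestApplySplit:
    def _sel(self, role="five_prime", exons=((0, 100),), strand="+"):
        t = mk_t(strand=strand, exons=exons)
        ivs = t.exons
        return ExonSelection(t, ivs, 0, len(ivs) - 1, role)

    def test_offsets_uniform_over_internal_positions(self):
        rng = np.random.default_rng(2)
        n = 10_000
        offs = []
        for _ in range(n):
            sel = apply_split(self._sel(), FusionOptions(), rng)
            offs.append(sel.split_offset_3p)
        assert min(offs) >= 1 and max(offs) <= 99
        mean = sum(offs) / n
        sigma_mean = math.sqrt((99**2 - 1) / 12) / math.sqrt(n)
        assert abs(mean - 50.0) < 3 * sigma_mean

    def test_keep_exon_boundary_leaves_offsets_unset(self, rng):
        opts = FusionOptions(keep_exon_boundary=True)
        sel = apply_split(self._sel(exons=((0, 100), (200, 300))), opts, rng)
        assert sel.split_offset_5p is None and sel.split_offset_3p is None
        # junction coordinate is an annotated boundary
        assert sel.fragments[-1][1] in sel.transcript.exon_ends

    def test_width_one_exon_cannot_split(self, rng):
        with pytest.warns(UserWarning, match="width-1"):
            sel = apply_split(self._sel(exons=((5, 6),)), FusionOptions(), rng)
        assert sel.split_offset_3p is None

    def test_internal_role_splits_both_ends(self, rng):
        sel = apply_split(
            self._sel(role="internal", exons=((0, 100), (200, 300))),
            FusionOptions(), rng,
        )
        assert sel.split_offset_5p is not None and sel.split_offset_3p is not None

    def test_minus_strand_split_trims_genomic_low_end(self):
        # five_prime on minus strand: junction exon is genomically first;
        # retaining k transcript bases keeps the interval's high end
        t = mk_t(strand="-", exons=((0, 100), (200, 300)))
        sel = ExonSelection(t, t.exons, 0, 1, "five_prime", split_offset_3p=30)
        assert sel.fragments == [(70, 100), (200, 300)]


class TestEnforceFrame:
    def _pair(self, off5=300, off3=3):
        tA = mk_t("GA", "TA", exons=((0, 400),))
        tB = mk_t("GB", "TB", exons=((1000, 1400),))
        s5 = ExonSelection(tA, tA.exons, 0, 0, "five_prime", split_offset_3p=off5)
        s3 = ExonSelection(tB, tB.exons, 0, 0, "three_prime", split_offset_5p=off3)
        return s5, s3

    def test_congruent_junction_accepted_unchanged(self):
        s5, s3 = self._pair(300, 3)  # 300 donated ≡ 3 upstream (mod 3)
        enforce_frame(s5, s3, "in_frame")
        assert (s5.split_offset_3p, s3.split_offset_5p) == (300, 3)
        assert junction_frame_shift([s5, s3], [0], 0) == 0

    def test_301_donated_shifted_back_into_frame(self):
        s5, s3 = self._pair(301, 3)
        enforce_frame(s5, s3, "in_frame")
        assert junction_frame_shift([s5, s3], [0], 0) == 0
        assert abs(s5.split_offset_3p - 301) <= 2 or abs(s3.split_offset_5p - 3) <= 2

    def test_out_of_frame_breaks_congruence(self):
        s5, s3 = self._pair(300, 3)
        enforce_frame(s5, s3, "out_of_frame")
        assert junction_frame_shift([s5, s3], [0], 0) != 0

    def test_insert_length_counts_toward_frame(self):
        s5, s3 = self._pair(300, 3)
        enforce_frame(s5, s3, "in_frame", insert_length=2)
        assert junction_frame_shift([s5, s3], [2], 0) == 0

    def test_noncoding_transcript_rejected(self):
        tA = mk_t("GA", "TA", exons=((0, 400),), cds=None)
        tB = mk_t("GB", "TB", exons=((1000, 1400),))
        s5 = ExonSelection(tA, tA.exons, 0, 0, "five_prime", split_offset_3p=10)
        s3 = ExonSelection(tB, tB.exons, 0, 0, "three_prime", split_offset_5p=10)
        with pytest.raises(FrameError, match="unconstrained"):
            enforce_frame(s5, s3, "in_frame")

    def test_unconstrained_mode_is_identity(self):
        s5, s3 = self._pair(301, 3)
        enforce_frame(s5, s3, "unconstrained")
        assert (s5.split_offset_3p, s3.split_offset_5p) == (301, 3)


class TestClassifyFusion:
    def test_different_chroms_ctx(self):
        a = mk_t("BCR", "T1", chrom="chr22")
        b = mk_t("ABL1", "T2", chrom="chr9")
        assert classify_fusion(a, b) == "CTX"

    def test_opposite_strands_itx(self, models):
        a = models.by_transcript["chr1.t4"]  # +
        b = models.by_transcript["chr1.t5"]  # -
        assert a.chrom == b.chrom and a.strand != b.strand
        assert classify_fusion(a, b, models) == "ITX"

    def test_adjacent_same_strand_readthrough(self, models):
        a = models.by_transcript["chr1.t2"]
        b = models.by_transcript["chr1.t3"]
        assert a.strand == b.strand == "+"
        assert classify_fusion(a, b, models) == "readthrough"

    def test_same_strand_with_intervening_gene_del(self, models):
        a = models.by_transcript["chr1.t2"]
        b = models.by_transcript["chr1.t4"]  # chr1.g3 (+) lies between
        assert classify_fusion(a, b, models) == "DEL"

    def test_downstream_to_upstream_dup(self, models):
        a = models.by_transcript["chr1.t4"]
        b = models.by_transcript["chr1.t2"]
        assert classify_fusion(a, b, models) == "DUP"

    def test_minus_strand_transcription_order(self):
        a = mk_t("A", "TA", strand="-", exons=((2000, 2100), (2200, 2400)))
        b = mk_t("B", "TB", strand="-", exons=((100, 300), (400, 500)))
        assert classify_fusion(a, b) == "DEL"  # a is transcriptionally upstream
        assert classify_fusion(b, a) == "DUP"

    def test_self_pair_not_classifiable(self):
        a = mk_t()
        with pytest.raises(FusionBuildError):
            classify_fusion(a, a)


class TestSampleEventClass:
    def test_degenerate_mixture_always_ctx(self, rng):
        mix = TypeMixture({"CTX": 1.0, "ITX": 0.0, "DUP": 0.0, "DEL": 0.0})
        assert {sample_event_class(mix, rng) for _ in range(100)} == {"CTX"}

    def test_unnormalized_mixture_rejected(self):
        with pytest.raises(ValueError, match="sums to 0.9"):
            TypeMixture({"CTX": 0.5, "ITX": 0.4})

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            TypeMixture({"CTX": 1.5, "ITX": -0.5})


class TestForeignInsert:
    def test_length_and_alphabet(self, rng):
        s = generate_foreign_insert(10, rng)
        assert len(s) == 10 and set(s) <= set("ACGT")

    def test_base_frequencies_within_3_sigma(self):
        s = generate_foreign_insert(100_000, np.random.default_rng(8))
        sigma = math.sqrt(0.25 * 0.75 / len(s))
        for b in "ACGT":
            assert abs(s.count(b) / len(s) - 0.25) < 3 * sigma

    def test_same_seed_identical(self):
        a = generate_foreign_insert(50, np.random.default_rng(4))
        b = generate_foreign_insert(50, np.random.default_rng(4))
        assert a == b


class TestBuildFusion:
    def test_boundary_mode_junction_on_annotated_boundaries(self, models, rng):
        opts = FusionOptions(keep_exon_boundary=True)
        f = build_fusion(("chr1.g2", "chr1.g3"), models, opts, rng)
        p5, p3 = f.parts
        assert p5.fragments[-1][1] in p5.transcript.exon_ends
        assert p3.fragments[0][0] in p3.transcript.exon_starts

    def test_self_fusion_two_runs_of_one_transcript(self, models, rng):
        f = build_fusion(("chr1.g2",), models, FusionOptions(), rng)
        assert f.arity_class == "self"
        assert len(f.parts) == 2
        t_ids = {p.transcript.transcript_id for p in f.parts}
        assert t_ids == {"chr1.t2"}
        # non-overlapping exon runs
        assert f.parts[0].last < f.parts[1].first or f.parts[1].last < f.parts[0].first

    def test_complex_fusion_three_distinct_genes(self, models, rng):
        f = build_fusion(("chr1.g2", "chr2.g3", "chr3.g4"), models, FusionOptions(), rng)
        assert f.arity_class == "complex"
        assert len({p.transcript.gene_id for p in f.parts}) == 3

    def test_in_frame_default_holds_at_every_junction(self, models, rng):
        for _ in range(20):
            f = build_fusion(("chr1.g2", "chr2.g3", "chr3.g4"), models,
                             FusionOptions(), rng)
            for j in range(len(f.parts) - 1):
                assert junction_frame_shift(f.parts, f.inserts, j) == 0

    def test_duplicate_genes_rejected(self, models, rng):
        with pytest.raises(FusionBuildError, match="distinct"):
            build_fusion(("chr1.g2", "chr1.g2"), models, FusionOptions(), rng)

    def test_requested_class_must_match_pair(self, models, rng):
        with pytest.raises(FusionBuildError, match="CTX"):
            build_fusion(("chr1.g2", "chr1.g3"), models, FusionOptions(), rng,
                         event_class="CTX")


class TestAssembleSequence:
    def test_matches_manual_concatenation(self, models, ref, rng):
        opts = FusionOptions(keep_exon_boundary=True)
        f = build_fusion(("chr1.g2", "chr1.g3"), models, opts, rng)
        manual = "".join(
            ref.fetch(p.transcript.chrom, s, e)
            for p in f.parts for s, e in p.fragments
        )
        assert assemble_sequence(f, ref) == manual

    def test_insert_extends_length_exactly(self, models, ref, rng):
        opts = FusionOptions(foreign_insert_length=10, frame_mode="unconstrained")
        f = build_fusion(("chr1.g2", "chr2.g3"), models, opts, rng)
        assert len(assemble_sequence(f, ref)) == sum(
            p.donated_length for p in f.parts) + 10

    def test_auto_correct_rc_of_opposite_strand_part(self, models, ref, rng):
        opts = FusionOptions(auto_correct_orientation=True, frame_mode="unconstrained")
        # chr1.g4 is plus strand, chr1.g5 minus
        f = build_fusion(("chr1.g4", "chr1.g5"), models, opts, rng)
        p5, p3 = f.parts
        assert p3.reverse_complemented
        plus_splice = "".join(ref.fetch(p3.transcript.chrom, s, e)
                              for s, e in p3.fragments)
        assert assemble_sequence(f, ref).endswith(reverse_complement(plus_splice))
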