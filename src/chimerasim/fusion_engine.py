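"""Construction of chimeric (fusion) transcripts.

A fusion is an ordered list of one to three *parts*, each a contiguous
run of (possibly split) exons from one transcript. Fusions built from
1, 2 or 3 distinct genes are called *self*, *hybrid* and *complex*.
Two-gene events are further classified by genomic geometry:

  CTX  inter-chromosomal;
  ITX  same chromosome, opposite strands;
  DEL  same chromosome and strand, 5' partner transcriptionally
       upstream of the 3' partner (interstitial loss);
  DUP  same chromosome and strand, 5' partner downstream (tandem
       duplication);
  readthrough  DEL between adjacent genes (no annotated same-strand
       gene in between), modelling transcription running through.

Breakpoints either split an exon at a random internal position
(default) or fall on annotated exon boundaries; optional extras are
restriction to coding exons, a random non-templated insert at each
junction, orientation auto-correction, and reading-frame control at the
junctions (in-frame by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gene_models import (
    GeneModelError,
    GeneModelSet,
    TranscriptModel,
    coding_exon_intervals,
)
from .reference_io import ReferenceGenome, reverse_complement

logger = logging.getLogger(__name__)

RETRY_CAP = 1000

EVENT_CLASSES = ("CTX", "ITX", "DUP", "DEL", "readthrough")
ARITY_CLASSES = {1: "self", 2: "hybrid", 3: "complex"}


class FusionBuildError(RuntimeError):
    """A fusion could not be constructed; the message names the stage."""


class FrameError(FusionBuildError):
    pass


@dataclass
class FusionOptions:
    """Knobs controlling breakpoint placement and junction semantics.

    ``keep_exon_boundary`` and ``split_exons`` are mutually exclusive
    resolutions of the breakpoint; boundary wins when both are set.
    ``foreign_insert_length`` of 0 disables junction inserts.
    ``frame_mode`` is one of ``in_frame`` (default), ``out_of_frame``,
    ``unconstrained``.
    """

    split_exons: bool = True
    keep_exon_boundary: bool = False
    cds_only: bool = False
    foreign_insert_length: int = 0
    auto_correct_orientation: bool = False
    frame_mode: str = "in_frame"

    def __post_init__(self) -> None:
        if self.frame_mode not in ("in_frame", "out_of_frame", "unconstrained"):
            raise ValueError(f"unknown frame_mode {self.frame_mode!r}")
        if self.foreign_insert_length < 0:
            raise ValueError("foreign_insert_length must be >= 0")

    @property
    def splitting(self) -> bool:
        return self.split_exons and not self.keep_exon_boundary


@dataclass
class ExonSelection:
    """A contiguous run of effective exons from one transcript.

    ``intervals`` is the transcript's full effective interval list
    (annotated exons, or their CDS intersections under cds_only), in
    genomic order; the run is ``intervals[first : last + 1]``. Split
    offsets are measured in transcript orientation: ``split_offset_5p``
    drops that many bases from the run's transcript-5' terminal exon,
    ``split_offset_3p`` retains that many bases of the transcript-3'
    terminal exon. Offsets are strictly inside their exon, so fragments
    are never empty.
    """

    transcript: TranscriptModel
    intervals: list[tuple[int, int]]
    first: int
    last: int
    role: str  # five_prime | internal | three_prime
    split_offset_5p: int | None = None
    split_offset_3p: int | None = None
    reverse_complemented: bool = False

    @property
    def run_intervals(self) -> list[tuple[int, int]]:
        return self.intervals[self.first : self.last + 1]

    @property
    def fragments(self) -> list[tuple[int, int]]:
        """Genomic intervals actually donated, after split trimming."""
        ivs = [list(iv) for iv in self.run_intervals]
        minus = self.transcript.strand == "-"
        if self.split_offset_5p is not None:
            k = self.split_offset_5p
            i = -1 if minus else 0  # transcript-5' terminal exon
            if minus:
                ivs[i][1] -= k
            else:
                ivs[i][0] += k
        if self.split_offset_3p is not None:
            k = self.split_offset_3p
            i = 0 if minus else -1  # transcript-3' terminal exon
            if minus:
                ivs[i][0] = ivs[i][1] - k
            else:
                ivs[i][1] = ivs[i][0] + k
        out = [(s, e) for s, e in ivs]
        if any(s >= e for s, e in out):
            raise FusionBuildError(
                f"split offsets empty a fragment in {self.transcript.transcript_id}"
            )
        return out

    @property
    def donated_length(self) -> int:
        return sum(e - s for s, e in self.fragments)

    def coding_donated(self) -> int:
        """Donated bases falling inside the transcript's CDS."""
        t = self.transcript
        return sum(
            max(0, min(e, t.cds_end) - max(s, t.cds_start))
            for s, e in self.fragments
        )

    def coding_upstream(self) -> int:
        """Coding bases of the transcript strictly 5' of the first
        retained base (the downstream partner's codon-grid offset)."""
        t = self.transcript
        cds = [
            (max(s, t.cds_start), min(e, t.cds_end))
            for s, e in t.exons
        ]
        cds = [(s, e) for s, e in cds if s < e]
        frags = self.fragments
        if t.strand == "+":
            g0 = frags[0][0]
            return sum(max(0, min(e, g0) - s) for s, e in cds)
        g0 = frags[-1][1]
        return sum(max(0, e - max(s, g0)) for s, e in cds)


@dataclass
class TypeMixture:
    """Normalized categorical distribution over event classes."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        for cls, p in self.probabilities.items():
            if cls not in EVENT_CLASSES:
                raise ValueError(f"unknown event class {cls!r}")
            if p < 0:
                raise ValueError(f"negative probability for {cls}")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"event-class mixture sums to {total:.6g}, not 1 (normalize it)"
            )


#: CTX/ITX/DUP/DEL proportions among known cancer fusion events, as
#: catalogued in fusion databases such as ChimerDB.
CANCER_CATALOG_MIXTURE = TypeMixture(
    {"CTX": 0.883, "ITX": 0.048, "DUP": 0.055, "DEL": 0.014}
)


@dataclass
class FusionTranscript:
    """An ordered assembly of exon selections with junction metadata."""

    parts: list[ExonSelection]
    inserts: list[str]  # one per inter-part junction; "" = no insert
    arity_class: str
    event_class: str | None
    options: FusionOptions
    fusion_id: str = "fusion"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_genes = len({p.transcript.gene_id for p in self.parts})
        if ARITY_CLASSES[n_genes] != self.arity_class:
            raise FusionBuildError(
                f"arity_class {self.arity_class} inconsistent with "
                f"{n_genes} distinct genes"
            )
        if len(self.inserts) != len(self.parts) - 1:
            raise FusionBuildError("need exactly one insert slot per junction")


# ---------------------------------------------------------------------------
# exon-run selection and splitting
# ---------------------------------------------------------------------------

def effective_intervals(
    t: TranscriptModel, options: FusionOptions
) -> list[tuple[int, int]]:
    if options.cds_only:
        return coding_exon_intervals(t)  # raises for non-coding
    return t.exons


def choose_exon_run(
    t: TranscriptModel,
    role: str,
    options: FusionOptions,
    rng: np.random.Generator,
    max_n: int | None = None,
) -> ExonSelection:
    """Pick a contiguous run of n effective exons for the given role.

    ``five_prime`` takes the first n exons from the transcript's 5' end
    (strand-aware: genomically last exons for a minus-strand
    transcript), ``three_prime`` the last n through the 3' end,
    ``internal`` any contiguous run. n is uniform on [1, E], optionally
    capped by ``max_n`` so a partner selection stays non-empty.
    """
    ivs = effective_intervals(t, options)
    n_eff = len(ivs)
    hi = min(n_eff, max_n) if max_n else n_eff
    if hi < 1:
        raise FusionBuildError(
            f"choose_exon_run: {t.transcript_id} too small for role {role}"
        )
    n = int(rng.integers(1, hi + 1))
    minus = t.strand == "-"
    if role == "five_prime":
        first, last = (n_eff - n, n_eff - 1) if minus else (0, n - 1)
    elif role == "three_prime":
        first, last = (0, n - 1) if minus else (n_eff - n, n_eff - 1)
    elif role == "internal":
        start = int(rng.integers(0, n_eff - n + 1))
        first, last = start, start + n - 1
    else:
        raise ValueError(f"unknown role {role!r}")
    return ExonSelection(transcript=t, intervals=ivs, first=first, last=last, role=role)


def apply_split(
    sel: ExonSelection, options: FusionOptions, rng: np.random.Generator
) -> ExonSelection:
    """Draw random split offsets on the junction-side terminal exons.

    Five-prime parts split their transcript-3' terminal exon,
    three-prime parts their transcript-5' terminal exon, internal parts
    both. Offsets are uniform on [1, width - 1]; a width-1 exon cannot
    split and keeps the annotated boundary with a warning. Under
    keep_exon_boundary no offsets are set at all.
    """
    if not options.splitting:
        return sel
    minus = sel.transcript.strand == "-"
    run = sel.run_intervals

    def width(transcript_end: str) -> int:
        if transcript_end == "5p":
            s, e = run[-1] if minus else run[0]
        else:
            s, e = run[0] if minus else run[-1]
        return e - s

    def draw(w: int) -> int | None:
        if w < 2:
            warnings.warn("width-1 exon cannot be split; kept whole", stacklevel=2)
            return None
        return int(rng.integers(1, w))

    if sel.role in ("five_prime", "internal"):
        sel.split_offset_3p = draw(width("3p"))
    if sel.role in ("three_prime", "internal"):
        sel.split_offset_5p = draw(width("5p"))
    return sel


# ---------------------------------------------------------------------------
# reading-frame control
# ---------------------------------------------------------------------------

def junction_frame_shift(
    parts: Sequence[ExonSelection], inserts: Sequence[str | int], junction: int
) -> int:
    """Frame shift (mod 3) at junction ``junction`` (0-based).

    The translated length upstream of the junction is the 5' part's
    donated coding length (measured from its CDS start, UTR excluded)
    plus the full donated length of any intermediate parts and all
    intervening inserts. The shift is that length minus the downstream
    part's codon-grid offset, mod 3; 0 means the downstream CDS reads in
    its native frame.
    """
    upstream = parts[0].coding_donated()
    for j in range(junction):
        upstream += parts[j + 1].donated_length
    for j in range(junction + 1):
        ins = inserts[j]
        upstream += ins if isinstance(ins, int) else len(ins)
    downstream = parts[junction + 1].coding_upstream()
    return (upstream - downstream) % 3


def _try_offset_adjust(sel: ExonSelection, attr: str, delta: int) -> bool:
    """Shift a split offset by delta if the result stays strictly inside
    its exon; returns True on success."""
    cur = getattr(sel, attr)
    if cur is None:
        return False
    new = cur + delta
    minus = sel.transcript.strand == "-"
    run = sel.run_intervals
    if attr == "split_offset_5p":
        s, e = run[-1] if minus else run[0]
    else:
        s, e = run[0] if minus else run[-1]
    if not (1 <= new <= (e - s) - 1):
        return False
    setattr(sel, attr, new)
    try:
        _ = sel.fragments
    except FusionBuildError:
        setattr(sel, attr, cur)
        return False
    return True


def enforce_frame(
    sel5: ExonSelection,
    sel3: ExonSelection,
    mode: str,
    insert_length: int = 0,
) -> tuple[ExonSelection, ExonSelection]:
    """Adjust split offsets (by <= 2 bp) so the junction between two
    coding parts is in frame (``in_frame``) or deliberately out of frame
    (``out_of_frame``).

    Raises :class:`FrameError` when a part is non-coding (use
    ``unconstrained`` mode) or when no small adjustment can satisfy the
    constraint — e.g. in boundary mode, where offsets are unset and the
    caller must re-draw exon runs instead.
    """
    if mode == "unconstrained":
        return sel5, sel3
    for sel in (sel5, sel3):
        if not sel.transcript.is_coding:
            raise FrameError(
                f"enforce_frame: {sel.transcript.transcript_id} is non-coding; "
                "use frame_mode='unconstrained'"
            )

    def shift() -> int:
        return junction_frame_shift([sel5, sel3], [insert_length], 0)

    want_zero = mode == "in_frame"
    if (shift() == 0) == want_zero:
        return sel5, sel3
    # candidate bp adjustments on either side of the junction
    for attr, sel in (("split_offset_3p", sel5), ("split_offset_5p", sel3)):
        for delta in (1, -1, 2, -2):
            if _try_offset_adjust(sel, attr, delta):
                if (shift() == 0) == want_zero:
                    return sel5, sel3
                _try_offset_adjust(sel, attr, -delta)  # roll back
    raise FrameError(
        "enforce_frame: no <=2 bp split adjustment satisfies the frame "
        "constraint (boundary-mode junctions may need re-drawing)"
    )


# ---------------------------------------------------------------------------
# event-class taxonomy
# ---------------------------------------------------------------------------

def classify_fusion(
    a: TranscriptModel, b: TranscriptModel, models: GeneModelSet | None = None
) -> str:
    """Classify the two-gene event formed by fusing a (5') to b (3').

    Different chromosomes give CTX; same chromosome with opposite
    strands gives ITX; same strand gives DEL when the 5' gene lies
    transcriptionally upstream of the 3' gene and DUP otherwise. When a
    gene-model set is supplied, a DEL between adjacent genes (no
    annotated same-strand gene strictly between them) is refined to
    readthrough.
    """
    if a.transcript_id == b.transcript_id:
        raise FusionBuildError("classify_fusion: self fusions are not classified")
    if a.chrom != b.chrom:
        return "CTX"
    if a.strand != b.strand:
        return "ITX"
    if a.strand == "+":
        upstream = a.tx_start < b.tx_start
        gap = (a.tx_end, b.tx_start)
    else:
        upstream = a.tx_start > b.tx_start
        gap = (b.tx_end, a.tx_start)
    if not upstream:
        return "DUP"
    if models is not None and gap[0] < gap[1]:
        for t in models.by_chrom.get(a.chrom, []):
            if t.gene_id in (a.gene_id, b.gene_id) or t.strand != a.strand:
                continue
            if t.tx_start < gap[1] and t.tx_end > gap[0]:
                return "DEL"
        return "readthrough"
    if models is not None:
        return "readthrough"  # overlapping/adjacent spans, nothing between
    return "DEL"


def sample_event_class(mix: TypeMixture, rng: np.random.Generator) -> str:
    """Categorical draw of an event class from a normalized mixture."""
    classes = list(mix.probabilities)
    probs = np.array([mix.probabilities[c] for c in classes], dtype=float)
    probs = probs / probs.sum()  # exact renormalization of fp dust
    return classes[int(rng.choice(len(classes), p=probs))]


def generate_foreign_insert(length: int, rng: np.random.Generator) -> str:
    """Random i.i.d. uniform sequence over {A,C,G,T}."""
    if length < 1:
        raise ValueError("insert length must be >= 1")
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# fusion assembly
# ---------------------------------------------------------------------------

def pick_transcript(
    models: GeneModelSet,
    gene_id: str,
    options: FusionOptions,
    rng: np.random.Generator,
) -> TranscriptModel:
    """One transcript of a gene, uniformly at random; frame-constrained
    or CDS-only modes restrict the draw to coding transcripts."""
    candidates = models.by_gene.get(gene_id)
    if not candidates:
        raise FusionBuildError(f"gene {gene_id!r} not in model set")
    if options.cds_only or options.frame_mode != "unconstrained":
        coding = [t for t in candidates if t.is_coding]
        if not coding:
            raise FrameError(
                f"gene {gene_id} has no coding transcript; "
                "use frame_mode='unconstrained' without cds_only"
            )
        candidates = coding
    return candidates[int(rng.integers(len(candidates)))]


def _draw_parts(
    transcripts: list[TranscriptModel],
    options: FusionOptions,
    rng: np.random.Generator,
) -> list[ExonSelection]:
    if len(transcripts) == 1:  # self fusion: two non-overlapping runs
        t = transcripts[0]
        ivs = effective_intervals(t, options)
        n_eff = len(ivs)
        if n_eff < 2:
            raise FusionBuildError(
                f"self fusion needs >= 2 (effective) exons; "
                f"{t.transcript_id} has {n_eff}"
            )
        n1 = int(rng.integers(1, n_eff))  # leave >= 1 exon for the 3' run
        p1 = ExonSelection(
            transcript=t, intervals=ivs, role="five_prime",
            first=n_eff - n1 if t.strand == "-" else 0,
            last=n_eff - 1 if t.strand == "-" else n1 - 1,
        )
        n2 = int(rng.integers(1, n_eff - n1 + 1))
        p2 = ExonSelection(
            transcript=t, intervals=ivs, role="three_prime",
            first=0 if t.strand == "-" else n_eff - n2,
            last=n2 - 1 if t.strand == "-" else n_eff - 1,
        )
        parts = [p1, p2]
    elif len(transcripts) == 2:
        parts = [
            choose_exon_run(transcripts[0], "five_prime", options, rng),
            choose_exon_run(transcripts[1], "three_prime", options, rng),
        ]
    else:
        parts = [
            choose_exon_run(transcripts[0], "five_prime", options, rng),
            choose_exon_run(transcripts[1], "internal", options, rng),
            choose_exon_run(transcripts[2], "three_prime", options, rng),
        ]
    return [apply_split(p, options, rng) for p in parts]


def build_fusion(
    parts_genes: Sequence[str],
    models: GeneModelSet,
    options: FusionOptions,
    rng: np.random.Generator,
    event_class: str | None = None,
    transcripts: Sequence[TranscriptModel] | None = None,
    fusion_id: str = "fusion",
) -> FusionTranscript:
    """Build one fusion transcript from an ordered gene tuple.

    Composes exon-run selection, random splitting, frame enforcement
    and orientation correction. Self fusions (one gene) join two
    non-overlapping runs of a single transcript; hybrids order parts
    5'/3'; complex fusions 5'/internal/3'. When ``event_class`` is
    given the built pair must classify to it.
    """
    arity = len(parts_genes)
    if arity not in (1, 2, 3):
        raise FusionBuildError(f"fusion arity must be 1-3, got {arity}")
    if arity > 1 and len(set(parts_genes)) != arity:
        raise FusionBuildError(f"genes within a fusion must be distinct: {parts_genes}")

    if transcripts is None:
        transcripts = [pick_transcript(models, g, options, rng) for g in parts_genes]
    transcripts = list(transcripts)

    if options.cds_only or options.frame_mode != "unconstrained":
        for t in transcripts:
            if not t.is_coding:
                raise FrameError(
                    f"build_fusion: {t.transcript_id} is non-coding; "
                    "use frame_mode='unconstrained' without cds_only"
                )

    if arity >= 2:
        observed = classify_fusion(transcripts[0], transcripts[1], models)
        if event_class is not None and observed != event_class and not (
            event_class == "DEL" and observed == "readthrough"
        ):
            raise FusionBuildError(
                f"build_fusion: requested event class {event_class}, "
                f"gene pair classifies as {observed}"
            )
    else:
        observed = None

    last_err: Exception | None = None
    for _ in range(RETRY_CAP):
        try:
            parts = _draw_parts(transcripts, options, rng)
            inserts = [
                generate_foreign_insert(options.foreign_insert_length, rng)
                if options.foreign_insert_length > 0
                else ""
                for _ in range(len(parts) - 1)
            ]
            if options.frame_mode != "unconstrained":
                for j in range(len(parts) - 1):
                    # cumulative translated length seen by junction j
                    shift_now = junction_frame_shift(parts, inserts, j)
                    target_zero = options.frame_mode == "in_frame"
                    if (shift_now == 0) != target_zero:
                        _adjust_junction(parts, inserts, j, target_zero)
            break
        except FusionBuildError as exc:
            last_err = exc
            continue
    else:
        raise FusionBuildError(
            f"build_fusion: retry cap {RETRY_CAP} exceeded at breakpoint/frame "
            f"stage for genes {tuple(parts_genes)}: {last_err}"
        )

    if options.auto_correct_orientation:
        lead = parts[0].transcript.strand
        for p in parts[1:]:
            if p.transcript.strand != lead:
                p.reverse_complemented = True

    return FusionTranscript(
        parts=parts,
        inserts=inserts,
        arity_class=ARITY_CLASSES[len(set(parts_genes))],
        event_class=observed,
        options=options,
        fusion_id=fusion_id,
        provenance={
            "genes": tuple(parts_genes),
            "transcripts": tuple(t.transcript_id for t in transcripts),
        },
    )


def _adjust_junction(
    parts: list[ExonSelection],
    inserts: list[str],
    junction: int,
    want_zero: bool,
) -> None:
    """In-place <=2 bp split adjustment at one junction; raises
    FusionBuildError when no adjustment satisfies the constraint."""
    for sel in parts:
        if not sel.transcript.is_coding:
            raise FrameError(
                f"frame-constrained mode with non-coding "
                f"{sel.transcript.transcript_id}; use frame_mode='unconstrained'"
            )

    def ok() -> bool:
        return (junction_frame_shift(parts, inserts, junction) == 0) == want_zero

    up, down = parts[junction], parts[junction + 1]
    for attr, sel in (("split_offset_3p", up), ("split_offset_5p", down)):
        for delta in (1, -1, 2, -2):
            if _try_offset_adjust(sel, attr, delta):
                if ok():
                    return
                _try_offset_adjust(sel, attr, -delta)
    raise FrameError(
        f"junction {junction}: no <=2 bp adjustment satisfies the frame constraint"
    )


def assemble_sequence(f: FusionTranscript, ref: ReferenceGenome) -> str:
    """Raw fusion sequence: per part, fetch the split-adjusted fragments,
    concatenate in genomic order and reverse-complement the part when
    flagged; join parts with their junction inserts."""
    chunks = []
    for i, part in enumerate(f.parts):
        seq = "".join(
            ref.fetch(part.transcript.chrom, s, e) for s, e in part.fragments
        )
        if part.reverse_complemented:
            seq = reverse_complement(seq)
        chunks.append(seq)
        if i < len(f.parts) - 1 and f.inserts[i]:
            chunks.append(f.inserts[i])
    return "".join(chunks)


def part_lengths(f: FusionTranscript) -> list[int]:
    """Donated length per part (inserts excluded)."""
    return [p.donated_length for p in f.parts]
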