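"""Gene selection for fusions: mode dispatch, filters, arity handling.

Two modes exist. *random* draws genes uniformly from the gene model
(each gene weight 1/n). *background* draws from an expression profile
computed over background RNA-Seq alignments, by one of three methods:
uniform over genes passing the RPKM cutoff, empirical (histogram of
RPKM values) or binned (one gene per rank stratum, computed once per
batch of fusions). Per-slot filters pin individual fusion partners to
specific genes, e.g. a BCR-ABL1 style constraint on slots 1 and 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .expression import (
    DEFAULT_RPKM_CUTOFF,
    EmpiricalDistribution,
    ExpressionProfile,
    build_empirical_distribution,
    sample_gene_empirical,
    select_binned,
    select_uniform_expressed,
)
from .gene_models import GeneModelSet

logger = logging.getLogger(__name__)

RETRY_CAP = 1000


class SelectionError(RuntimeError):
    pass


@dataclass
class SelectionConfig:
    """How genes are picked for each fusion.

    ``mode`` is ``random`` (uniform over the gene model) or
    ``background`` (expression-weighted; requires a profile).
    ``method`` applies in background mode only: ``uniform``,
    ``empirical`` or ``binned``. ``slot_filters`` pins fusion slots
    1-3 to a gene/transcript/chrom match.
    """

    mode: str = "random"
    method: str = "uniform"
    rpkm_cutoff: float = DEFAULT_RPKM_CUTOFF
    limit: str | None = None
    slot_filters: tuple[str | None, str | None, str | None] = (None, None, None)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "background"):
            raise SelectionError(f"unknown mode {self.mode!r}")
        if self.method not in ("uniform", "empirical", "binned"):
            raise SelectionError(f"unknown method {self.method!r}")


def _slot_candidates(models: GeneModelSet, flt: str) -> list[str]:
    """Genes matching a slot filter on gene_id, transcript_id or chrom."""
    hits = []
    for gid, transcripts in models.by_gene.items():
        for t in transcripts:
            if flt in (t.gene_id, t.transcript_id, t.chrom):
                hits.append(gid)
                break
    if not hits:
        raise SelectionError(f"slot filter {flt!r} matches no gene")
    return hits


class GeneSelector:
    """Stateful selector: owns the (filtered) gene universe and, in
    background mode, the empirical distribution or binned schedule."""

    def __init__(
        self,
        cfg: SelectionConfig,
        models: GeneModelSet,
        profile: ExpressionProfile | None = None,
        n_fusions: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.cfg = cfg
        self.models = models
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self._dist: EmpiricalDistribution | None = None
        self._binned_queue: list[str] = []
        self.profile = None

        if cfg.mode == "background":
            if profile is None:
                raise SelectionError("background mode requires an expression profile")
            # keep only profiled genes present in the (possibly limited) model
            keep = {g: x for g, x in profile.genes.items() if g in models.by_gene}
            if not keep:
                raise SelectionError("no profiled gene is present in the gene model")
            self.profile = ExpressionProfile(
                genes=keep, total_mapped_reads=profile.total_mapped_reads
            )
            if cfg.method == "empirical":
                self._dist = build_empirical_distribution(self.profile)
            elif cfg.method == "binned":
                if n_fusions is None:
                    raise SelectionError("binned method needs the fusion count up front")
                # one gene per rank stratum, computed once per batch
                self._binned_queue = select_binned(self.profile, n_fusions, self.rng)

    # -- single-slot draws ------------------------------------------------
    def _draw_unfiltered(self, slot: int) -> str:
        cfg = self.cfg
        if cfg.mode == "random":
            gids = self.models.gene_ids
            return gids[int(self.rng.integers(len(gids)))]
        if cfg.method == "empirical":
            return sample_gene_empirical(self._dist, self.rng)
        if cfg.method == "binned":
            if slot == 0 and self._binned_queue:
                return self._binned_queue.pop(0)
            # slot-2/3 partners (and any overflow): uniform over profile
            return select_uniform_expressed(self.profile, self.rng)
        return select_uniform_expressed(self.profile, self.rng)

    def _draw_slot(self, slot: int, flt: str | None, taken: set[str]) -> str:
        if flt is not None:
            candidates = [g for g in _slot_candidates(self.models, flt) if g not in taken]
            if self.profile is not None:
                candidates = [g for g in candidates if g in self.profile.genes]
            if not candidates:
                raise SelectionError(
                    f"slot filter {flt!r}: no eligible gene (already used, "
                    "or below the RPKM cutoff)"
                )
            return candidates[int(self.rng.integers(len(candidates)))]
        for _ in range(RETRY_CAP):
            g = self._draw_unfiltered(slot)
            if g not in taken:
                return g
        raise SelectionError(
            f"retry cap {RETRY_CAP} exceeded drawing a distinct partner gene"
        )

    # -- public API -------------------------------------------------------
    def select_fusion_genes(self, arity: int) -> tuple[str, ...]:
        """Gene ids for one fusion: ``arity`` slots, distinct unless
        arity == 1, each honoring its slot filter if set."""
        if arity not in (1, 2, 3):
            raise SelectionError(f"arity must be 1-3, got {arity}")
        filters = self.cfg.slot_filters
        for extra in filters[arity:]:
            if extra is not None:
                warnings.warn(
                    f"slot filter {extra!r} beyond fusion arity {arity} ignored",
                    stacklevel=2,
                )
        out: list[str] = []
        taken: set[str] = set()
        for i in range(arity):
            g = self._draw_slot(i, filters[i], taken)
            out.append(g)
            if arity > 1:
                taken.add(g)
        return tuple(out)


def select_fusion_genes(
    cfg: SelectionConfig,
    models: GeneModelSet,
    profile: ExpressionProfile | None,
    arity: int,
    rng: np.random.Generator,
    n_fusions: int | None = None,
) -> tuple[str, ...]:
    """One-shot convenience wrapper around :class:`GeneSelector`."""
    return GeneSelector(cfg, models, profile, n_fusions=n_fusions, rng=rng).select_fusion_genes(arity)
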