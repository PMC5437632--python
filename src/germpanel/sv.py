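"""Breakpoint refinement of coverage-derived CNV segments using SV evidence.

Coverage ratios resolve CNVs only to exon granularity; paired-end/split-read
structural-variant records carry base-pair breakpoints. A CNV segment is
matched to the same-direction SV (DEL for losses, DUP for gains) with
maximal reciprocal overlap against the segment's genomic exon span; matched
segments gain refined breakpoint coordinates and a human-readable note
locating each breakpoint within the gene's exon/intron anatomy (the
"starting in the middle of exon 10" description a clinical report wants).
Translocations and inversions are outside the assay's validated scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .cnv import GAIN, LOSS, CnvSegment
from .panel import GenePanel

MIN_SUPPORT_DEFAULT = 3
RECIPROCAL_OVERLAP_DEFAULT = 0.5

SV_DEL = "DEL"
SV_DUP = "DUP"
_DIRECTION_FOR = {SV_DEL: LOSS, SV_DUP: GAIN}


class SvError(ValueError):
    pass


@dataclass(frozen=True)
class SvRecord:
    """A deletion or duplication interval with read-pair/split-read support."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    sv_type: str
    support: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SvError(f"SV start {self.start} >= end {self.end}")
        if self.sv_type not in (SV_DEL, SV_DUP):
            raise SvError(
                f"sv_type must be DEL or DUP (translocations/inversions are "
                f"out of scope), got {self.sv_type!r}"
            )
        if self.support < 0:
            raise SvError("support must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RefinedCnv:
    """A CNV segment with optional SV-derived breakpoints.

    Refinement never alters the base segment's direction, scope, fold
    change or p-value; it only adds coordinates and a boundary note.
    """

    base: CnvSegment
    refined_start: Optional[int] = None
    refined_end: Optional[int] = None
    boundary_note: Optional[str] = None

    @property
    def refined(self) -> bool:
        return self.refined_start is not None


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|) for two half-open intervals."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _boundary_note(panel: GenePanel, segment: CnvSegment, sv: SvRecord) -> str:
    """Describe breakpoints in transcript orientation.

    The transcript-5' breakpoint is reported as the start; for minus-strand
    genes that is the genomically rightmost coordinate.
    """
    strand = panel.gene_regions(segment.gene)[0].strand
    left = panel.locate(segment.gene, sv.start)
    right = panel.locate(segment.gene, sv.end - 1)
    first, second = (left, right) if strand == "+" else (right, left)
    return f"starts {first}; ends {second}"


def reconcile(
    segments: Iterable[CnvSegment],
    svs: Iterable[SvRecord],
    panel: GenePanel,
    min_support: int = MIN_SUPPORT_DEFAULT,
    min_reciprocal_overlap: float = RECIPROCAL_OVERLAP_DEFAULT,
) -> list[RefinedCnv]:
    """Attach SV breakpoints to coverage CNV segments.

    Each segment independently takes the same-direction SV with the highest
    reciprocal overlap (>= ``min_reciprocal_overlap``) against the genomic
    interval of its exon span; SVs below ``min_support`` are ignored. Ties
    break by higher support, then smaller SV interval, then leftmost start,
    so the result is deterministic under input permutation. Unmatched
    segments pass through unrefined.
    """
    svs = [s for s in svs if s.support >= min_support]
    out: list[RefinedCnv] = []
    for seg in segments:
        chrom, span_start, span_end = panel.span(
            seg.gene, seg.first_exon, seg.last_exon
        )
        best: Optional[SvRecord] = None
        best_ov = 0.0
        for sv in svs:
            if sv.chrom != chrom or _DIRECTION_FOR[sv.sv_type] != seg.direction:
                continue
            ov = reciprocal_overlap((span_start, span_end), (sv.start, sv.end))
            if ov < min_reciprocal_overlap:
                continue
            if best is None or (ov, sv.support, -sv.length, -sv.start) > (
                best_ov, best.support, -best.length, -best.start
            ):
                best, best_ov = sv, ov
        if best is None:
            out.append(RefinedCnv(base=seg))
        else:
            out.append(
                RefinedCnv(
                    base=seg,
                    refined_start=best.start,
                    refined_end=best.end,
                    boundary_note=_boundary_note(panel, seg, best),
                )
            )
    return out
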