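"""Targeted-panel model: genes, exons and their flanking intronic regions.

The panel is the coordinate ground truth for every downstream computation.
Coordinates are 0-based half-open internally (BED-native); 1-based
coordinates appear only at VCF-facing boundaries.

A *flank* is the intronic sequence within ``flank_bp`` of an exon boundary.
Capture baits tile exon edges, so flanks are covered incidentally and are
eligible for splice-region variant calls. In short introns a full-width
flank from each neighbouring exon would overlap; we truncate both flanks at
the intron midpoint so every intronic position maps to at most one exon's
flank (the upstream exon takes the extra base of an odd-length intron).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

EXONIC = "exonic"
NONCODING_FLANK = "noncoding_flank"
OFF_TARGET = "off_target"


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True, order=True)
class TargetRegion:
    """One exon interval of a canonical transcript.

    ``start``/``end`` are 0-based half-open; ``exon_index`` is the 1-based
    ordinal within the gene's canonical transcript (for minus-strand genes
    the ordinal therefore *decreases* with genomic position).
    """

    chrom: str
    start: int
    end: int
    gene: str
    exon_index: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"exon {self.gene}_exon{self.exon_index}: start {self.start} "
                f">= end {self.end}"
            )
        if self.exon_index < 1:
            raise PanelError(f"exon_index must be >= 1, got {self.exon_index}")
        if self.strand not in ("+", "-"):
            raise PanelError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.gene}_exon{self.exon_index}"


@dataclass
class GenePanel:
    """An ordered collection of exon targets plus the flank convention."""

    regions: list[TargetRegion]
    flank_bp: int = 50
    _flanks: list[tuple[str, int, int, TargetRegion]] = field(
        default_factory=list, repr=False
    )
    _warned_chroms: set[str] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise PanelError(f"flank_bp must be >= 0, got {self.flank_bp}")
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        self._validate()
        self._flanks = self._build_flanks()

    def _validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        strands: dict[str, str] = {}
        for r in self.regions:
            key = (r.gene, r.exon_index)
            if key in seen:
                raise PanelError(f"duplicate exon {r.gene}_exon{r.exon_index}")
            seen.add(key)
            if r.gene in strands and strands[r.gene] != r.strand:
                raise PanelError(f"gene {r.gene} has mixed strands")
            strands[r.gene] = r.strand
        # within one gene, exon intervals must not overlap
        by_gene: dict[str, list[TargetRegion]] = {}
        for r in self.regions:
            by_gene.setdefault(r.gene, []).append(r)
        for gene, regs in by_gene.items():
            regs = sorted(regs, key=lambda r: (r.chrom, r.start))
            for a, b in zip(regs, regs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise PanelError(f"gene {gene}: overlapping exons {a.name}, {b.name}")

    def _build_flanks(self) -> list[tuple[str, int, int, TargetRegion]]:
        """Flank intervals as (chrom, start, end, owner-exon) tuples.

        Flanks of the same gene truncate at the intron midpoint; flanks never
        extend into *any* exon of the panel (exonic class wins regardless).
        """
        flanks: list[tuple[str, int, int, TargetRegion]] = []
        if self.flank_bp == 0:
            return flanks
        by_gene: dict[str, list[TargetRegion]] = {}
        for r in self.regions:
            by_gene.setdefault(r.gene, []).append(r)
        for regs in by_gene.values():
            regs = sorted(regs, key=lambda r: (r.chrom, r.start))
            for i, r in enumerate(regs):
                # upstream (genomic-left) flank
                left_limit = r.start - self.flank_bp
                if i > 0 and regs[i - 1].chrom == r.chrom:
                    gap = r.start - regs[i - 1].end
                    # downstream neighbour keeps ceil(gap/2); this exon floor
                    left_limit = max(left_limit, r.start - gap // 2)
                if left_limit < r.start:
                    flanks.append((r.chrom, left_limit, r.start, r))
                # downstream (genomic-right) flank
                right_limit = r.end + self.flank_bp
                if i + 1 < len(regs) and regs[i + 1].chrom == r.chrom:
                    gap = regs[i + 1].start - r.end
                    right_limit = min(right_limit, r.end + (gap + 1) // 2)
                if right_limit > r.end:
                    flanks.append((r.chrom, r.end, right_limit, r))
        return flanks

    # -- queries ---------------------------------------------------------

    def __iter__(self) -> Iterator[TargetRegion]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for r in self.regions:
            if r.gene not in out:
                out.append(r.gene)
        return out

    def gene_regions(self, gene: str) -> list[TargetRegion]:
        regs = [r for r in self.regions if r.gene == gene]
        if not regs:
            raise PanelError(f"unknown gene {gene!r}")
        return sorted(regs, key=lambda r: r.exon_index)

    def exon(self, gene: str, exon_index: int) -> TargetRegion:
        for r in self.regions:
            if r.gene == gene and r.exon_index == exon_index:
                return r
        raise PanelError(f"unknown exon {gene}_exon{exon_index}")

    def flank_intervals(self) -> list[tuple[str, int, int, TargetRegion]]:
        """Truncated flank intervals, each owned by exactly one exon."""
        return list(self._flanks)

    def classify_position(self, chrom: str, pos: int) -> str:
        """Region class of a 0-based position.

        Exonic beats flank; an unknown chromosome is simply off-target
        (logged once, not an error).
        """
        known = any(r.chrom == chrom for r in self.regions)
        if not known:
            if chrom not in self._warned_chroms:
                self._warned_chroms.add(chrom)
                logger.warning("chromosome %r not in panel; classifying off_target", chrom)
            return OFF_TARGET
        for r in self.regions:
            if r.chrom == chrom and r.start <= pos < r.end:
                return EXONIC
        for fchrom, fstart, fend, _ in self._flanks:
            if fchrom == chrom and fstart <= pos < fend:
                return NONCODING_FLANK
        return OFF_TARGET

    def locate(self, gene: str, pos: int) -> str:
        """Describe a position relative to a gene's exon/intron anatomy.

        Returns text such as ``"within exon 10"`` or
        ``"in the intron between exons 17 and 18 (5' of exon 18)"``.
        Intron descriptions follow transcript orientation: for a
        minus-strand gene the 5'-adjacent exon is the genomically left
        neighbour's transcript successor.
        """
        regs = sorted(self.gene_regions(gene), key=lambda r: r.start)
        for r in regs:
            if r.start <= pos < r.end:
                return f"within exon {r.exon_index}"
        for a, b in zip(regs, regs[1:]):
            if a.end <= pos < b.start:
                # transcript order: lower exon_index is 5'
                first, second = sorted((a, b), key=lambda r: r.exon_index)
                return (
                    f"in the intron between exons {first.exon_index} and "
                    f"{second.exon_index} (5' of exon {second.exon_index})"
                )
        if pos < regs[0].start:
            side = "upstream" if regs[0].strand == "+" else "downstream"
            return f"{side} of {gene}"
        side = "downstream" if regs[0].strand == "+" else "upstream"
        return f"{side} of {gene}"

    def span(self, gene: str, first_exon: int, last_exon: int) -> tuple[str, int, int]:
        """Genomic interval covered by an inclusive exon-ordinal span."""
        regs = [
            r
            for r in self.gene_regions(gene)
            if first_exon <= r.exon_index <= last_exon
        ]
        if not regs:
            raise PanelError(f"{gene}: no exons in span {first_exon}-{last_exon}")
        return regs[0].chrom, min(r.start for r in regs), max(r.end for r in regs)


def _parse_name(name: str, lineno: int) -> tuple[str, int]:
    gene, sep, tail = name.rpartition("_exon")
    if not sep or not gene:
        raise PanelError(
            f"line {lineno}: name field {name!r} does not match 'GENE_exonN'"
        )
    try:
        idx = int(tail)
    except ValueError:
        raise PanelError(
            f"line {lineno}: exon ordinal in {name!r} is not an integer"
        ) from None
    return gene, idx


def load_panel(bed_path: str | Path, flank_bp: int = 50) -> GenePanel:
    """Load a panel from a 4+-column BED whose name field is ``GENE_exonN``.

    Column 6, when present, is the strand. Malformed lines raise
    :class:`PanelError` citing the offending line number.
    """
    bed_path = Path(bed_path)
    regions: list[TargetRegion] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(f"line {lineno}: expected >= 4 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise PanelError(f"line {lineno}: non-integer coordinates") from None
            gene, exon_index = _parse_name(fields[3], lineno)
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            try:
                regions.append(
                    TargetRegion(chrom, start, end, gene, exon_index, strand)
                )
            except PanelError as exc:
                raise PanelError(f"line {lineno}: {exc}") from None
    return GenePanel(regions=regions, flank_bp=flank_bp)


def write_panel(panel: GenePanel, bed_path: str | Path) -> None:
    """Write a panel back to 6-column BED (inverse of :func:`load_panel`)."""
    with open(bed_path, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


def classify_position(panel: GenePanel, chrom: str, pos: int) -> str:
    """Module-level alias for :meth:`GenePanel.classify_position`."""
    return panel.classify_position(chrom, pos)


def panel_summary(panel: GenePanel) -> list[dict]:
    """Per-gene summary rows: gene, n_exons, total_bp."""
    rows = []
    for gene in panel.genes:
        regs = panel.gene_regions(gene)
        rows.append(
            {
                "gene": gene,
                "n_exons": len(regs),
                "total_bp": sum(r.length for r in regs),
            }
        )
    return rows
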