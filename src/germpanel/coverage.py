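"""Per-exon and per-flank coverage statistics.

Assay validity rests on the *minimum* per-position depth of an exon, not its
mean: a variant at a single poorly covered base is a variant missed. Exons
are therefore judged on the lowest depth across all of their positions
(missing positions count as depth 0, the conservative reading), and exons
that fail the minimum-depth rule in most reference samples are excluded
from copy-number analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import GenePanel

MIN_DEPTH_DEFAULT = 50

DEPTH_COLUMNS = ["sample_id", "chrom", "pos", "depth"]


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class ExonCoverageStat:
    gene: str
    exon_index: int
    mean_depth: float
    min_depth: int
    passes_min: bool


def _depth_lookup(depths: pd.DataFrame, sample_id: str) -> dict[tuple[str, int], int]:
    sub = depths[depths["sample_id"] == sample_id]
    if sub.empty:
        raise CoverageError(f"sample {sample_id!r} absent from depth table")
    if sub.duplicated(subset=["chrom", "pos"]).any():
        dup = sub[sub.duplicated(subset=["chrom", "pos"], keep=False)].iloc[0]
        raise CoverageError(
            f"duplicate depth row for sample {sample_id!r} at "
            f"{dup['chrom']}:{dup['pos']} — ambiguous input"
        )
    if (sub["depth"] < 0).any():
        raise CoverageError("negative depth values")
    return {
        (c, int(p)): int(d)
        for c, p, d in zip(sub["chrom"], sub["pos"], sub["depth"])
    }


def exon_coverage(
    panel: GenePanel,
    depths: pd.DataFrame,
    sample_id: str,
    min_depth: int = MIN_DEPTH_DEFAULT,
) -> list[ExonCoverageStat]:
    """Mean and minimum depth over every exonic position of each exon.

    ``depths`` is a long table with columns sample_id, chrom, pos (0-based),
    depth. Positions absent from the table are implicit zeros.
    """
    lookup = _depth_lookup(depths, sample_id)
    stats = []
    for region in panel:
        vals = np.array(
            [lookup.get((region.chrom, p), 0) for p in range(region.start, region.end)],
            dtype=float,
        )
        mn = int(vals.min())
        stats.append(
            ExonCoverageStat(
                gene=region.gene,
                exon_index=region.exon_index,
                mean_depth=float(vals.mean()),
                min_depth=mn,
                passes_min=mn >= min_depth,
            )
        )
    return stats


def flag_failing_exons(
    stats: Iterable[ExonCoverageStat], min_depth: int = MIN_DEPTH_DEFAULT
) -> list[tuple[str, int]]:
    """Exons whose minimum position depth falls below ``min_depth``."""
    stats = list(stats)
    if not stats:
        raise CoverageError("empty coverage statistics")
    return [(s.gene, s.exon_index) for s in stats if s.min_depth < min_depth]


def consistently_failing_exons(
    panel: GenePanel,
    depths: pd.DataFrame,
    sample_ids: Iterable[str],
    min_depth: int = MIN_DEPTH_DEFAULT,
    fail_fraction: float = 0.5,
) -> list[tuple[str, int]]:
    """Exons failing the minimum rule in more than ``fail_fraction`` of samples.

    These are the "consistently poorly performing" targets to exclude from
    copy-number calling.
    """
    sample_ids = list(sample_ids)
    counts: dict[tuple[str, int], int] = {}
    for sid in sample_ids:
        for gene, idx in flag_failing_exons(exon_coverage(panel, depths, sid), min_depth):
            counts[(gene, idx)] = counts.get((gene, idx), 0) + 1
    cutoff = fail_fraction * len(sample_ids)
    return sorted(k for k, n in counts.items() if n > cutoff)


def flank_coverage_profile(
    panel: GenePanel,
    depths: pd.DataFrame,
    sample_id: str,
    max_flank: int = 200,
    min_depth: int = MIN_DEPTH_DEFAULT,
) -> pd.DataFrame:
    """Coverage decay with distance from the exon-intron boundary.

    For each distance d = 1..max_flank the profile reports the mean depth
    over all positions exactly d bp outside an exon boundary, and the
    fraction of flank regions of size d (one per exon side) whose minimum
    depth over distances 1..d is at least ``min_depth``. Positions that fall
    inside another exon are not intronic and are excluded.

    Returns a DataFrame with columns distance, mean_depth,
    fraction_ge_min.
    """
    if max_flank < 1:
        raise CoverageError(f"max_flank must be >= 1, got {max_flank}")
    lookup = _depth_lookup(depths, sample_id)
    exonic: set[tuple[str, int]] = set()
    for r in panel:
        for p in range(r.start, r.end):
            exonic.add((r.chrom, p))

    # one flank region per exon side; rows: region, cols: distance 1..max
    n_regions = 2 * len(panel)
    depth_at = np.full((n_regions, max_flank), np.nan)
    for i, r in enumerate(panel):
        for d in range(1, max_flank + 1):
            left = (r.chrom, r.start - d)
            if left not in exonic:
                depth_at[2 * i, d - 1] = lookup.get(left, 0)
            right = (r.chrom, r.end - 1 + d)
            if right not in exonic:
                depth_at[2 * i + 1, d - 1] = lookup.get(right, 0)

    rows = []
    running_min = np.full(n_regions, np.inf)
    for d in range(1, max_flank + 1):
        col = depth_at[:, d - 1]
        valid = ~np.isnan(col)
        mean_depth = float(col[valid].mean()) if valid.any() else float("nan")
        running_min = np.where(valid, np.minimum(running_min, col), running_min)
        # a region with no intronic positions at all stays inf -> counts pass
        frac = float((running_min >= min_depth).mean())
        rows.append(
            {"distance": d, "mean_depth": mean_depth, "fraction_ge_min": frac}
        )
    return pd.DataFrame(rows)


def coverage_report(stats: Iterable[ExonCoverageStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "exon_index": s.exon_index,
                "mean_depth": s.mean_depth,
                "min_depth": s.min_depth,
                "passes_min": s.passes_min,
            }
            for s in stats
        ]
    )
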