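"""Exon-level germline CNV calling against a pool of reference diploid normals.

The model: per-exon mean read depth, library-size normalized per sample so a
diploid sample centers at 1.0, ratioed against the mean of the reference
normals. A heterozygous deletion halves coverage (ratio 0.5), a single-copy
gain raises it to 1.5. Fold change uses the signed-reciprocal convention
(ratio for gains, -1/ratio for losses) so a het deletion sits at -2.0.

An exon is called significant when fold change > 1.3 with p < 0.05 (gain)
or fold change < -1.7 with p < 0.05 (loss); p-values come from a two-sided
one-sample z-test of the test sample's log2 value against the reference
pool's per-exon log2 distribution, with a standard-deviation floor of 0.05
on the log2 scale. Maximal runs of consecutive same-direction significant
exons within one gene become segments; a run spanning every callable exon
is a whole-gene event, anything shorter intragenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

GAIN_FC_DEFAULT = 1.3
LOSS_FC_DEFAULT = -1.7
ALPHA_DEFAULT = 0.05
LOG2_SD_FLOOR = 0.05

ROLE_TEST = "test"
ROLE_REFERENCE = "reference_normal"

GAIN = "gain"
LOSS = "loss"
WHOLE_GENE = "whole_gene"
INTRAGENIC = "intragenic"


class CnvError(ValueError):
    pass


@dataclass
class DepthMatrix:
    """Samples x exons mean read depth with per-sample roles.

    ``values``: DataFrame indexed by (gene, exon_index) MultiIndex, one
    column per sample. ``roles`` maps sample id to "test" or
    "reference_normal".
    """

    values: pd.DataFrame
    roles: dict[str, str]
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise CnvError("negative depth values")
        unknown = set(self.values.columns) - set(self.roles)
        if unknown:
            raise CnvError(f"samples without role: {sorted(unknown)}")
        bad = set(self.roles.values()) - {ROLE_TEST, ROLE_REFERENCE}
        if bad:
            raise CnvError(f"unknown roles: {sorted(bad)}")

    @property
    def reference_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.roles[s] == ROLE_REFERENCE]

    @property
    def test_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.roles[s] == ROLE_TEST]

    def drop_exons(self, exons: Iterable[tuple[str, int]]) -> "DepthMatrix":
        keep = [idx for idx in self.values.index if tuple(idx) not in set(exons)]
        return DepthMatrix(self.values.loc[keep], dict(self.roles), self.normalized)


@dataclass(frozen=True)
class ExonRatio:
    gene: str
    exon_index: int
    ratio: float
    log2_ratio: float
    fold_change: float
    p_value: float


@dataclass(frozen=True)
class CnvSegment:
    gene: str
    first_exon: int
    last_exon: int
    direction: str
    scope: str
    mean_fold_change: float
    combined_p: float
    sample_id: Optional[str] = None

    @property
    def exon_span(self) -> tuple[int, int]:
        return (self.first_exon, self.last_exon)


def signed_fold_change(ratio: float) -> float:
    """Signed-reciprocal fold change: ratio if >= 1, else -1/ratio."""
    if ratio <= 0:
        raise CnvError(f"ratio must be positive, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def normalize(matrix: DepthMatrix) -> DepthMatrix:
    """Library-size normalization: divide each sample by its own exon median.

    Calls become invariant to any per-sample scale factor (sequencing
    yield). The median, not the mean, is the scale estimator: a real CNV
    spanning many exons would drag a mean-based size factor toward itself
    and bias every other exon's ratio, whereas the median stays anchored on
    the diploid majority of the panel.
    """
    if matrix.values.mean(axis=0).le(0).any():
        dead = list(matrix.values.columns[matrix.values.mean(axis=0) <= 0])
        raise CnvError(f"sample(s) with zero total depth: {dead}")
    scale = matrix.values.median(axis=0)
    scale = scale.where(scale > 0, matrix.values.mean(axis=0))
    return DepthMatrix(matrix.values / scale, dict(matrix.roles), normalized=True)


def exon_ratios(matrix: DepthMatrix, test_sample: str) -> list[ExonRatio]:
    """Per-exon coverage ratio and z-test p-value for one test sample.

    Requires at least 2 reference normals (warns below 10). Exons where the
    reference pool mean is zero are uncallable and excluded.
    """
    if not matrix.normalized:
        matrix = normalize(matrix)
    refs = matrix.reference_samples
    if len(refs) < 2:
        raise CnvError(f"need >= 2 reference normals, have {len(refs)}")
    if len(refs) < 10:
        logger.warning("only %d reference normals; significance will be unstable",
                       len(refs))
    if test_sample not in matrix.values.columns:
        raise CnvError(f"unknown test sample {test_sample!r}")

    ref_vals = matrix.values[refs].to_numpy(dtype=float)
    test_vals = matrix.values[test_sample].to_numpy(dtype=float)
    out: list[ExonRatio] = []
    for i, (gene, exon_index) in enumerate(matrix.values.index):
        refs_i = ref_vals[i]
        ref_mean = refs_i.mean()
        if ref_mean <= 0 or (refs_i <= 0).any() or test_vals[i] <= 0:
            logger.warning("exon %s_exon%d uncallable (zero coverage)", gene, exon_index)
            continue
        ratio = test_vals[i] / ref_mean
        log2_ratio = float(np.log2(ratio))
        log2_refs = np.log2(refs_i / ref_mean)
        sd = max(float(np.std(log2_refs, ddof=1)), LOG2_SD_FLOOR)
        z = float(np.log2(test_vals[i]) - np.mean(np.log2(refs_i))) / sd
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        out.append(
            ExonRatio(
                gene=gene,
                exon_index=int(exon_index),
                ratio=float(ratio),
                log2_ratio=log2_ratio,
                fold_change=signed_fold_change(float(ratio)),
                p_value=p,
            )
        )
    return out


def _significant_direction(
    r: ExonRatio, gain_fc: float, loss_fc: float, alpha: float
) -> Optional[str]:
    if r.fold_change > gain_fc and r.p_value < alpha:
        return GAIN
    if r.fold_change < loss_fc and r.p_value < alpha:
        return LOSS
    return None


def call_segments(
    ratios: Sequence[ExonRatio],
    gain_fc: float = GAIN_FC_DEFAULT,
    loss_fc: float = LOSS_FC_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    sample_id: Optional[str] = None,
) -> list[CnvSegment]:
    """Segment significant exons into whole-gene and intragenic CNV events.

    Within each gene, maximal runs of consecutive (by callable-exon order)
    same-direction significant exons form segments; one intervening
    non-significant exon splits a run. combined_p is Fisher's combination
    of the member exons' p-values, reported for ranking only.
    """
    segments: list[CnvSegment] = []
    by_gene: dict[str, list[ExonRatio]] = {}
    for r in ratios:
        by_gene.setdefault(r.gene, []).append(r)
    for gene, gene_ratios in by_gene.items():
        gene_ratios = sorted(gene_ratios, key=lambda r: r.exon_index)
        n_callable = len(gene_ratios)
        run: list[ExonRatio] = []
        run_dir: Optional[str] = None

        def flush() -> None:
            nonlocal run, run_dir
            if run:
                _, combined_p = sps.combine_pvalues([r.p_value for r in run],
                                                    method="fisher")
                segments.append(
                    CnvSegment(
                        gene=gene,
                        first_exon=run[0].exon_index,
                        last_exon=run[-1].exon_index,
                        direction=run_dir,
                        scope=WHOLE_GENE if len(run) == n_callable else INTRAGENIC,
                        mean_fold_change=float(np.mean([r.fold_change for r in run])),
                        combined_p=float(combined_p),
                        sample_id=sample_id,
                    )
                )
            run, run_dir = [], None

        for r in gene_ratios:
            direction = _significant_direction(r, gain_fc, loss_fc, alpha)
            if direction is None:
                flush()
            elif direction == run_dir:
                run.append(r)
            else:
                flush()
                run, run_dir = [r], direction
        flush()
    return segments


def call_sample(
    matrix: DepthMatrix,
    test_sample: str,
    gain_fc: float = GAIN_FC_DEFAULT,
    loss_fc: float = LOSS_FC_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> list[CnvSegment]:
    """Normalize, ratio and segment in one step for a single test sample."""
    ratios = exon_ratios(matrix, test_sample)
    return call_segments(ratios, gain_fc, loss_fc, alpha, sample_id=test_sample)


def ratios_frame(ratios: Iterable[ExonRatio]) -> pd.DataFrame:
    """Per-exon ratio table for plotting (log2 ratio vs. region index)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "exon_index": r.exon_index,
                "ratio": r.ratio,
                "log2_ratio": r.log2_ratio,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
            }
            for r in ratios
        ]
    )


def segments_frame(segments: Iterable[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "gene": s.gene,
                "first_exon": s.first_exon,
                "last_exon": s.last_exon,
                "direction": s.direction,
                "scope": s.scope,
                "mean_fold_change": s.mean_fold_change,
                "combined_p": s.combined_p,
            }
            for s in segments
        ],
        columns=[
            "sample_id", "gene", "first_exon", "last_exon",
            "direction", "scope", "mean_fold_change", "combined_p",
        ],
    )
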