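"""Assay-validation statistics: detection power, noise thresholds, concordance.

Three computations underpin the analytic validation of the panel:

* **Detection power.** A heterozygous variant at depth ``d`` is detected
  when the observed alt-read fraction clears the exonic filter threshold.
  With alt reads binomially distributed, sensitivity is the exact upper
  binomial tail P(X >= ceil(t*d)) — computed exactly, never by normal
  approximation, because the depths of interest are small (17X covers a
  heterozygous variant with 99% sensitivity at a 20% threshold).

* **False-positive thresholds.** Replicates of control samples identify
  noise: a call present in *all* replicates of its control is reproducible;
  anything else is an artifact. Sweeping candidate DP/VF thresholds counts
  the artifacts that survive — the validated thresholds (50X, 20% exonic /
  25% noncoding) should leave none.

* **Replicate concordance.** Pairwise Jaccard of normalized variant keys
  per region class across intra- and inter-run replicates; discordant
  calls are cross-checked against the borderline flag, since calls that
  barely pass filtering explain most replicate-to-replicate differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import EXONIC, NONCODING_FLANK
from .variants import (
    DP_MIN_DEFAULT,
    VF_EXONIC_DEFAULT,
    VF_NONCODING_DEFAULT,
    VariantCall,
    flag_borderline,
)

logger = logging.getLogger(__name__)

INTRA_RUN = "intra_run"
INTER_RUN = "inter_run"


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PowerSpec:
    depth: int
    true_vf: float
    vf_threshold: float
    sensitivity: float


@dataclass
class ReplicateSet:
    """Filtered call sets from replicate libraries of one sample."""

    sample_id: str
    replicates: list[list[VariantCall]]
    run_labels: list[str]
    barcode_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise ValidationError("need >= 2 replicates")
        if len(self.run_labels) != len(self.replicates):
            raise ValidationError("one run label per replicate required")
        if not self.barcode_labels:
            self.barcode_labels = [f"BC{i+1}" for i in range(len(self.replicates))]

    @property
    def design(self) -> str:
        return INTRA_RUN if len(set(self.run_labels)) == 1 else INTER_RUN


def _alt_reads_required(depth: int, vf_threshold: float) -> int:
    """Smallest alt-read count k with k/depth >= vf_threshold."""
    k = math.ceil(vf_threshold * depth - 1e-9)
    return max(k, 0)


def detection_power(depth: int, true_vf: float, vf_threshold: float) -> float:
    """Exact binomial sensitivity of the VF-threshold detection rule.

    P(X >= ceil(vf_threshold * depth)) with X ~ Binomial(depth, true_vf).
    """
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if not (0.0 < true_vf <= 1.0):
        raise ValidationError(f"true_vf {true_vf} outside (0, 1]")
    if not (0.0 < vf_threshold <= 1.0):
        raise ValidationError(f"vf_threshold {vf_threshold} outside (0, 1]")
    k = _alt_reads_required(depth, vf_threshold)
    if k > depth:
        logger.warning("required alt reads %d exceed depth %d; sensitivity 0", k, depth)
        return 0.0
    return float(sps.binom.sf(k - 1, depth, true_vf))


def min_depth_for_power(
    true_vf: float, vf_threshold: float, target: float = 0.99
) -> int:
    """Smallest depth from which sensitivity stays at or above ``target``.

    Because the required alt-read count is a ceiling, sensitivity is not
    monotone in depth: it can clear the target at one depth and dip below
    it a few reads later (e.g. at a 20% threshold for a heterozygous
    variant it wobbles around 99% until 17X, the depth from which it never
    drops again). The guaranteed minimum depth is therefore one past the
    last failing depth, not the first passing one.

    Requires true_vf > vf_threshold; otherwise power does not converge to 1
    as depth grows (the observed fraction concentrates below the cutoff).
    """
    if not (0.0 < target < 1.0):
        raise ValidationError(f"target {target} outside (0, 1)")
    if true_vf <= vf_threshold:
        raise ValidationError(
            f"true_vf ({true_vf}) must exceed vf_threshold ({vf_threshold})"
        )
    # Hoeffding: for depth d, P(miss) <= exp(-2 d (vf - t)^2), so beyond
    # d_max every depth satisfies the target and the scan is complete.
    d_max = math.ceil(
        math.log(1.0 / (1.0 - target)) / (2.0 * (true_vf - vf_threshold) ** 2)
    ) + 1
    last_fail = 0
    for depth in range(1, d_max + 1):
        if detection_power(depth, true_vf, vf_threshold) < target:
            last_fail = depth
    return last_fail + 1


def power_table(
    depths: Sequence[int],
    true_vfs: Sequence[float],
    vf_threshold: float,
) -> pd.DataFrame:
    """Sensitivity grid over depth x true VF at a fixed detection threshold."""
    rows = [
        {
            "depth": d,
            "true_vf": v,
            "vf_threshold": vf_threshold,
            "sensitivity": detection_power(d, v, vf_threshold),
        }
        for d in depths
        for v in true_vfs
    ]
    return pd.DataFrame(rows)


def _keys(calls: Iterable[VariantCall]) -> set[tuple]:
    return {c.key for c in calls}


def characterize_noise(
    controls: dict[str, list[list[VariantCall]]],
    dp_grid: Sequence[int] = (30, 40, 50, 60),
    vf_exonic_grid: Sequence[float] = (0.10, 0.15, 0.20, 0.25),
    vf_noncoding_offset: float = 0.05,
    dp_min: int = DP_MIN_DEFAULT,
    vf_exonic: float = VF_EXONIC_DEFAULT,
    vf_noncoding: float = VF_NONCODING_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Characterize non-reproducible noise across control replicates.

    ``controls`` maps control-sample id to its pre-filter replicate call
    sets (region_class must be assigned). A call is *reproducible* iff its
    normalized key appears in every replicate of its control.

    Returns (per-call table, threshold sweep, thresholds_eliminate_noise)
    where the last element verifies that the validated thresholds leave no
    surviving non-reproducible call.
    """
    rows = []
    for control_id, replicates in controls.items():
        if len(replicates) < 2:
            logger.warning("control %s has < 2 replicates; excluded", control_id)
            continue
        shared = set.intersection(*(_keys(r) for r in replicates))
        seen: set[tuple] = set()
        for rep in replicates:
            for call in rep:
                if call.key in seen:
                    continue
                seen.add(call.key)
                rows.append(
                    {
                        "control_id": control_id,
                        "chrom": call.chrom,
                        "pos": call.pos,
                        "ref": call.ref,
                        "alt": call.alt,
                        "DP": call.DP,
                        "VF": call.VF,
                        "region_class": call.region_class,
                        "reproducible": call.key in shared,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "control_id", "chrom", "pos", "ref", "alt",
            "DP", "VF", "region_class", "reproducible",
        ],
    )

    def surviving(dp_thr: int, vf_ex: float, vf_nc: float) -> int:
        if table.empty:
            return 0
        noise = table[~table["reproducible"]]
        vf_thr = np.where(noise["region_class"] == EXONIC, vf_ex, vf_nc)
        keep = (noise["DP"] >= dp_thr) & (noise["VF"] >= vf_thr)
        return int(keep.sum())

    sweep = pd.DataFrame(
        [
            {
                "dp_threshold": dp_thr,
                "vf_exonic": vf_ex,
                "vf_noncoding": vf_ex + vf_noncoding_offset,
                "surviving_noise_calls": surviving(
                    dp_thr, vf_ex, vf_ex + vf_noncoding_offset
                ),
            }
            for dp_thr in dp_grid
            for vf_ex in vf_exonic_grid
        ]
    )
    ok = surviving(dp_min, vf_exonic, vf_noncoding) == 0
    return table, sweep, ok


def surviving_noise_count(
    table: pd.DataFrame,
    dp_min: int = DP_MIN_DEFAULT,
    vf_exonic: float = VF_EXONIC_DEFAULT,
    vf_noncoding: float = VF_NONCODING_DEFAULT,
) -> int:
    """Non-reproducible calls that would pass the given thresholds."""
    if table.empty:
        return 0
    noise = table[~table["reproducible"]]
    vf_thr = np.where(noise["region_class"] == EXONIC, vf_exonic, vf_noncoding)
    return int(((noise["DP"] >= dp_min) & (noise["VF"] >= vf_thr)).sum())


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def replicate_concordance(rs: ReplicateSet) -> dict:
    """Per-region-class concordance across the replicates of one sample.

    Reports variant counts per replicate, mean pairwise Jaccard on
    normalized keys, whether the exonic call sets are identical, and the
    fraction of discordant calls carrying the borderline flag.
    """
    by_class: dict[str, list[set]] = {EXONIC: [], NONCODING_FLANK: []}
    borderline_keys: set[tuple] = set()
    for rep in rs.replicates:
        for cls in by_class:
            by_class[cls].append(
                {c.key for c in rep if c.region_class == cls}
            )
        borderline_keys |= {c.key for c in rep if c.borderline}

    result: dict = {
        "sample_id": rs.sample_id,
        "design": rs.design,
        "n_exonic_per_replicate": [len(s) for s in by_class[EXONIC]],
        "n_noncoding_per_replicate": [len(s) for s in by_class[NONCODING_FLANK]],
    }
    for cls, name in ((EXONIC, "exonic"), (NONCODING_FLANK, "noncoding")):
        sets = by_class[cls]
        pairs = [(a, b) for a, b in combinations(sets, 2)]
        result[f"jaccard_{name}"] = (
            float(np.mean([_jaccard(a, b) for a, b in pairs])) if pairs else 1.0
        )
    result["all_identical_exonic"] = all(
        s == by_class[EXONIC][0] for s in by_class[EXONIC]
    )
    all_sets = [
        set.union(ex, nc) for ex, nc in zip(by_class[EXONIC], by_class[NONCODING_FLANK])
    ]
    union_keys = set.union(*all_sets)
    shared_keys = set.intersection(*all_sets)
    discordant = union_keys - shared_keys
    result["n_discordant"] = len(discordant)
    result["borderline_explained"] = (
        len(discordant & borderline_keys) / len(discordant) if discordant else 1.0
    )
    return result
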