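"""Two-caller union merge and depth/allele-fraction filtering of germline calls.

Call sets from two complementary callers (a haplotype assembler and a
position-wise caller) are unified on normalized variant keys; the merged
calls then pass region-class-dependent thresholds: exonic SNVs/indels need
DP >= 50 and VF >= 20%, anything else (flanking noncoding) DP >= 50 and
VF >= 25%, both bounds inclusive. Passing calls near a threshold are
flagged *borderline* — these explain most replicate-to-replicate
discordance in noncoding calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .panel import EXONIC, NONCODING_FLANK, OFF_TARGET, GenePanel

logger = logging.getLogger(__name__)

DP_MIN_DEFAULT = 50
VF_EXONIC_DEFAULT = 0.20
VF_NONCODING_DEFAULT = 0.25
MAX_INDEL_LEN = 30  # longer events belong to the CNV/SV path

CALLER_A = "caller_A"
CALLER_B = "caller_B"

PASS = "pass"
FAIL_DEPTH = "fail_depth"
FAIL_VF = "fail_vf"
FAIL_REGION = "fail_region"

HET = "heterozygous"
HOM = "homozygous"
AMBIGUOUS = "ambiguous"

_BASES = frozenset("ACGT")


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """A single SNV/indel call with caller provenance and filter state.

    ``pos`` is 1-based (VCF-native). ``VF`` is the alt-allele read fraction.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    DP: int
    VF: float
    region_class: Optional[str] = None
    filter_status: Optional[str] = None
    zygosity: Optional[str] = None
    borderline: bool = False
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.VF <= 1.0):
            raise VariantError(f"VF {self.VF} outside [0, 1]")
        if self.DP < 0:
            raise VariantError(f"DP {self.DP} negative")
        if not self.callers:
            raise VariantError("callers must be non-empty")

    @property
    def variant_type(self) -> str:
        return "indel" if len(self.ref) != len(self.alt) else "SNV"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Deterministic key unifying padded representations of one variant.

    Trims the shared suffix, then the shared prefix (keeping at least one
    base of each allele), adjusting ``pos`` for trimmed prefix bases.
    """
    if ref == alt:
        raise VariantError(f"ref == alt ({ref!r}) at {chrom}:{pos}")
    if not ref or not alt:
        raise VariantError(f"empty allele at {chrom}:{pos}")
    if not (_BASES.issuperset(ref) and _BASES.issuperset(alt)):
        raise VariantError(f"non-ACGT allele at {chrom}:{pos}: {ref!r}>{alt!r}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def union_merge(
    calls_a: Iterable[VariantCall],
    calls_b: Iterable[VariantCall],
    vf_discrepancy_warn: float = 0.10,
) -> list[VariantCall]:
    """Union of two callers' outputs on normalized keys.

    When both callers report a variant, DP and VF come from caller A
    (declared precedence); VF disagreement beyond ``vf_discrepancy_warn``
    is logged. Conflicting ref alleles at an identical normalized locus are
    a normalization inconsistency and raise.
    """
    merged: dict[tuple[str, int, str, str], VariantCall] = {}
    locus_ref: dict[tuple[str, int, str], str] = {}

    def ingest(calls: Iterable[VariantCall], caller: str) -> None:
        seen: set[tuple[str, int, str, str]] = set()
        for call in calls:
            key = call.key
            if key in seen:
                raise VariantError(f"caller {caller}: duplicate call at {key}")
            seen.add(key)
            chrom, pos, ref, alt = key
            locus = (chrom, pos, alt)
            if locus in locus_ref and locus_ref[locus] != ref:
                raise VariantError(
                    f"inconsistent ref alleles at {chrom}:{pos} "
                    f"({locus_ref[locus]!r} vs {ref!r})"
                )
            locus_ref[locus] = ref
            norm = replace(
                call, chrom=chrom, pos=pos, ref=ref, alt=alt,
                callers=frozenset({caller}),
            )
            if key not in merged:
                merged[key] = norm
                continue
            prev = merged[key]
            if abs(prev.VF - norm.VF) > vf_discrepancy_warn:
                logger.warning(
                    "VF discrepancy at %s:%d %s>%s: %.3f vs %.3f",
                    chrom, pos, ref, alt, prev.VF, norm.VF,
                )
            keep = prev if CALLER_A in prev.callers else norm
            merged[key] = replace(keep, callers=prev.callers | norm.callers)

    ingest(calls_a, CALLER_A)
    ingest(calls_b, CALLER_B)
    return sorted(merged.values(), key=lambda c: (c.chrom, c.pos, c.ref, c.alt))


def class_vf_threshold(
    region_class: str,
    vf_exonic: float = VF_EXONIC_DEFAULT,
    vf_noncoding: float = VF_NONCODING_DEFAULT,
) -> float:
    return vf_exonic if region_class == EXONIC else vf_noncoding


def apply_filters(
    calls: Iterable[VariantCall],
    panel: GenePanel,
    dp_min: int = DP_MIN_DEFAULT,
    vf_exonic: float = VF_EXONIC_DEFAULT,
    vf_noncoding: float = VF_NONCODING_DEFAULT,
) -> list[VariantCall]:
    """Assign region class and pass/fail status to each call.

    A call passes iff its region is on target, DP >= dp_min and VF >= the
    region-class threshold (all inclusive). Failure reasons are recorded
    with region checked first, then depth, then allele fraction. Passing
    calls also receive zygosity and the borderline flag.
    """
    out = []
    for call in calls:
        region = panel.classify_position(call.chrom, call.pos - 1)  # VCF 1-based
        if region == OFF_TARGET:
            status = FAIL_REGION
        elif call.DP < dp_min:
            status = FAIL_DEPTH
        elif call.VF < class_vf_threshold(region, vf_exonic, vf_noncoding):
            status = FAIL_VF
        else:
            status = PASS
        call = replace(call, region_class=region, filter_status=status)
        if status == PASS:
            call = replace(
                call,
                zygosity=assign_zygosity(call),
                borderline=flag_borderline(
                    call, dp_min=dp_min, vf_exonic=vf_exonic,
                    vf_noncoding=vf_noncoding,
                ),
            )
        out.append(call)
    return out


def assign_zygosity(call: VariantCall) -> str:
    """Allele-fraction zygosity bands: 40–60% het, >= 90% hom, else ambiguous."""
    if 0.40 <= call.VF <= 0.60:
        return HET
    if call.VF >= 0.90:
        return HOM
    return AMBIGUOUS


def flag_borderline(
    call: VariantCall,
    dp_min: int = DP_MIN_DEFAULT,
    vf_exonic: float = VF_EXONIC_DEFAULT,
    vf_noncoding: float = VF_NONCODING_DEFAULT,
    dp_margin: int = 10,
    vf_margin: float = 0.03,
) -> bool:
    """A passing call that barely clears either threshold.

    True iff DP < dp_min + dp_margin or VF < class threshold + vf_margin.
    """
    thr = class_vf_threshold(call.region_class or EXONIC, vf_exonic, vf_noncoding)
    return call.DP < dp_min + dp_margin or call.VF < thr + vf_margin


def reject_long_indels(
    calls: Iterable[VariantCall], max_len: int = MAX_INDEL_LEN
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split calls into (kept, rejected-to-CNV/SV-path) by indel length."""
    kept, rejected = [], []
    for call in calls:
        (rejected if call.indel_length >= max_len else kept).append(call)
    if rejected:
        logger.info("%d indel(s) >= %d bp deferred to the CNV/SV path",
                    len(rejected), max_len)
    return kept, rejected


def passing(calls: Iterable[VariantCall]) -> list[VariantCall]:
    return [c for c in calls if c.filter_status == PASS]
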