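"""Five-class germline variant classification from ACMG/AMP evidence tags.

Evidence codes follow the ACMG/AMP 2015 framework: pathogenic-side tags
(PVS1 very strong; PS1-4 strong; PM1-6 moderate; PP1-5 supporting) and
benign-side tags (BA1 stand-alone; BS1-4 strong; BP1-7 supporting). The
published combining rules are implemented as an explicit rule table — a
deliberate dependency on the guideline as *data*, not code — and mapped to
the clinical 5-class scale: benign (1), likely benign (2), VUS (3), likely
pathogenic (4), pathogenic (5).

BA1 is the stand-alone benign rule: population allele frequency above 5%
(strict) in any supplied population cohort suffices on its own. When a
variant satisfies both a pathogenic-qualifying and a benign-qualifying
combination, the evidence is contradictory and the call drops to VUS with
the conflict flag set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .variants import PASS, VariantCall

BA1_THRESHOLD_DEFAULT = 0.05

PATHOGENIC_TAGS = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_TAGS = frozenset(
    {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
)
VALID_TAGS = PATHOGENIC_TAGS | BENIGN_TAGS

CLASS_LABELS = {
    1: "benign",
    2: "likely_benign",
    3: "VUS",
    4: "likely_pathogenic",
    5: "pathogenic",
}


class AcmgError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceSet:
    """ACMG evidence tags plus the maximum population allele frequency.

    A ``pop_af_max`` above the BA1 threshold forces BA1 into the tag set.
    """

    tags: frozenset[str] = frozenset()
    pop_af_max: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.tags) - VALID_TAGS
        if unknown:
            raise AcmgError(f"unknown evidence tag(s): {sorted(unknown)}")
        if not (0.0 <= self.pop_af_max <= 1.0):
            raise AcmgError(f"pop_af_max {self.pop_af_max} outside [0, 1]")
        if apply_ba1(self.pop_af_max) and "BA1" not in self.tags:
            object.__setattr__(self, "tags", frozenset(self.tags) | {"BA1"})


@dataclass(frozen=True)
class Classification:
    class_number: int
    label: str
    conflict: bool = False

    def __post_init__(self) -> None:
        if CLASS_LABELS[self.class_number] != self.label:
            raise AcmgError(
                f"label {self.label!r} does not match class {self.class_number}"
            )

    @property
    def group(self) -> str:
        """Reporting group: Class_4_5, Class_3 or Class_1_2."""
        if self.class_number >= 4:
            return "Class_4_5"
        if self.class_number == 3:
            return "Class_3"
        return "Class_1_2"


def apply_ba1(pop_af_max: float, threshold: float = BA1_THRESHOLD_DEFAULT) -> bool:
    """Stand-alone benign: allele frequency strictly above the threshold."""
    return pop_af_max > threshold


def _tag_counts(tags: frozenset[str]) -> Counter:
    c: Counter = Counter()
    for t in tags:
        c[t[:2] if not t.startswith("PVS") else "PVS"] += 1
    return c


def _pathogenic(c: Counter) -> bool:
    pvs, ps, pm, pp = c["PVS"], c["PS"], c["PM"], c["PP"]
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        return True
    if ps >= 2:
        return True
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return True
    return False


def _likely_pathogenic(c: Counter) -> bool:
    pvs, ps, pm, pp = c["PVS"], c["PS"], c["PM"], c["PP"]
    if pvs == 1 and pm == 1:
        return True
    if ps == 1 and 1 <= pm <= 2:
        return True
    if ps == 1 and pp >= 2:
        return True
    if pm >= 3:
        return True
    if pm == 2 and pp >= 2:
        return True
    if pm == 1 and pp >= 4:
        return True
    return False


def _benign(tags: frozenset[str], c: Counter) -> bool:
    return "BA1" in tags or c["BS"] >= 2


def _likely_benign(c: Counter) -> bool:
    return (c["BS"] == 1 and c["BP"] >= 1) or c["BP"] >= 2


def combine(evidence: EvidenceSet) -> Classification:
    """Combine evidence tags into a 5-class call.

    Pathogenic-side and benign-side qualification are evaluated
    independently; satisfying both is contradictory evidence and yields
    VUS (Class 3) with ``conflict=True``. No qualifying combination on
    either side is VUS without conflict.
    """
    c = _tag_counts(evidence.tags)
    path_side = _pathogenic(c) or _likely_pathogenic(c)
    benign_side = _benign(evidence.tags, c) or _likely_benign(c)
    if path_side and benign_side:
        return Classification(3, "VUS", conflict=True)
    if _pathogenic(c):
        return Classification(5, "pathogenic")
    if _likely_pathogenic(c):
        return Classification(4, "likely_pathogenic")
    if _benign(evidence.tags, c):
        return Classification(1, "benign")
    if _likely_benign(c):
        return Classification(2, "likely_benign")
    return Classification(3, "VUS")


def parse_tags(text: str) -> frozenset[str]:
    """Parse a semicolon-joined tag string (empty string -> no tags)."""
    return frozenset(t.strip() for t in text.split(";") if t.strip())


def classify_callset(
    calls: Iterable[VariantCall],
    evidence_table: Mapping[tuple[str, int, str, str], EvidenceSet],
) -> tuple[list[tuple[VariantCall, Classification]], dict[str, int]]:
    """Classify every passing call and tally the reporting groups.

    ``evidence_table`` maps normalized variant keys to evidence; calls
    without a row get an empty EvidenceSet (hence VUS). Returns per-call
    classifications and counts for the Class_4_5 / Class_3 / Class_1_2
    groups.
    """
    results: list[tuple[VariantCall, Classification]] = []
    counts = {"Class_4_5": 0, "Class_3": 0, "Class_1_2": 0}
    for call in calls:
        if call.filter_status is not None and call.filter_status != PASS:
            continue
        evidence = evidence_table.get(call.key, EvidenceSet())
        cls = combine(evidence)
        results.append((call, cls))
        counts[cls.group] += 1
    return results, counts


def classification_frame(
    results: Iterable[tuple[VariantCall, Classification]]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "region_class": call.region_class,
                "class_number": cls.class_number,
                "label": cls.label,
                "conflict": cls.conflict,
            }
            for call, cls in results
        ],
        columns=[
            "chrom", "pos", "ref", "alt", "region_class",
            "class_number", "label", "conflict",
        ],
    )
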