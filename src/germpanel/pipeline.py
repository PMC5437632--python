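"""End-to-end germline analysis: filter -> classify -> CNV -> SV refinement.

The run consumes a panel BED, two caller call sets, an exon depth matrix,
optional SV records and optional evidence/population-AF tables, and emits
the report bundle: filtered/classified variant TSVs, CNV segment and
refined-segment TSVs, and a per-sample JSON summary with class-group
counts. All thresholds default to the validated values and every one is
overridable; the effective configuration is echoed into the bundle for
provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as gio
from .acmg import BA1_THRESHOLD_DEFAULT, classification_frame, classify_callset
from .cnv import (
    ALPHA_DEFAULT,
    GAIN_FC_DEFAULT,
    LOSS_FC_DEFAULT,
    call_sample,
    segments_frame,
)
from .panel import EXONIC, NONCODING_FLANK, load_panel
from .sv import MIN_SUPPORT_DEFAULT, RECIPROCAL_OVERLAP_DEFAULT, reconcile
from .variants import (
    DP_MIN_DEFAULT,
    PASS,
    VF_EXONIC_DEFAULT,
    VF_NONCODING_DEFAULT,
    apply_filters,
    reject_long_indels,
    union_merge,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths and thresholds for one germline analysis run.

    Threshold defaults are the validated assay values: DP >= 50, VF >= 20%
    exonic / 25% noncoding, CNV fold change > 1.3 / < -1.7 at p < 0.05,
    BA1 population frequency > 5%.
    """

    panel: str
    out_dir: str
    calls_a: Optional[str] = None
    calls_b: Optional[str] = None
    depth_matrix: Optional[str] = None
    sv_records: Optional[str] = None
    evidence: Optional[str] = None
    population_af: Optional[str] = None
    sample_id: Optional[str] = None
    flank_bp: int = 50
    dp_min: int = DP_MIN_DEFAULT
    vf_exonic: float = VF_EXONIC_DEFAULT
    vf_noncoding: float = VF_NONCODING_DEFAULT
    gain_fc: float = GAIN_FC_DEFAULT
    loss_fc: float = LOSS_FC_DEFAULT
    alpha: float = ALPHA_DEFAULT
    ba1_threshold: float = BA1_THRESHOLD_DEFAULT
    dp_margin: int = 10
    vf_margin: float = 0.03
    min_support: int = MIN_SUPPORT_DEFAULT
    reciprocal_overlap: float = RECIPROCAL_OVERLAP_DEFAULT
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("vf_exonic", "vf_noncoding", "alpha", "ba1_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.dp_min < 0 or self.flank_bp < 0:
            raise ConfigError("dp_min and flank_bp must be >= 0")
        if self.gain_fc < 1.0:
            raise ConfigError(f"gain_fc must be >= 1, got {self.gain_fc}")
        if self.loss_fc > -1.0:
            raise ConfigError(f"loss_fc must be <= -1, got {self.loss_fc}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _read_calls(path: str, caller: str):
    if path.endswith((".vcf", ".vcf.gz")):
        return gio.read_calls_vcf(path, caller)
    return gio.read_calls_tsv(path)


def run_germline(config: RunConfig) -> dict:
    """Execute the germline arm end to end; returns the report bundle paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel, flank_bp=config.flank_bp)
    logger.info("panel: %d exons across %d genes", len(panel), len(panel.genes))
    bundle: dict = {}

    summary: dict = {"sample_id": config.sample_id, "counts": {}}

    if config.calls_a and config.calls_b:
        calls_a = _read_calls(config.calls_a, "caller_A")
        calls_b = _read_calls(config.calls_b, "caller_B")
        merged = union_merge(calls_a, calls_b)
        merged, long_indels = reject_long_indels(merged)
        filtered = apply_filters(
            merged, panel,
            dp_min=config.dp_min,
            vf_exonic=config.vf_exonic,
            vf_noncoding=config.vf_noncoding,
        )
        logger.info(
            "calls: %d merged, %d deferred long indels, %d pass",
            len(merged), len(long_indels),
            sum(c.filter_status == PASS for c in filtered),
        )
        calls_path = out_dir / "calls.tsv"
        gio.write_calls_tsv(filtered, calls_path)
        bundle["calls"] = str(calls_path)

        passing = [c for c in filtered if c.filter_status == PASS]
        by_region = {
            "exonic": sum(c.region_class == EXONIC for c in passing),
            "noncoding_flank": sum(c.region_class == NONCODING_FLANK for c in passing),
        }
        summary["counts"]["passing_by_region"] = by_region
        summary["counts"]["filter_status"] = {
            status: sum(c.filter_status == status for c in filtered)
            for status in sorted({c.filter_status for c in filtered})
        }
        summary["counts"]["long_indels_deferred"] = len(long_indels)

        pop_af = (
            gio.read_population_af(config.population_af)
            if config.population_af else {}
        )
        evidence = (
            gio.read_evidence(config.evidence, pop_af)
            if config.evidence
            else {k: None for k in ()}
        )
        if config.evidence or config.population_af:
            from .acmg import EvidenceSet

            if not config.evidence:
                evidence = {k: EvidenceSet(pop_af_max=v) for k, v in pop_af.items()}
            results, class_counts = classify_callset(passing, evidence)
            classified_path = out_dir / "classified.tsv"
            gio.write_tsv(classification_frame(results), classified_path)
            bundle["classified"] = str(classified_path)
            summary["counts"]["class_groups"] = class_counts

    segments = []
    if config.depth_matrix:
        matrix = gio.read_depth_matrix(config.depth_matrix)
        test_samples = (
            [config.sample_id]
            if config.sample_id and config.sample_id in matrix.test_samples
            else matrix.test_samples
        )
        for sample in test_samples:
            segments.extend(
                call_sample(
                    matrix, sample,
                    gain_fc=config.gain_fc,
                    loss_fc=config.loss_fc,
                    alpha=config.alpha,
                )
            )
        seg_path = out_dir / "cnv_segments.tsv"
        gio.write_tsv(segments_frame(segments), seg_path)
        bundle["cnv_segments"] = str(seg_path)
        summary["counts"]["cnv_segments"] = len(segments)

    if config.sv_records and segments:
        if config.sv_records.endswith((".vcf", ".vcf.gz")):
            svs = gio.read_sv_vcf(config.sv_records)
        else:
            svs = gio.read_sv_tsv(config.sv_records)
        refined = reconcile(
            segments, svs, panel,
            min_support=config.min_support,
            min_reciprocal_overlap=config.reciprocal_overlap,
        )
        rows = segments_frame([r.base for r in refined])
        rows["refined_start"] = [
            r.refined_start if r.refined else "" for r in refined
        ]
        rows["refined_end"] = [r.refined_end if r.refined else "" for r in refined]
        rows["boundary_note"] = [r.boundary_note or "" for r in refined]
        refined_path = out_dir / "cnv_refined.tsv"
        gio.write_tsv(rows, refined_path)
        bundle["cnv_refined"] = str(refined_path)
        summary["counts"]["refined_segments"] = sum(r.refined for r in refined)

    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    bundle["summary"] = str(summary_path)

    config_path = out_dir / "effective_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    bundle["effective_config"] = str(config_path)
    return bundle
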