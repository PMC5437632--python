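"""Synthetic panel data with planted ground truth.

Every input the pipeline consumes can be generated here: a panel BED, a
samples x exons depth matrix with spiked copy-number events, two-caller
replicate call sets with reproducible true variants and non-reproducible
noise, SV breakpoint records, and evidence/population-AF tables. All
outputs are deterministic for a fixed seed and come with machine-readable
truth so recovery can be scored exactly.

The depth model is gamma-Poisson (negative binomial): each exon has a
capture-efficiency factor shared across samples, and per-sample exon depth
is drawn with a configurable coefficient of variation (default 10%,
consistent with hybridization-capture panel variability) around
``mean_exon_depth`` x efficiency x copy ratio. Copy ratios 0.5 / 1.5 model
single-copy loss / gain in a diploid genome; 0.0 / 2.0 model homozygous
deletion / two-copy gain.

Variant allele fractions are binomial draws at the call's depth — the same
sampling model the detection-power analysis assumes — so planted
heterozygous variants scatter realistically around 50%. Noise calls are
planted below the validated DP/VF thresholds by default (as the
false-positive characterization observed) and appear in only a subset of
replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cnv import (
    GAIN,
    INTRAGENIC,
    LOSS,
    ROLE_REFERENCE,
    ROLE_TEST,
    WHOLE_GENE,
    DepthMatrix,
)
from .panel import EXONIC, NONCODING_FLANK, GenePanel, TargetRegion, write_panel
from .sv import SvRecord
from .variants import CALLER_A, CALLER_B, VariantCall

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CnvSpike:
    """A planted copy-number event: gene, inclusive exon span, copy ratio.

    ``first_exon``/``last_exon`` of None mean the whole gene.
    """

    gene: str
    first_exon: Optional[int] = None
    last_exon: Optional[int] = None
    copy_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.copy_ratio < 0:
            raise SimulationError(f"copy_ratio must be >= 0, got {self.copy_ratio}")


@dataclass(frozen=True)
class VariantSpike:
    """A planted variant: region class, nominal DP and allele fraction.

    ``is_noise`` variants are non-reproducible artifacts: they appear in a
    strict subset of replicates and, when ``below_thresholds`` (default),
    are guaranteed to fail the validated DP or VF filter.
    """

    region_class: str = EXONIC
    DP: int = 500
    true_vf: float = 0.5
    is_noise: bool = False
    below_thresholds: bool = True


def _default_spikes() -> list[CnvSpike]:
    return [
        CnvSpike("GENE1", None, None, 0.5),  # whole-gene het deletion
        CnvSpike("GENE2", 3, 3, 1.5),  # single-exon duplication
    ]


def _default_variant_spikes() -> list[VariantSpike]:
    true_calls = [
        VariantSpike(EXONIC, 500, 0.5),
        VariantSpike(EXONIC, 300, 0.5),
        VariantSpike(EXONIC, 400, 1.0),
        VariantSpike(NONCODING_FLANK, 200, 0.5),
        VariantSpike(NONCODING_FLANK, 60, 0.30),  # borderline-prone
    ]
    noise = [
        VariantSpike(EXONIC, 30, 0.15, is_noise=True),
        VariantSpike(EXONIC, 80, 0.10, is_noise=True),
        VariantSpike(NONCODING_FLANK, 40, 0.12, is_noise=True),
        VariantSpike(NONCODING_FLANK, 120, 0.10, is_noise=True),
    ]
    return true_calls + noise


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic assay."""

    seed: int
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 20)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 2000)
    flank_bp: int = 50
    n_reference_normals: int = 20
    mean_exon_depth: float = 800.0
    depth_cv: float = 0.10
    spikes: list[CnvSpike] = field(default_factory=_default_spikes)
    n_unspiked_tests: int = 1
    variant_spikes: list[VariantSpike] = field(default_factory=_default_variant_spikes)
    n_controls: int = 13
    n_replicates: int = 3
    n_runs: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.n_genes < 1:
            raise SimulationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.depth_cv <= 0:
            raise SimulationError("depth_cv must be > 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator function
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def make_panel(config: SimulationConfig) -> GenePanel:
    """Deterministic toy panel: ``n_genes`` genes on one chromosome."""
    rng = _rng(config, 0)
    regions: list[TargetRegion] = []
    pos = 10_000
    for g in range(1, config.n_genes + 1):
        gene = f"GENE{g}"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        starts_ends = []
        for _ in range(n_exons):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            starts_ends.append((pos, pos + length))
            pos += length + int(
                rng.integers(config.intron_length[0], config.intron_length[1] + 1)
            )
        pos += 20_000  # intergenic spacer
        # minus-strand genes number exons in decreasing genomic order
        order = range(1, n_exons + 1) if strand == "+" else range(n_exons, 0, -1)
        for (start, end), idx in zip(starts_ends, order):
            regions.append(TargetRegion("chr1", start, end, gene, idx, strand))
    return GenePanel(regions=regions, flank_bp=config.flank_bp)


def _nb_depth(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Gamma-Poisson depth draws with total coefficient of variation ~ cv."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape)
    pos = mean > 0
    if pos.any():
        m = mean[pos]
        cv2_extra = np.maximum(cv * cv - 1.0 / m, 1e-8)
        shape = 1.0 / cv2_extra
        lam = m * rng.gamma(shape, 1.0 / shape)
        out[pos] = rng.poisson(lam)
    return out


def make_depths(
    config: SimulationConfig, panel: GenePanel
) -> tuple[DepthMatrix, list[dict]]:
    """Depth matrix with reference normals, spiked and unspiked test samples.

    Returns the matrix plus a truth list of planted events (sample_id, gene,
    first_exon, last_exon, copy_ratio, direction, scope).
    """
    rng = _rng(config, 1)
    exon_keys = [(r.gene, r.exon_index) for r in panel]
    n_exons = len(exon_keys)
    efficiency = rng.lognormal(mean=0.0, sigma=0.25, size=n_exons)

    samples: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for i in range(1, config.n_reference_normals + 1):
        sid = f"NORM{i:02d}"
        depth_scale = rng.uniform(0.7, 1.3)  # per-sample library size
        samples[sid] = _nb_depth(
            rng, config.mean_exon_depth * depth_scale * efficiency, config.depth_cv
        )
        roles[sid] = ROLE_REFERENCE

    truth: list[dict] = []
    known_genes = {r.gene for r in panel}
    for j, spike in enumerate(config.spikes, start=1):
        if spike.gene not in known_genes:
            raise SimulationError(f"spike references unknown gene {spike.gene!r}")
        sid = f"TEST{j}"
        gene_exons = sorted(
            idx for g, idx in exon_keys if g == spike.gene
        )
        first = spike.first_exon if spike.first_exon is not None else gene_exons[0]
        last = spike.last_exon if spike.last_exon is not None else gene_exons[-1]
        ratios = np.ones(n_exons)
        for k, (g, idx) in enumerate(exon_keys):
            if g == spike.gene and first <= idx <= last:
                ratios[k] = spike.copy_ratio
        depth_scale = rng.uniform(0.7, 1.3)
        samples[sid] = _nb_depth(
            rng, config.mean_exon_depth * depth_scale * efficiency * ratios,
            config.depth_cv,
        )
        roles[sid] = ROLE_TEST
        truth.append(
            {
                "sample_id": sid,
                "gene": spike.gene,
                "first_exon": first,
                "last_exon": last,
                "copy_ratio": spike.copy_ratio,
                "direction": LOSS if spike.copy_ratio < 1 else GAIN,
                "scope": WHOLE_GENE
                if (first, last) == (gene_exons[0], gene_exons[-1])
                else INTRAGENIC,
            }
        )
    for j in range(1, config.n_unspiked_tests + 1):
        sid = f"TESTNULL{j}"
        depth_scale = rng.uniform(0.7, 1.3)
        samples[sid] = _nb_depth(
            rng, config.mean_exon_depth * depth_scale * efficiency, config.depth_cv
        )
        roles[sid] = ROLE_TEST

    values = pd.DataFrame(
        samples, index=pd.MultiIndex.from_tuples(exon_keys, names=["gene", "exon_index"])
    )
    return DepthMatrix(values=values, roles=roles), truth


def _draw_position(
    rng: np.random.Generator,
    panel: GenePanel,
    region_class: str,
    used: set[tuple[str, int]],
) -> tuple[str, int]:
    """A fresh 0-based position of the requested region class."""
    regions = panel.regions
    for _ in range(1000):
        r = regions[int(rng.integers(len(regions)))]
        if region_class == EXONIC:
            pos = int(rng.integers(r.start, r.end))
        else:
            d = int(rng.integers(1, panel.flank_bp + 1))
            pos = r.start - d if rng.random() < 0.5 else r.end - 1 + d
        if (r.chrom, pos) in used or panel.classify_position(r.chrom, pos) != region_class:
            continue
        used.add((r.chrom, pos))
        return r.chrom, pos
    raise SimulationError("could not place variant; panel too small")


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return _BASES[i], _BASES[j]


def _clip_noise(
    dp: int, vf: float, spike: VariantSpike, dp_min: int = 50,
    vf_exonic: float = 0.20, vf_noncoding: float = 0.25,
) -> tuple[int, float]:
    """Keep a noise call on the intended side of the validated thresholds."""
    if not spike.below_thresholds:
        return dp, vf
    thr = vf_exonic if spike.region_class == EXONIC else vf_noncoding
    if spike.DP < dp_min:
        dp = min(dp, dp_min - 1)
    if spike.true_vf < thr:
        vf = min(vf, thr - 0.01)
    return max(dp, 1), vf


@dataclass
class ReplicateCallset:
    """One replicate library's two-caller output."""

    control_id: str
    run_label: str
    barcode: str
    calls_a: list[VariantCall]
    calls_b: list[VariantCall]


def make_callsets(
    config: SimulationConfig, panel: GenePanel
) -> tuple[dict[str, list[ReplicateCallset]], pd.DataFrame]:
    """Replicate two-caller call sets for each control, plus truth table.

    True variants appear in every replicate of their control with
    binomially drawn VF at a Poisson-jittered DP; noise variants appear in
    a strict subset of replicates. Caller A and B both report a true
    variant with probability 0.8 (else one of them at random); noise calls
    land in one caller, or both with probability 0.2.
    """
    rng = _rng(config, 2)
    used: set[tuple[str, int]] = set()
    controls: dict[str, list[ReplicateCallset]] = {}
    truth_rows = []
    run_labels = [f"RUN{(i % config.n_runs) + 1}" for i in range(config.n_replicates)]
    for c in range(1, config.n_controls + 1):
        control_id = f"CTRL{c:02d}"
        planted = []
        for s_idx, spike in enumerate(config.variant_spikes):
            chrom, pos = _draw_position(rng, panel, spike.region_class, used)
            ref, alt = _draw_alleles(rng)
            if spike.is_noise:
                n_present = int(rng.integers(1, config.n_replicates))
                present = set(
                    rng.choice(config.n_replicates, size=n_present, replace=False).tolist()
                )
            else:
                present = set(range(config.n_replicates))
            planted.append((spike, chrom, pos, ref, alt, present))
            truth_rows.append(
                {
                    "control_id": control_id,
                    "chrom": chrom,
                    "pos": pos + 1,  # VCF-native
                    "ref": ref,
                    "alt": alt,
                    "region_class": spike.region_class,
                    "nominal_DP": spike.DP,
                    "true_vf": spike.true_vf,
                    "is_noise": spike.is_noise,
                    "n_replicates_present": len(present),
                }
            )
        reps = []
        for r in range(config.n_replicates):
            calls_a: list[VariantCall] = []
            calls_b: list[VariantCall] = []
            for spike, chrom, pos, ref, alt, present in planted:
                if r not in present:
                    continue
                dp = max(int(rng.poisson(spike.DP)), 1)
                vf = rng.binomial(dp, spike.true_vf) / dp
                if spike.is_noise:
                    dp, vf = _clip_noise(dp, vf, spike)
                in_a = in_b = False
                if spike.is_noise:
                    if rng.random() < 0.2:
                        in_a = in_b = True
                    else:
                        in_a = rng.random() < 0.5
                        in_b = not in_a
                else:
                    if rng.random() < 0.8:
                        in_a = in_b = True
                    else:
                        in_a = rng.random() < 0.5
                        in_b = not in_a
                for flag, target, caller in (
                    (in_a, calls_a, CALLER_A),
                    (in_b, calls_b, CALLER_B),
                ):
                    if flag:
                        target.append(
                            VariantCall(
                                chrom=chrom,
                                pos=pos + 1,
                                ref=ref,
                                alt=alt,
                                callers=frozenset({caller}),
                                DP=dp,
                                VF=float(vf),
                                sample_id=control_id,
                            )
                        )
            reps.append(
                ReplicateCallset(
                    control_id=control_id,
                    run_label=run_labels[r],
                    barcode=f"BC{((c + r) % 8) + 1:02d}",
                    calls_a=calls_a,
                    calls_b=calls_b,
                )
            )
        controls[control_id] = reps
    truth = pd.DataFrame(truth_rows)
    return controls, truth


def make_sv_records(
    config: SimulationConfig,
    panel: GenePanel,
    truth: list[dict],
    breakpoint_jitter: int = 40,
) -> list[SvRecord]:
    """SV breakpoint evidence consistent with the planted CNV truth.

    Breakpoints are jittered into the flanking introns (or partway into the
    boundary exons) to emulate base-pair-resolution split-read evidence.
    """
    rng = _rng(config, 3)
    records = []
    for event in truth:
        chrom, span_start, span_end = panel.span(
            event["gene"], event["first_exon"], event["last_exon"]
        )
        start = span_start - int(rng.integers(1, breakpoint_jitter + 1))
        end = span_end + int(rng.integers(1, breakpoint_jitter + 1))
        records.append(
            SvRecord(
                chrom=chrom,
                start=start,
                end=end,
                sv_type="DEL" if event["direction"] == LOSS else "DUP",
                support=int(rng.integers(5, 40)),
            )
        )
    return records


def make_evidence(
    config: SimulationConfig,
    truth: pd.DataFrame,
    common_fraction: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-AF and ACMG evidence tables for the planted true variants.

    A ``common_fraction`` of true variants are common polymorphisms
    (population AF drawn above 5%, hence BA1/benign); the remainder are
    rare, and a third of those carry pathogenic evidence (PVS1 + PM2).
    """
    rng = _rng(config, 4)
    af_rows, ev_rows = [], []
    for _, row in truth[~truth["is_noise"]].drop_duplicates(
        subset=["chrom", "pos", "ref", "alt"]
    ).iterrows():
        key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
        if rng.random() < common_fraction:
            af = float(rng.uniform(0.06, 0.40))
            tags = ""
        else:
            af = float(rng.uniform(0.0, 0.005))
            tags = "PVS1;PM2" if rng.random() < 0.33 else ""
        for cohort in ("COHORT_A", "COHORT_B"):
            af_rows.append(
                {
                    "variant_key": key,
                    "cohort": cohort,
                    "af": af * float(rng.uniform(0.8, 1.0)) if cohort == "COHORT_B" else af,
                }
            )
        ev_rows.append({"variant_key": key, "tags": tags})
    return pd.DataFrame(af_rows), pd.DataFrame(ev_rows)


def write_bundle(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate and write the full synthetic input bundle to ``out_dir``.

    Writes panel BED, depth-matrix TSV, per-replicate caller TSVs, SV TSV,
    evidence and population-AF TSVs, and a truth JSON; returns the paths.
    """
    from . import io as gio  # local import to avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = make_panel(config)
    write_panel(panel, out_dir / "panel.bed")
    matrix, cnv_truth = make_depths(config, panel)
    gio.write_depth_matrix(matrix, out_dir / "depth_matrix.tsv")
    controls, variant_truth = make_callsets(config, panel)
    call_paths = []
    for control_id, reps in controls.items():
        for i, rep in enumerate(reps, start=1):
            pa = out_dir / f"{control_id}_rep{i}_callerA.tsv"
            pb = out_dir / f"{control_id}_rep{i}_callerB.tsv"
            gio.write_calls_tsv(rep.calls_a, pa)
            gio.write_calls_tsv(rep.calls_b, pb)
            call_paths.append({"control": control_id, "replicate": i,
                               "run": rep.run_label, "barcode": rep.barcode,
                               "caller_A": pa.name, "caller_B": pb.name})
    svs = make_sv_records(config, panel, cnv_truth)
    gio.write_sv_tsv(svs, out_dir / "sv_records.tsv")
    pop_af, evidence = make_evidence(config, variant_truth)
    pop_af.to_csv(out_dir / "population_af.tsv", sep="\t", index=False)
    evidence.to_csv(out_dir / "evidence.tsv", sep="\t", index=False)
    truth = {
        "cnv": cnv_truth,
        "variants": variant_truth.to_dict(orient="records"),
        "replicates": call_paths,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {
        "panel": str(out_dir / "panel.bed"),
        "depth_matrix": str(out_dir / "depth_matrix.tsv"),
        "sv_records": str(out_dir / "sv_records.tsv"),
        "population_af": str(out_dir / "population_af.tsv"),
        "evidence": str(out_dir / "evidence.tsv"),
        "truth": str(out_dir / "truth.json"),
    }
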