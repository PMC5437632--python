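"""Readers and writers for the panel's tabular and VCF dialects.

Report outputs are TSV with the header line prefixed by ``#``; input
readers accept headers with or without the prefix (depth and caller tables
in the wild usually come unprefixed).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .acmg import EvidenceSet, parse_tags
from .cnv import DepthMatrix
from .sv import SvRecord
from .variants import VariantCall, normalize_variant


class FormatError(ValueError):
    pass


def read_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with an optionally '#'-prefixed header line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    names = first.lstrip("#").strip().split("\t")
    return pd.read_csv(path, sep="\t", skiprows=1, names=names)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Report-style TSV: '#'-prefixed header, tab-separated rows."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# -- depth tables --------------------------------------------------------

def read_position_depths(path: str | Path) -> pd.DataFrame:
    """Per-position depth TSV: sample_id, chrom, pos (0-based), depth."""
    df = read_tsv(path)
    missing = {"sample_id", "chrom", "pos", "depth"} - set(df.columns)
    if missing:
        raise FormatError(f"depth table missing column(s): {sorted(missing)}")
    return df


def write_depth_matrix(matrix: DepthMatrix, path: str | Path) -> None:
    """Exon x sample matrix TSV; sample roles ride in a '#roles:' line."""
    with open(path, "w") as fh:
        roles = ";".join(f"{s}={matrix.roles[s]}" for s in matrix.values.columns)
        fh.write(f"#roles: {roles}\n")
        fh.write("#gene\texon_index\t" + "\t".join(matrix.values.columns) + "\n")
        for (gene, exon_index), row in matrix.values.iterrows():
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{gene}\t{exon_index}\t{vals}\n")


def read_depth_matrix(path: str | Path) -> DepthMatrix:
    path = Path(path)
    with open(path) as fh:
        roles_line = fh.readline().strip()
        header = fh.readline().lstrip("#").strip().split("\t")
        if not roles_line.startswith("#roles:"):
            raise FormatError("depth matrix must start with a '#roles:' line")
        roles = {}
        for item in roles_line.removeprefix("#roles:").strip().split(";"):
            sample, _, role = item.partition("=")
            roles[sample] = role
        rows, index = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            index.append((fields[0], int(fields[1])))
            rows.append([float(v) for v in fields[2:]])
    values = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["gene", "exon_index"]),
        columns=header[2:],
    )
    return DepthMatrix(values=values, roles=roles)


# -- variant calls -------------------------------------------------------

_CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "caller", "DP", "VF",
    "sample_id", "region_class", "filter_status", "zygosity", "borderline",
]


def write_calls_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "caller": ";".join(sorted(c.callers)),
                "DP": c.DP,
                "VF": round(c.VF, 6),
                "sample_id": c.sample_id or "",
                "region_class": c.region_class or "",
                "filter_status": c.filter_status or "",
                "zygosity": c.zygosity or "",
                "borderline": int(c.borderline),
            }
        )
    write_tsv(pd.DataFrame(rows, columns=_CALL_COLUMNS), path)


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    df = read_tsv(path)
    missing = {"chrom", "pos", "ref", "alt", "caller", "DP", "VF"} - set(df.columns)
    if missing:
        raise FormatError(f"call table missing column(s): {sorted(missing)}")
    calls = []
    for _, row in df.iterrows():
        calls.append(
            VariantCall(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                callers=frozenset(str(row["caller"]).split(";")),
                DP=int(row["DP"]),
                VF=float(row["VF"]),
                sample_id=(
                    str(row["sample_id"])
                    if "sample_id" in df.columns and pd.notna(row["sample_id"]) and str(row["sample_id"])
                    else None
                ),
            )
        )
    return calls


def write_calls_vcf(calls: Iterable[VariantCall], path: str | Path,
                    sample_name: str = "SAMPLE") -> None:
    """Minimal VCF 4.2 with DP and AD in FORMAT (alt reads from DP*VF)."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    contigs = []
    for c in calls:
        if c.chrom not in contigs:
            contigs.append(c.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        for c in calls:
            ad_alt = round(c.VF * c.DP)
            ad_ref = c.DP - ad_alt
            filt = c.filter_status if c.filter_status else "."
            filt = "PASS" if filt == "pass" else filt
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t.\t"
                f"GT:DP:AD\t0/1:{c.DP}:{ad_ref},{ad_alt}\n"
            )


def read_calls_vcf(path: str | Path, caller: str) -> list[VariantCall]:
    """Read a single-sample VCF; VF comes from AD/DP FORMAT fields."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    calls = []
    vcf = VCF(str(path))
    for rec in vcf:
        if not rec.ALT:
            continue
        dp = int(rec.format("DP")[0][0]) if rec.format("DP") is not None else 0
        ad = rec.format("AD")
        if ad is not None and dp > 0:
            vf = float(ad[0][1]) / dp
        else:
            vf = 0.0
        calls.append(
            VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                callers=frozenset({caller}),
                DP=dp,
                VF=min(max(vf, 0.0), 1.0),
            )
        )
    return calls


# -- structural variants -------------------------------------------------

def write_sv_tsv(svs: Iterable[SvRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "sv_type": s.sv_type,
            "support": s.support,
        }
        for s in svs
    ]
    write_tsv(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "sv_type", "support"]),
        path,
    )


def read_sv_tsv(path: str | Path) -> list[SvRecord]:
    df = read_tsv(path)
    return [
        SvRecord(
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            sv_type=str(r["sv_type"]),
            support=int(r["support"]),
        )
        for _, r in df.iterrows()
    ]


def read_sv_vcf(path: str | Path) -> list[SvRecord]:
    """SVs from a VCF with SVTYPE/END INFO keys (DEL/DUP records only)."""
    from cyvcf2 import VCF

    records = []
    for rec in VCF(str(path)):
        sv_type = rec.INFO.get("SVTYPE")
        if sv_type not in ("DEL", "DUP"):
            continue
        end = rec.INFO.get("END")
        support = rec.INFO.get("PE", 0) or 0
        records.append(
            SvRecord(
                chrom=rec.CHROM,
                start=rec.POS - 1,
                end=int(end),
                sv_type=sv_type,
                support=int(support),
            )
        )
    return records


# -- evidence / population AF -------------------------------------------

def _parse_variant_key(key: str) -> tuple[str, int, str, str]:
    parts = key.split(":")
    if len(parts) != 4:
        raise FormatError(f"variant key {key!r} is not chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return normalize_variant(chrom, int(pos), ref, alt)


def read_population_af(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """Max allele frequency per normalized variant over all cohorts."""
    df = read_tsv(path)
    out: dict[tuple[str, int, str, str], float] = {}
    for _, row in df.iterrows():
        key = _parse_variant_key(str(row["variant_key"]))
        out[key] = max(out.get(key, 0.0), float(row["af"]))
    return out


def read_evidence(
    path: str | Path,
    pop_af: Mapping[tuple[str, int, str, str], float] | None = None,
) -> dict[tuple[str, int, str, str], EvidenceSet]:
    """Evidence tags per normalized variant, merged with population AFs.

    Variants present only in the population table still get an EvidenceSet
    (their AF alone may trigger the stand-alone benign rule).
    """
    df = read_tsv(path)
    pop_af = dict(pop_af or {})
    out: dict[tuple[str, int, str, str], EvidenceSet] = {}
    for _, row in df.iterrows():
        key = _parse_variant_key(str(row["variant_key"]))
        tags = parse_tags(str(row["tags"])) if pd.notna(row["tags"]) else frozenset()
        out[key] = EvidenceSet(tags=tags, pop_af_max=pop_af.pop(key, 0.0))
    for key, af in pop_af.items():
        out[key] = EvidenceSet(pop_af_max=af)
    return out
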