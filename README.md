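# germpanel

Germline variant, copy-number and assay-validation analytics for targeted
hybridization-capture cancer-predisposition panels.

Clinical laboratories validating a targeted germline panel need more than a
variant caller: they need the analysis layer that sits on top of caller
output — coverage quality control at single-base resolution, principled
merging and filtering of two callers' calls, exon-level copy-number
detection against a pool of reference diploid normals, breakpoint
refinement from structural-variant evidence, 5-class ACMG interpretation,
and the statistics that justify the assay's thresholds (detection power,
false-positive characterization, replicate reproducibility). `germpanel`
implements that layer as an importable Python library with a thin
`germpanel` command-line interface, plus a synthetic-data generator that
emulates every input with planted ground truth, so the whole pipeline is
exercisable and testable without sequencing data.

## The models at the core

**Variant filtering.** Calls from two complementary callers are unified on
normalized `(chrom, pos, ref, alt)` keys (shared suffix then prefix
trimmed). A call passes when

- DP ≥ 50 and VF ≥ 0.20 for exonic SNVs/indels,
- DP ≥ 50 and VF ≥ 0.25 for noncoding (exon-flanking) calls,

where DP is total read depth and VF the alt-allele fraction; both bounds
are inclusive. Passing calls with VF in [0.40, 0.60] are heterozygous,
VF ≥ 0.90 homozygous. Calls that barely clear a threshold (DP < 60 or VF
within 0.03 of the cutoff) carry a *borderline* flag — these account for
most replicate-to-replicate discordance.

**Detection power.** With alt reads X ~ Binomial(d, v) at depth d and true
VF v, the filter detects the variant when X/d ≥ t, so sensitivity is the
exact binomial tail P(X ≥ ⌈t·d⌉). At d = 17, v = 0.5, t = 0.20 this is
0.9936 — 17X suffices for 99% heterozygous sensitivity, and 17 is the
smallest depth from which sensitivity never drops below 99% again (the
ceiling on required alt reads makes power non-monotone in depth).

**CNV calling.** Per-exon mean depths are scaled per sample by the exon
median (library-size normalization robust to real CNVs), then ratioed
against the mean of ≥ 2 reference diploid normals. Significance per exon is
a two-sided z-test of the sample's log2 value against the reference pool's
per-exon log2 distribution (SD floored at 0.05). An exon is called when
fold change > 1.3 with p < 0.05 (single-copy gain) or fold change < −1.7
with p < 0.05 (single-copy loss), with fold change in the signed-reciprocal
convention (ratio r for gains, −1/r for losses; a heterozygous deletion sits
at −2.0). Maximal runs of same-direction significant exons become segments,
whole-gene when they span every callable exon.

**SV reconciliation.** Coverage segments are matched to same-direction
DEL/DUP records (≥ 3 supporting reads) by maximal reciprocal overlap ≥ 0.5;
matched segments gain base-pair breakpoints and a note locating each
breakpoint in exon/intron anatomy ("starts within exon 10; ends ... 5' of
exon 18").

**ACMG classification.** Evidence tags (PVS1, PS1–4, PM1–6, PP1–5, BA1,
BS1–4, BP1–7) combine per the published ACMG/AMP rules into the 5-class
scale: benign (1), likely benign (2), VUS (3), likely pathogenic (4),
pathogenic (5). Population allele frequency > 5% in any supplied cohort is
stand-alone benign (BA1); two-sided evidence conflicts resolve to Class 3
with a conflict flag.

## Worked example

```bash
python examples/power_analysis.py
```

```
sensitivity for a heterozygous variant (VF 0.5) at 17X: 0.9936
minimum depth guaranteeing >= 99% sensitivity: 17X
```

The first line is the exact binomial tail P(X ≥ 4) for X ~ Binomial(17,
0.5): a heterozygous variant at 17 reads clears the 20% VF filter 99.4% of
the time. The second is the smallest depth from which that sensitivity is
guaranteed at every greater depth.

```bash
python examples/sv_refinement.py
```

```
coverage segment : BRCA1 exons 11-18 (loss)
SV evidence      : DEL chr17:41005925-41010800 (14 supporting read pairs)
refined interval : 41005925-41010800
boundary note    : starts within exon 10; ends in the intron between exons 17 and 18 (5' of exon 18)
```

Read-depth ratios resolved the deletion only to whole exons (11–18); the
split-read record shows it actually begins mid-exon-10 and stops at the
intron just 5' of exon 18 — the breakpoint-level description a clinical
report wants.

The other examples cover CNV spike recovery (`cnv_calling.py`), filtering
and classification (`filter_and_classify.py`), replicate concordance and
noise thresholds (`replicate_concordance.py`), and the full pipeline on a
generated bundle (`end_to_end.py`). The same capabilities are available as
CLI subcommands: `germpanel simulate | filter | cnv | power | concordance |
run`.

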