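# Methods

This note records the models, conventions and numerical choices behind
`germpanel`, what the synthetic generator does and does not emulate, and
the design decisions taken where more than one reasonable option existed.

## Panel model and coordinates

All internal coordinates are 0-based half-open (BED-native); 1-based
coordinates appear only at VCF-facing boundaries. A panel is an ordered set
of exon targets `(chrom, start, end, gene, exon_index, strand)`; exon
ordinals are 1-based within the gene's canonical transcript, so for
minus-strand genes they decrease with genomic position. Exon definitions
are taken as given in the input BED; transcript-model parsing is out of
scope.

Each exon owns up to `flank_bp` (default 50) of flanking intronic
sequence per side. In introns shorter than twice the flank the two flanks
would overlap, so both truncate at the intron midpoint — the genomically
upstream exon keeps the extra base of an odd-length intron. This makes
every intronic position belong to at most one exon's flank, which the
region classifier (`exonic` > `noncoding_flank` > `off_target`, exonic
winning all ties) and the flank-coverage profile both rely on. The
midpoint rule is a declared convention: nothing forces it, but any
alternative (first-come, proportional-to-exon-length) shares its
properties and none is observably better.

## Coverage QC

Exons are judged on their *minimum* per-position depth, not the mean: a
single under-covered base is a potential missed variant. The pass
threshold is 50X, inclusive. Positions absent from the input depth table
count as depth 0 — the conservative choice for a minimum statistic.
Duplicate `(sample, chrom, pos)` rows raise an error rather than being
silently aggregated, because duplication signals corrupt input, not an
alternative encoding.

"Consistently poorly performing" exons — those excluded from downstream
CNV calling — are operationalized as exons failing the minimum rule in
more than 50% of reference samples. The fraction is a configuration
default, not a derived constant.

The flank profile reports, for each distance d = 1..200, the mean depth
over all positions exactly d bp outside an exon boundary and the fraction
of flank regions of size d whose running minimum stays ≥ 50X. Positions
that fall inside another exon are excluded (they are not intronic), and a
region with no intronic positions at a given size counts as passing
vacuously. The fraction is non-increasing in d by construction.

## Variant filtering

Two callers' outputs are unified on normalized variant keys: the shared
allele suffix is trimmed first, then the shared prefix (each keeping at
least one base), adjusting the position for trimmed prefix bases. This
unifies padded representations of the same SNV always, and of indels
whenever the callers' representations differ only by shared padding; full
left-alignment against the reference genome is the upstream callers'
responsibility and is not re-done here. Within the merged record the
caller set is the union of provenances; when both callers report, DP and
VF come from caller A (a declared precedence — the data give no basis for
preferring either), and VF disagreements over 10 percentage points are
logged for review.

Filter thresholds are inclusive: DP ≥ 50 and VF ≥ 0.20 (exonic) / 0.25
(noncoding flank). Off-target calls never pass. Failure reasons are
recorded deterministically: region first, then depth, then allele
fraction. Zygosity bands are VF ∈ [0.40, 0.60] heterozygous and
VF ≥ 0.90 homozygous; everything between is reported as ambiguous and
never auto-resolved. The borderline flag (DP within 10 reads or VF within
0.03 of its threshold) marks passing calls likely to flicker across
replicates; both margins are configuration defaults. Indels of 30 bp or
more are deferred to the CNV/SV path rather than filtered as small
variants.

## CNV model

Per-exon mean depths form a samples × exons matrix with each sample
labelled `test` or `reference_normal`. Normalization divides each sample
by its own median over retained exons. The median rather than the mean is
deliberate: a true CNV spanning many exons shifts a mean-based size
factor toward itself and biases every other exon's ratio in the opposite
direction, which on a compact panel is enough to push null exons over the
gain threshold; the median stays anchored on the panel's diploid
majority. No GC or bait-efficiency correction is applied — exon-specific
capture efficiency is shared across samples and cancels in the ratio; a
hook for additional correction factors would slot in before
normalization.

For a test sample, each exon's ratio is its normalized value over the mean
of the reference normals' normalized values; the signed fold change is r
for r ≥ 1 and −1/r otherwise, the only convention under which a
heterozygous deletion (r = 0.5) satisfies the printed loss cutoff of
−1.7 at its expected −2.0. Significance is a two-sided one-sample z-test
of the sample's log2 value against the reference pool's per-exon log2 mean
and standard deviation (ddof = 1), with the SD floored at 0.05 log2 units
so that an unrealistically tight pool cannot declare trivial deviations
significant. At least 2 reference normals are required; below 10 a
warning is emitted because the SD estimate is unstable.

An exon is called significant when (fold change > 1.3 and p < 0.05) for
gains or (fold change < −1.7 and p < 0.05) for losses. Thresholds are
applied per exon exactly as stated, with no multiple-testing correction —
fidelity to the validated decision rule is preferred over statistical
taste, and the per-exon false rate this implies (~0.04 false segments per
gene under the default simulation conditions) is measured, not hidden.
Maximal runs of consecutive same-direction significant exons form
segments; a single intervening non-significant exon splits a run
(conservative — no gap bridging), which means a borderline exon can
fragment a whole-gene event into adjacent runs while the gene-level
interpretation remains clear. A segment's combined p (Fisher's method) is
reported for ranking only and plays no part in calling. Exons with zero
reference coverage are uncallable and excluded from both calling and the
whole-gene span definition.

## SV reconciliation

A coverage segment is matched to the same-direction SV record (DEL for
losses, DUP for gains; translocations and inversions are outside the
validated scope) with maximal reciprocal overlap against the segment's
genomic exon span, requiring reciprocal overlap ≥ 0.5 and ≥ 3 supporting
reads — both declared defaults. Ties break by higher support, then smaller
SV interval, then leftmost start, making the matching deterministic under
input permutation. Refinement adds breakpoint coordinates and a boundary
note locating each breakpoint in the gene's anatomy ("within exon k", "in
the intron between exons k and k+1 (5' of exon k+1)"), with start/end
reported in transcript orientation. Refinement never alters the
underlying segment's direction, scope, fold change or p-value. One SV may
refine segments of different genes independently; an unrefined segment
passes through unchanged.

## ACMG classification

The evidence-combining rules of the ACMG/AMP framework are implemented as
an explicit rule table over tag-category counts: a deliberate dependency
on the published guideline as *data*. Pathogenic and likely-pathogenic
qualification, and benign and likely-benign qualification, are evaluated
independently; if both sides qualify the call is Class 3 (VUS) with a
conflict flag, following the framework's treatment of contradictory
evidence. BA1 — population allele frequency strictly above 5% in any
supplied cohort table, the maximum across cohorts — is stand-alone benign
and is forced into the tag set whenever the frequency warrants it. No
evidence at all is VUS. The class/label mapping is fixed: benign 1,
likely benign 2, VUS 3, likely pathogenic 4, pathogenic 5; reporting
groups Class_1_2 / Class_3 / Class_4_5 follow the clinical convention.
Evidence derivation itself (predictors, segregation, database lookups) is
out of scope: tags arrive as input.

## Validation statistics

Detection power uses the exact binomial tail — never a normal
approximation, since the depths of interest are small. The detection rule
is "observed alt fraction clears the exonic VF threshold", i.e. success
needs X ≥ ⌈t·d⌉ alt reads. Because the ceiling jumps at depths where t·d
crosses an integer, power is non-monotone in depth: it reaches 99% for a
heterozygous variant at 14X, dips below at 16X, and only from 17X never
drops again. `min_depth_for_power` therefore returns the smallest depth
from which power stays at or above target for *all* larger depths (one
past the last failing depth, with the scan bounded by Hoeffding's
inequality), which is the operationally meaningful guarantee.

Noise characterization takes pre-filter replicate call sets from control
samples; a call is reproducible iff its normalized key appears in every
replicate of its control (strict all-replicates presence — reproducibility
is binary, not majority vote). The threshold sweep counts non-reproducible
calls surviving candidate DP/VF pairs; the validated thresholds are
checked to leave zero. Replicate concordance reports per-region-class call
counts, mean pairwise Jaccard on normalized keys, whether exonic sets are
identical, and the fraction of discordant calls carrying the borderline
flag. Barcode labels are carried through for reporting but never alter
computation.

## Synthetic data generator

The generator emulates the statistical structure of hybridization-capture
panel data with planted, machine-readable truth.

* **Panel geometry**: 20 genes of 4–20 exons (80–300 bp, introns
  ≥ 200 bp) on one chromosome, ≈ 240 exons — a scaled-down rendering of a
  76-gene / 1166-exon clinical panel, kept large enough that a whole-gene
  event is a small fraction of the panel (as in the real assay) while
  simulation rounds stay fast.
* **Depth model**: gamma-Poisson (negative binomial) per exon with a
  lognormal exon capture-efficiency factor (σ = 0.25) shared across
  samples, a per-sample library-size factor (uniform 0.7–1.3), mean exon
  depth 800 (matching observed panel coverage of ~800X), and total
  per-exon coefficient of variation 10% — a typical value for capture
  panels, entering as the binding noise parameter of the CNV recovery
  conditions. Copy ratios 0.5 / 1.5 model single-copy loss / gain in a
  diploid; 0.0 / 2.0 are available for homozygous events.
* **Variants**: each control sample receives reproducible true variants
  (VF drawn binomially at a Poisson-jittered DP — the same sampling model
  the power analysis assumes, so planted heterozygotes scatter around
  50%) and noise calls that appear in a strict subset of replicates and
  are clipped to stay below the validated DP or VF threshold (the
  structure observed for real non-reproducible artifacts). One planted
  noncoding variant sits deliberately near the 25% VF threshold to
  exercise the borderline machinery. Caller membership: both callers with
  probability 0.8 for true variants, predominantly one caller for noise.
* **SV records**: breakpoints bracketing each planted CNV's exon span,
  jittered up to 40 bp into the flanking sequence, with 5–40 supporting
  reads.
* **Determinism**: every generator function draws from its own seed
  stream derived from `(seed, stream-id)`, so outputs are byte-identical
  for a fixed seed and independent of call order.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: GC- and mappability-driven coverage waves
correlated across samples, homopolymer-context indel artifacts and local
realignment effects (a known source of depressed VF in noncoding calls),
pseudogene cross-mapping, batch effects between sequencing runs, and any
dependence between variants. Recovery rates measured here are therefore
upper bounds for panels whose reference pools are less homogeneous.

## Problem sizes used in checks

The shipped checks run the power analysis exactly; the noise and
concordance analyses on 13 controls × 3 replicates with 9 planted variant
classes per control; and CNV recovery over 100 simulation rounds of the
default panel (20 reference normals, one whole-gene 0.5 spike, one
single-exon 1.5 spike, one unspiked sample — ~2000 gene-rounds for the
false-call rate). These sizes give binomial standard errors of ~2–4
percentage points on the recovery rates while keeping a full run in
seconds.

## Known limitations

* The z-test treats per-exon log2 depths as normal; negative-binomial
  skew at low depth makes tail p-values slightly optimistic. The
  fold-change gate, not the p-value, is the binding constraint at
  realistic depths, so calling is insensitive to this.
* Per-exon thresholds without multiple-testing correction imply ~1
  expected false single-exon segment per ~500 null exons tested; on a
  large panel a reviewer should expect occasional single-exon false gains
  (they carry mild fold changes just over 1.3).
* Indel key normalization unifies padded representations, not arbitrary
  repeat-context shifts; callers are assumed to left-align.
* Whole-gene scope requires every callable exon to be individually
  significant; under noise a whole-gene event may be reported as several
  adjacent segments (direction and gene remain correct).
* The BA1 rule takes the maximum allele frequency over whichever
  population tables are supplied; curation of those tables (founder
  populations, cohort quality) is the user's responsibility.
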