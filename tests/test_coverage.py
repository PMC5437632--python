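import numpy as np
import pandas as pd
import pytest

from germpanel.coverage import (
    CoverageError,
    consistently_failing_exons,
    exon_coverage,
    flag_failing_exons,
    flank_coverage_profile,
)
from germpanel.panel import GenePanel, TargetRegion


def depth_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "depth"])


def constant_depths(panel, sample_id, depth, pad=250):
    rows = []
    lo = min(r.start for r in panel) - pad
    hi = max(r.end for r in panel) + pad
    for chrom in {r.chrom for r in panel}:
        for pos in range(lo, hi):
            rows.append((sample_id, chrom, pos, depth))
    return depth_frame(rows)


@pytest.fixture
def one_exon_panel():
    return GenePanel(regions=[TargetRegion("chr1", 100, 103, "G", 1)], flank_bp=50)


class TestExonCoverage:
    def test_three_position_exon(self, one_exon_panel):
        depths = depth_frame(
            [("S", "chr1", 100, 60), ("S", "chr1", 101, 55), ("S", "chr1", 102, 50)]
        )
        (stat,) = exon_coverage(one_exon_panel, depths, "S")
        assert stat.mean_depth == pytest.approx(55.0)
        assert stat.min_depth == 50
        assert stat.passes_min  # 50X boundary is inclusive

    def test_missing_position_counts_as_zero(self, one_exon_panel):
        depths = depth_frame([("S", "chr1", 100, 60), ("S", "chr1", 101, 55)])
        (stat,) = exon_coverage(one_exon_panel, depths, "S")
        assert stat.min_depth == 0
        assert not stat.passes_min

    def test_absent_sample_errors(self, one_exon_panel):
        depths = depth_frame([("S", "chr1", 100, 60)])
        with pytest.raises(CoverageError, match="absent"):
            exon_coverage(one_exon_panel, depths, "OTHER")

    def test_duplicate_rows_error(self, one_exon_panel):
        depths = depth_frame([("S", "chr1", 100, 60), ("S", "chr1", 100, 70)])
        with pytest.raises(CoverageError, match="duplicate"):
            exon_coverage(one_exon_panel, depths, "S")

    def test_matches_brute_force_oracle(self, rng):
        """Random 10-exon panel: stats equal a hand-rolled per-position loop."""
        regions, pos = [], 1000
        for i in range(1, 11):
            length = int(rng.integers(5, 30))
            regions.append(TargetRegion("chr1", pos, pos + length, "G", i))
            pos += length + 300
        panel = GenePanel(regions=regions, flank_bp=50)
        rows = []
        for r in regions:
            for p in range(r.start, r.end):
                if rng.random() < 0.9:  # some implicit zeros
                    rows.append(("S", "chr1", p, int(rng.integers(0, 200))))
        depths = depth_frame(rows)
        lookup = {(c, p): d for _, c, p, d in depths.itertuples(index=False)}
        stats = {(s.gene, s.exon_index): s for s in exon_coverage(panel, depths, "S")}
        for r in regions:
            vals = [lookup.get(("chr1", p), 0) for p in range(r.start, r.end)]
            s = stats[(r.gene, r.exon_index)]
            assert s.mean_depth == pytest.approx(sum(vals) / len(vals))
            assert s.min_depth == min(vals)

    def test_permutation_invariance(self, one_exon_panel):
        rows = [("S", "chr1", 100, 60), ("S", "chr1", 101, 55), ("S", "chr1", 102, 50)]
        a = exon_coverage(one_exon_panel, depth_frame(rows), "S")
        b = exon_coverage(one_exon_panel, depth_frame(rows[::-1]), "S")
        assert a == b


class TestFlagFailingExons:
    def test_all_pass_empty(self, one_exon_panel):
        depths = constant_depths(one_exon_panel, "S", 100)
        stats = exon_coverage(one_exon_panel, depths, "S")
        assert flag_failing_exons(stats) == []

    def test_boundary_49_fails(self, one_exon_panel):
        depths = constant_depths(one_exon_panel, "S", 49)
        stats = exon_coverage(one_exon_panel, depths, "S")
        assert flag_failing_exons(stats) == [("G", 1)]

    def test_planted_low_coverage_exons_flagged(self, rng):
        regions = [
            TargetRegion("chr1", 1000 * i, 1000 * i + 20, "G", i) for i in range(1, 9)
        ]
        panel = GenePanel(regions=regions, flank_bp=0)
        low = {2, 5, 7}
        rows = []
        for r in regions:
            d = 30 if r.exon_index in low else 200
            for p in range(r.start, r.end):
                rows.append(("S", "chr1", p, d + int(rng.integers(0, 10))))
        stats = exon_coverage(panel, depth_frame(rows), "S")
        assert set(flag_failing_exons(stats)) == {("G", i) for i in low}

    def test_consistently_failing_requires_majority(self, one_exon_panel):
        rows = []
        for sid, d in (("A", 10), ("B", 10), ("C", 100)):
            for p in range(100, 103):
                rows.append((sid, "chr1", p, d))
        failing = consistently_failing_exons(
            one_exon_panel, depth_frame(rows), ["A", "B", "C"]
        )
        assert failing == [("G", 1)]
        failing = consistently_failing_exons(
            one_exon_panel, depth_frame(rows), ["A", "C"]
        )
        assert failing == []  # 1 of 2 is not > 50%


class TestFlankProfile:
    def test_constant_field(self, one_exon_panel):
        depths = constant_depths(one_exon_panel, "S", 100)
        prof = flank_coverage_profile(one_exon_panel, depths, "S", max_flank=30)
        assert (prof["mean_depth"] == 100).all()
        assert (prof["fraction_ge_min"] == 1.0).all()

    def test_stepwise_decay_drops_beyond_100bp(self):
        panel = GenePanel(regions=[TargetRegion("chr1", 1000, 1100, "G", 1)],
                          flank_bp=50)
        rows = []
        for pos in range(700, 1400):
            if 1000 <= pos < 1100:
                d = 500
            else:
                dist = min(abs(pos - 999), abs(pos - 1100)) if pos < 1000 else pos - 1099
                dist = 1000 - pos if pos < 1000 else pos - 1099
                d = 200 if dist <= 100 else 0
            rows.append(("S", "chr1", pos, d))
        prof = flank_coverage_profile(
            panel, pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "depth"]),
            "S", max_flank=150,
        )
        prof = prof.set_index("distance")
        assert prof.loc[100, "fraction_ge_min"] == 1.0
        assert prof.loc[101, "fraction_ge_min"] == 0.0

    def test_matches_brute_force(self, toy_panel, rng):
        rows = []
        for chrom, lo, hi in (("chr1", 0, 900), ("chr2", 700, 1700)):
            for pos in range(lo, hi):
                rows.append(("S", chrom, pos, int(rng.integers(0, 300))))
        depths = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "depth"])
        lookup = {(c, p): d for _, c, p, d in depths.itertuples(index=False)}
        exonic = {
            (r.chrom, p) for r in toy_panel for p in range(r.start, r.end)
        }
        max_flank = 60
        prof = flank_coverage_profile(toy_panel, depths, "S", max_flank=max_flank)
        for d in (1, 7, 33, 60):
            vals, region_mins = [], []
            for r in toy_panel:
                for side_positions in (
                    [(r.chrom, r.start - k) for k in range(1, d + 1)],
                    [(r.chrom, r.end - 1 + k) for k in range(1, d + 1)],
                ):
                    intronic = [p for p in side_positions if p not in exonic]
                    vals_side = [lookup.get(p, 0) for p in intronic]
                    if intronic:
                        region_mins.append(min(vals_side))
                    else:
                        region_mins.append(float("inf"))
            # mean at exactly distance d
            at_d = []
            for r in toy_panel:
                for p in ((r.chrom, r.start - d), (r.chrom, r.end - 1 + d)):
                    if p not in exonic:
                        at_d.append(lookup.get(p, 0))
            row = prof[prof["distance"] == d].iloc[0]
            assert row["mean_depth"] == pytest.approx(np.mean(at_d))
            assert row["fraction_ge_min"] == pytest.approx(
                np.mean([m >= 50 for m in region_mins])
            )

    def test_fraction_non_increasing(self, toy_panel, rng):
        rows = []
        for chrom, lo, hi in (("chr1", 0, 900), ("chr2", 700, 1700)):
            for pos in range(lo, hi):
                rows.append(("S", chrom, pos, int(rng.integers(0, 300))))
        depths = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "depth"])
        prof = flank_coverage_profile(toy_panel, depths, "S", max_flank=120)
        frac = prof["fraction_ge_min"].to_numpy()
        assert (np.diff(frac) <= 1e-12).all()
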