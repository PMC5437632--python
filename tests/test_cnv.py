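import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from germpanel.cnv import (
    GAIN,
    LOSS,
    WHOLE_GENE,
    INTRAGENIC,
    CnvError,
    DepthMatrix,
    call_sample,
    call_segments,
    exon_ratios,
    normalize,
    signed_fold_change,
    ExonRatio,
)


def matrix_from(values: dict, n_ref: int, exons=None) -> DepthMatrix:
    samples = list(values)
    exons = exons or [("G", i + 1) for i in range(len(next(iter(values.values()))))]
    roles = {
        s: ("reference_normal" if i < n_ref else "test")
        for i, s in enumerate(samples)
    }
    return DepthMatrix(
        values=pd.DataFrame(
            values, index=pd.MultiIndex.from_tuples(exons, names=["gene", "exon_index"])
        ),
        roles=roles,
    )


def random_matrix(rng, n_exons=30, n_ref=20, ratio_by_exon=None):
    """Reference pool + one test sample ('T') with optional spiked ratios."""
    efficiency = rng.lognormal(0, 0.25, n_exons)
    values = {}
    for i in range(n_ref):
        scale = rng.uniform(0.7, 1.3)
        values[f"N{i:02d}"] = rng.normal(1, 0.10, n_exons).clip(0.5) * 800 * scale * efficiency
    ratios = np.ones(n_exons) if ratio_by_exon is None else np.asarray(ratio_by_exon)
    scale = rng.uniform(0.7, 1.3)
    values["T"] = rng.normal(1, 0.10, n_exons).clip(0.5) * 800 * scale * efficiency * ratios
    return matrix_from(values, n_ref)


class TestFoldChange:
    def test_het_deletion_is_minus_two(self):
        assert signed_fold_change(0.5) == pytest.approx(-2.0)

    def test_neutral_is_plus_one(self):
        assert signed_fold_change(1.0) == 1.0

    def test_antisymmetry_on_ratio_grid(self):
        for r in np.linspace(0.05, 0.999, 200):
            assert signed_fold_change(r) == pytest.approx(-signed_fold_change(1 / r))

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(CnvError):
            signed_fold_change(0.0)


class TestNormalize:
    def test_uniform_sample_maps_to_one(self):
        m = matrix_from({"A": [500.0] * 5, "B": [200.0] * 5}, n_ref=2)
        norm = normalize(m)
        assert np.allclose(norm.values.to_numpy(), 1.0)

    def test_scale_invariance(self, rng):
        base = rng.uniform(100, 1000, 8)
        m1 = matrix_from({"A": base, "B": base * 2.0}, n_ref=2)
        norm = normalize(m1)
        assert np.allclose(norm.values["A"], norm.values["B"])

    def test_matches_per_sample_median_division(self, rng):
        vals = {s: rng.uniform(50, 1500, 12) for s in ("A", "B", "C")}
        norm = normalize(matrix_from(vals, n_ref=3))
        for s, v in vals.items():
            assert np.allclose(norm.values[s], v / np.median(v))

    def test_zero_sample_errors(self):
        with pytest.raises(CnvError, match="zero"):
            normalize(matrix_from({"A": [0.0] * 4, "B": [1.0] * 4}, n_ref=2))


class TestExonRatios:
    def test_null_exon_is_neutral(self, rng):
        m = random_matrix(rng)
        ratios = exon_ratios(m, "T")
        fc = np.array([r.fold_change for r in ratios])
        assert np.abs(np.log2([abs(f) for f in fc])).mean() < 0.2

    def test_spiked_loss_near_minus_two(self, rng):
        spikes = np.ones(30)
        spikes[5:10] = 0.5
        m = random_matrix(rng, ratio_by_exon=spikes)
        ratios = {r.exon_index: r for r in exon_ratios(m, "T")}
        spiked_fc = [ratios[i + 1].fold_change for i in range(5, 10)]
        assert np.mean(spiked_fc) == pytest.approx(-2.0, rel=0.15)
        assert all(r < -1.5 for r in spiked_fc)

    def test_requires_two_reference_normals(self, rng):
        m = matrix_from({"A": [1.0] * 4, "T": [1.0] * 4}, n_ref=1)
        with pytest.raises(CnvError, match="reference"):
            exon_ratios(m, "T")

    def test_unknown_sample_errors(self, rng):
        with pytest.raises(CnvError, match="unknown"):
            exon_ratios(random_matrix(rng), "NOPE")

    def test_z_pvalues_match_monte_carlo_oracle(self, rng):
        """z-tail p-values agree with a 10,000-draw simulation from the
        reference pool's fitted log2 distribution, within Monte-Carlo error,
        at 50 random exons."""
        m = random_matrix(rng, n_exons=50)
        norm = normalize(m)
        refs = norm.values[[c for c in norm.values.columns if c != "T"]]
        ratios = exon_ratios(m, "T")
        n_draws = 10_000
        for r in ratios:
            log2_refs = np.log2(refs.loc[(r.gene, r.exon_index)].to_numpy())
            mu, sd = log2_refs.mean(), max(log2_refs.std(ddof=1), 0.05)
            test_val = np.log2(norm.values.loc[(r.gene, r.exon_index), "T"])
            draws = rng.normal(mu, sd, n_draws)
            p_mc = np.mean(np.abs(draws - mu) >= abs(test_val - mu))
            se = np.sqrt(max(p_mc * (1 - p_mc), 1e-6) / n_draws)
            assert abs(r.p_value - p_mc) <= 4 * se + 0.005, (r, p_mc)


class TestCallSegments:
    def make_ratios(self, gene, fcs_ps):
        out = []
        for i, (fc, p) in enumerate(fcs_ps, start=1):
            ratio = fc if fc >= 1 else -1.0 / fc
            out.append(
                ExonRatio(gene=gene, exon_index=i, ratio=ratio,
                          log2_ratio=np.log2(ratio), fold_change=fc, p_value=p)
            )
        return out

    def test_whole_gene_loss(self):
        ratios = self.make_ratios("MSH2L", [(-2.0, 1e-6)] * 6)
        (seg,) = call_segments(ratios)
        assert seg.direction == LOSS
        assert seg.scope == WHOLE_GENE
        assert (seg.first_exon, seg.last_exon) == (1, 6)

    def test_intragenic_gain_exons_5_to_11(self):
        fcs = [(1.0, 0.9)] * 4 + [(1.5, 1e-4)] * 7 + [(1.0, 0.8)] * 4
        (seg,) = call_segments(self.make_ratios("BRCA2L", fcs))
        assert seg.direction == GAIN
        assert seg.scope == INTRAGENIC
        assert (seg.first_exon, seg.last_exon) == (5, 11)

    def test_loss_above_threshold_not_called(self):
        # -1.6 is milder than the -1.7 loss cutoff, however significant
        ratios = self.make_ratios("G", [(-1.6, 0.001)])
        assert call_segments(ratios) == []

    def test_gap_splits_segment(self):
        fcs = [(-2.0, 1e-6), (-1.0, 0.9), (-2.0, 1e-6)]
        segs = call_segments(self.make_ratios("G", fcs))
        assert [(s.first_exon, s.last_exon) for s in segs] == [(1, 1), (3, 3)]

    def test_direction_change_splits_segment(self):
        fcs = [(-2.0, 1e-6), (1.5, 1e-6)]
        segs = call_segments(self.make_ratios("G", fcs))
        assert {s.direction for s in segs} == {LOSS, GAIN}

    def test_combined_p_is_fisher(self):
        ratios = self.make_ratios("G", [(-2.0, 0.01), (-2.0, 0.02)])
        (seg,) = call_segments(ratios)
        expected = sps.combine_pvalues([0.01, 0.02], method="fisher")[1]
        assert seg.combined_p == pytest.approx(expected)


class TestEndToEndProperties:
    def test_scale_invariance_of_calls(self, rng):
        spikes = np.ones(30)
        spikes[0:6] = 0.5
        m = random_matrix(rng, ratio_by_exon=spikes)
        calls1 = call_sample(m, "T")
        scaled = m.values.copy()
        scaled["T"] = scaled["T"] * 7.3
        calls2 = call_sample(DepthMatrix(scaled, dict(m.roles)), "T")
        assert len(calls1) == len(calls2)
        for a, b in zip(calls1, calls2):
            assert (a.gene, a.first_exon, a.last_exon, a.direction, a.scope) == (
                b.gene, b.first_exon, b.last_exon, b.direction, b.scope
            )
            assert a.mean_fold_change == pytest.approx(b.mean_fold_change)
            assert a.combined_p == pytest.approx(b.combined_p, rel=1e-6)

    def test_null_false_call_rate_below_alpha(self, rng):
        """>= 2000 unspiked exon draws: significant-exon rate stays under
        alpha (the fold-change gate makes it far lower)."""
        n_sig = n_tot = 0
        for _ in range(4):
            m = random_matrix(rng, n_exons=500)
            ratios = exon_ratios(m, "T")
            n_tot += len(ratios)
            n_sig += sum(
                1 for r in ratios
                if (r.fold_change > 1.3 or r.fold_change < -1.7) and r.p_value < 0.05
            )
        assert n_tot >= 2000
        assert n_sig / n_tot <= 0.05
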