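import math

import numpy as np
import pandas as pd
import pytest

from germpanel.panel import EXONIC, NONCODING_FLANK
from germpanel.valstats import (
    ReplicateSet,
    ValidationError,
    characterize_noise,
    detection_power,
    min_depth_for_power,
    power_table,
    replicate_concordance,
    surviving_noise_count,
)
from germpanel.variants import VariantCall


def brute_force_power(depth: int, p: float, threshold: float) -> float:
    """Exhaustive binomial enumeration, independent of scipy tails."""
    k_min = math.ceil(threshold * depth - 1e-9)
    return sum(
        math.comb(depth, k) * p**k * (1 - p) ** (depth - k)
        for k in range(k_min, depth + 1)
    )


def call(pos, DP=100, VF=0.5, region=EXONIC, borderline=False, status="pass"):
    return VariantCall(
        chrom="chr1", pos=pos, ref="A", alt="T",
        callers=frozenset({"caller_A"}), DP=DP, VF=VF,
        region_class=region, filter_status=status, borderline=borderline,
    )


class TestDetectionPower:
    def test_17x_heterozygous_at_20pct_threshold(self):
        """17 reads detect a 50%-VF variant with >= 99% sensitivity; the
        exact tail is 1 - (C(17,0)+C(17,1)+C(17,2)+C(17,3)) / 2^17."""
        expected = 1 - (1 + 17 + 136 + 680) / 2**17
        got = detection_power(17, 0.5, 0.20)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got >= 0.99

    def test_certain_success_at_full_vf(self):
        for depth in (1, 10, 100):
            assert detection_power(depth, 1.0, 0.5) == 1.0

    def test_matches_exhaustive_enumeration(self):
        for depth in (1, 5, 17, 40):
            for vf in (0.3, 0.5, 0.9):
                for thr in (0.1, 0.2, 0.25, 0.5):
                    assert detection_power(depth, vf, thr) == pytest.approx(
                        brute_force_power(depth, vf, thr), abs=1e-10
                    )

    def test_matches_monte_carlo_oracle(self, rng):
        """Depth 10, 10^6 binomial draws: empirical detection rate within
        3 standard errors over a threshold grid."""
        draws = rng.binomial(10, 0.5, size=1_000_000)
        for thr in (0.1, 0.2, 0.3, 0.45, 0.6):
            k = math.ceil(thr * 10 - 1e-9)
            emp = float(np.mean(draws >= k))
            exact = detection_power(10, 0.5, thr)
            se = math.sqrt(max(emp * (1 - emp), 1e-9) / 1_000_000)
            assert abs(exact - emp) <= 3 * se + 1e-6

    def test_monotone_in_true_vf(self):
        for depth in (17, 60):
            powers = [detection_power(depth, v, 0.2) for v in np.linspace(0.05, 1, 40)]
            assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_no_wobble_from_17x_onwards(self):
        """Sensitivity stays >= 99% at every depth 17..500 despite the
        ceiling effect on the required alt-read count."""
        assert all(detection_power(d, 0.5, 0.20) >= 0.99 for d in range(17, 501))
        # and 16X genuinely dips below — the wobble the rule guards against
        assert detection_power(16, 0.5, 0.20) < 0.99

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            detection_power(0, 0.5, 0.2)
        with pytest.raises(ValidationError):
            detection_power(10, 0.0, 0.2)


class TestMinDepthForPower:
    def test_heterozygous_20pct_requires_17x(self):
        assert min_depth_for_power(0.5, 0.20, 0.99) == 17

    def test_full_vf_needs_one_read(self):
        assert min_depth_for_power(1.0, 0.5, 0.99) == 1

    def test_agrees_with_exhaustive_scan_oracle(self):
        """Guaranteed depth = one past the last depth failing the target,
        scanning an enumeration oracle far beyond the answer."""
        for vf, thr, target in [(0.5, 0.25, 0.99), (0.5, 0.20, 0.95), (0.4, 0.2, 0.99)]:
            got = min_depth_for_power(vf, thr, target)
            last_fail = max(
                (d for d in range(1, 400) if brute_force_power(d, vf, thr) < target),
                default=0,
            )
            assert got == last_fail + 1

    def test_nonconverging_setup_rejected(self):
        with pytest.raises(ValidationError, match="exceed"):
            min_depth_for_power(0.2, 0.25, 0.99)

    def test_power_table_grid(self):
        table = power_table([10, 17], [0.5, 1.0], 0.2)
        assert len(table) == 4
        row = table[(table.depth == 17) & (table.true_vf == 0.5)].iloc[0]
        assert row["sensitivity"] == pytest.approx(detection_power(17, 0.5, 0.2))


class TestCharacterizeNoise:
    def controls_with(self, noise_dp, noise_vf, region=EXONIC):
        """One control, 3 replicates: a reproducible true call plus one
        noise call present in a single replicate."""
        reps = [[call(100)] for _ in range(3)]  # reproducible true call
        reps[0].append(call(555, DP=noise_dp, VF=noise_vf, region=region))
        return {"CTRL": reps}

    def test_below_threshold_noise_eliminated(self):
        table, sweep, ok = characterize_noise(self.controls_with(30, 0.15))
        assert ok
        assert surviving_noise_count(table) == 0
        assert (~table["reproducible"]).sum() == 1

    def test_planted_violation_detected(self):
        # noise at DP 60 / VF 0.30 clears both thresholds -> check fails
        table, sweep, ok = characterize_noise(self.controls_with(60, 0.30))
        assert not ok
        assert surviving_noise_count(table) > 0

    def test_survival_matches_brute_force(self, rng):
        reps = [[], [], []]
        truth = []
        for i in range(60):
            dp = int(rng.integers(10, 120))
            vf = float(rng.uniform(0.02, 0.6))
            region = EXONIC if rng.random() < 0.5 else NONCODING_FLANK
            present = set(rng.choice(3, size=int(rng.integers(1, 4)), replace=False))
            for r in present:
                reps[r].append(call(1000 + i, DP=dp, VF=vf, region=region))
            truth.append((dp, vf, region, len(present) == 3))
        table, sweep, ok = characterize_noise({"C": reps})
        for dp_thr, vf_ex in [(50, 0.20), (40, 0.15), (60, 0.25)]:
            got = surviving_noise_count(table, dp_thr, vf_ex, vf_ex + 0.05)
            want = sum(
                1 for dp, vf, region, reproducible in truth
                if not reproducible and dp >= dp_thr
                and vf >= (vf_ex if region == EXONIC else vf_ex + 0.05)
            )
            assert got == want

    def test_survival_non_increasing_in_thresholds(self, rng):
        reps = [[], []]
        for i in range(40):
            dp, vf = int(rng.integers(5, 150)), float(rng.uniform(0, 0.7))
            for r in list(set(rng.choice(2, size=int(rng.integers(1, 3))).tolist())):
                reps[r].append(call(2000 + i, DP=dp, VF=vf))
        table, _, _ = characterize_noise({"C": reps})
        prev = None
        for dp_thr in (20, 40, 60, 80):
            n = surviving_noise_count(table, dp_thr, 0.1, 0.15)
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for vf_ex in (0.05, 0.15, 0.25, 0.35):
            n = surviving_noise_count(table, 30, vf_ex, vf_ex + 0.05)
            if prev is not None:
                assert n <= prev
            prev = n

    def test_single_replicate_control_excluded(self):
        table, sweep, ok = characterize_noise({"C": [[call(100)]]})
        assert table.empty and ok


class TestReplicateConcordance:
    def test_identical_replicates(self):
        reps = [[call(100), call(250, region=NONCODING_FLANK)] for _ in range(3)]
        rs = ReplicateSet("S", reps, ["R1", "R1", "R1"])
        out = replicate_concordance(rs)
        assert rs.design == "intra_run"
        assert out["jaccard_exonic"] == 1.0
        assert out["jaccard_noncoding"] == 1.0
        assert out["all_identical_exonic"]
        assert out["n_discordant"] == 0

    def test_borderline_noncoding_discordance(self):
        shared = [call(100), call(250, region=NONCODING_FLANK)]
        extra = call(300, DP=52, VF=0.26, region=NONCODING_FLANK, borderline=True)
        reps = [shared + [extra], list(shared), list(shared)]
        rs = ReplicateSet("S", reps, ["R1", "R2", "R3"])
        out = replicate_concordance(rs)
        assert rs.design == "inter_run"
        assert out["jaccard_exonic"] == 1.0
        assert out["jaccard_noncoding"] < 1.0
        assert out["all_identical_exonic"]
        assert out["borderline_explained"] == 1.0

    def test_jaccard_matches_set_arithmetic(self, rng):
        keysets = [
            set(rng.choice(range(100, 160), size=20, replace=False).tolist())
            for _ in range(3)
        ]
        reps = [[call(int(p)) for p in ks] for ks in keysets]
        rs = ReplicateSet("S", reps, ["R1", "R2", "R3"])
        out = replicate_concordance(rs)
        pairs = [(0, 1), (0, 2), (1, 2)]
        expected = np.mean(
            [len(keysets[a] & keysets[b]) / len(keysets[a] | keysets[b])
             for a, b in pairs]
        )
        assert out["jaccard_exonic"] == pytest.approx(float(expected))

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            ReplicateSet("S", [[call(100)]], ["R1"])
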