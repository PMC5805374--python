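import numpy as np
import pandas as pd
import pytest

from ribojam.profiles import (
    OccupancyProfile,
    call_peaks,
    detect_offset,
    downsample,
    feature_correlations,
    metagene,
    missing_mrpf,
    nfc,
    redistribute_multimapped,
    rpkm,
)


def prof(counts, gene="g", cls="mRPF"):
    return OccupancyProfile(gene, cls, np.asarray(counts, dtype=float))


class TestDetectOffset:
    def metagene_with_peak(self, peak_pos, background=1.0):
        return {p: (50.0 if p == peak_pos else background) for p in range(-50, 51)}

    def test_peak_in_window_returns_distance(self):
        assert detect_offset(self.metagene_with_peak(-15)) == 15

    def test_peak_outside_window_discards_read_length(self):
        assert detect_offset(self.metagene_with_peak(-25)) is None
        assert detect_offset(self.metagene_with_peak(-3)) is None

    def test_larger_peak_outside_window_discards(self):
        m = self.metagene_with_peak(-12)
        m[10] = 60.0  # downstream maximum dominates
        assert detect_offset(m) is None

    def test_fallback_mode(self):
        assert detect_offset(self.metagene_with_peak(-25), fallback=15) == 15
        assert detect_offset({}, fallback=15) == 15

    def test_empty_metagene_discards(self):
        assert detect_offset({}) is None


class TestRedistribute:
    def test_weights_proportional_to_window_density(self):
        uniq = {"a": np.zeros(300), "b": np.zeros(300)}
        uniq["a"][100:110] = 3.0  # window sum 30
        uniq["b"][100:110] = 1.0  # window sum 10
        out = redistribute_multimapped([("a", 105), ("b", 105)], uniq)
        assert [w for *_, w in out] == pytest.approx([0.75, 0.25])

    def test_empty_windows_split_uniformly(self):
        uniq = {"a": np.zeros(50)}
        out = redistribute_multimapped([("a", 10), ("a", 30), ("b", 5)], uniq)
        assert [w for *_, w in out] == pytest.approx([1 / 3] * 3)

    def test_three_way_split(self):
        uniq = {"a": np.ones(1000)}
        out = redistribute_multimapped(
            [("a", 100), ("a", 500), ("a", 900)], uniq, window=10
        )
        assert [w for *_, w in out] == pytest.approx([1 / 3, 1 / 3, 1 / 3])
        assert sum(w for *_, w in out) == pytest.approx(1.0)

    def test_mass_conserved_on_random_inputs(self):
        rng = np.random.default_rng(0)
        uniq = {"a": rng.poisson(2.0, 400).astype(float)}
        for _ in range(50):
            cands = [("a", int(p)) for p in rng.integers(0, 400, rng.integers(2, 6))]
            out = redistribute_multimapped(cands, uniq)
            assert sum(w for *_, w in out) == pytest.approx(1.0)


class TestRpkmNfc:
    def test_rpkm_definition(self):
        # 300 reads on a 1 kb ORF with 1e6 mapped reads -> 300
        p = prof(np.full(333, 300 / 333))
        assert rpkm(p, 1e6) == pytest.approx(300, rel=2e-3)
        assert rpkm(p, 2e6) == pytest.approx(150, rel=2e-3)

    def test_rpkm_invariant_to_position_split(self):
        a = prof([30, 0, 0, 0])
        b = prof([10, 10, 5, 5])
        assert rpkm(a, 1e6) == pytest.approx(rpkm(b, 1e6))

    def test_nfc_mean_is_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = prof(rng.poisson(3.0, 50))
            if p.total == 0:
                continue
            assert nfc(p).mean() == pytest.approx(1.0)

    def test_nfc_examples(self):
        assert np.allclose(nfc(prof([0, 2, 4])), [0, 1, 2])
        assert np.allclose(nfc(prof([7, 7, 7])), 1.0)
        assert nfc(prof([0, 0, 0])) is None


class TestCallPeaks:
    def test_single_outlier_called(self):
        counts = np.full(100, 2.0)
        counts[40] = 60.0
        nz = counts[counts > 0]
        assert nz.mean() + 5 * nz.std() < 60
        assert list(call_peaks(prof(counts))) == [40]

    def test_uniform_profile_has_no_peaks(self):
        assert len(call_peaks(prof(np.full(50, 3.0)))) == 0

    def test_zeros_ignored_in_threshold(self):
        # mean over nonzero only: zeros must not drag the threshold down
        counts = np.zeros(200)
        counts[:20] = 5.0
        counts[100] = 6.0  # mild bump, not 5 SDs above the nonzero mean
        assert len(call_peaks(prof(counts))) == 0

    def test_agrees_with_bruteforce_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            counts = rng.poisson(1.0, 80).astype(float)
            counts[rng.integers(0, 80)] *= rng.integers(1, 30)
            p = prof(counts)
            nz = counts[counts > 0]
            if len(nz) < 2:
                continue
            thr = nz.mean() + 5 * nz.std()
            expected = sorted(np.flatnonzero(counts >= thr))
            assert list(call_peaks(p)) == expected

    def test_fewer_than_two_nonzero_positions(self):
        assert len(call_peaks(prof([0, 0, 9, 0]))) == 0


class TestMetagene:
    def make_profiles(self, rng, n_genes=60, length=300):
        return {
            f"g{i}": np.maximum(rng.normal(1.0, 0.3, length), 0.0)
            for i in range(n_genes)
        }

    def test_random_anchors_give_background_ratio_near_one(self):
        rng = np.random.default_rng(3)
        profiles = self.make_profiles(rng)
        anchors = [
            (g, int(rng.integers(30, 270))) for g in profiles for _ in range(2)
        ]
        res = metagene(profiles, anchors, window=(20, 20), n_resamples=300, seed=4)
        assert res.background_ratio == pytest.approx(1.0, abs=0.05)
        assert res.p_value > 0.01
        assert res.null_band[0] <= res.null_band[1]

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(5)
        profiles = self.make_profiles(rng, n_genes=100)
        anchors = []
        for g, profm in profiles.items():
            pos = int(rng.integers(40, 260))
            profm[pos - 5 : pos + 6] *= 2.0  # planted 2x NFC bump
            anchors.append((g, pos))
        res = metagene(profiles, anchors * 2, window=(10, 10), n_resamples=500, seed=6)
        assert res.background_ratio > 1.0
        assert res.p_value < 0.01

    def test_out_of_bounds_anchors_skipped(self):
        profiles = {"g": np.ones(50)}
        res = metagene(profiles, [("g", 2), ("g", 25)], window=(10, 10),
                       n_resamples=50, seed=0)
        assert res.n_anchors == 1

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            metagene({"g": np.ones(50)}, [], window=(5, 5))


class TestDownsample:
    def test_identity_and_zero(self):
        ps = [prof([3, 4, 5]), prof([0, 8, 0], gene="h")]
        same = downsample(ps, 20, seed=1)
        assert sum(p.total for p in same) == 20
        assert np.array_equal(same[0].counts, [3, 4, 5])
        empty = downsample(ps, 0, seed=1)
        assert all(p.total == 0 for p in empty)

    def test_target_above_total_rejected(self):
        with pytest.raises(ValueError):
            downsample([prof([1, 1])], 5)

    def test_totals_exact_and_expectation_scales(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(5.0, 40).astype(float)
        ps = [prof(base)]
        total = int(base.sum())
        target = total // 2
        acc = np.zeros_like(base)
        n_rep = 100
        for s in range(n_rep):
            out = downsample(ps, target, seed=s)
            assert out[0].total == target
            acc += out[0].counts
        expected = base * target / total
        se = np.sqrt(expected * (1 - target / total) / n_rep) + 1e-9
        assert np.all(np.abs(acc / n_rep - expected) < 5 * se)


class TestMissingMrpf:
    def test_uniform_profiles_flag_nothing(self):
        m = prof(np.full(300, 4.0))
        d = prof(np.full(300, 4.0), cls="dRPF")
        positions, fractions = missing_mrpf(m, d)
        # a value shared by all positions is never "extreme"
        assert len(positions) == 0
        assert fractions["all"] == 0.0

    def test_constructed_missing_positions_found(self):
        n = 100
        mcounts = np.full(n, 10.0)
        dcounts = np.full(n, 1.0)
        planted = [3, 20, 50, 77, 98]
        for i in planted:
            mcounts[i] = 0.0
            dcounts[i] = 30.0
        positions, fractions = missing_mrpf(
            prof(mcounts), prof(dcounts, cls="dRPF"), region=30
        )
        assert list(positions) == planted
        assert fractions["all"] == pytest.approx(0.05)

    def test_low_coverage_gene_excluded(self):
        m = prof(np.full(200, 5.0))
        d = np.zeros(200)
        d[:10] = 1.0  # 5% coverage < 10%
        assert missing_mrpf(m, prof(d, cls="dRPF")) is None

    def test_region_fractions(self):
        n = 400
        mcounts = np.full(n, 10.0)
        dcounts = np.full(n, 1.0)
        for i in range(0, 20):  # all flagged positions in the first region
            mcounts[i] = 0.0
            dcounts[i] = 50.0
        _, fr = missing_mrpf(prof(mcounts), prof(dcounts, cls="dRPF"))
        assert fr["first"] == pytest.approx(0.20)
        assert fr["middle"] == 0.0 and fr["last"] == 0.0

    def test_quantile_oracle_on_random_profiles(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            m = rng.poisson(6.0, 150).astype(float)
            d = rng.poisson(2.0, 150).astype(float)
            if np.count_nonzero(d) < 15:
                continue
            out = missing_mrpf(prof(m), prof(d, cls="dRPF"))
            assert out is not None
            positions, _ = out
            # oracle by sorting: empirical CDF tail fractions per position
            expected = np.flatnonzero(
                np.array(
                    [
                        (np.mean(m <= mi) <= 0.10) and (np.mean(d >= di) <= 0.10)
                        for mi, di in zip(m, d)
                    ]
                )
            )
            assert np.array_equal(positions, expected)


class TestFeatureCorrelations:
    def test_statistic_equal_to_feature(self):
        rng = np.random.default_rng(9)
        n = 300
        feats = pd.DataFrame(
            {"f1": rng.normal(size=n), "f2": rng.normal(size=n)},
            index=[f"g{i}" for i in range(n)],
        )
        stat = dict(zip(feats.index, feats["f1"] + 0.01 * rng.normal(size=n)))
        table = feature_correlations(stat, feats)
        assert table.loc["f1", "rho"] > 0.95
        assert abs(table.loc["f2", "rho"]) < 0.15

    def test_independent_statistic_is_null(self):
        rng = np.random.default_rng(10)
        n = 1000
        feats = pd.DataFrame(
            {c: rng.normal(size=n) for c in ("a", "b", "c")},
            index=[f"g{i}" for i in range(n)],
        )
        stat = dict(zip(feats.index, rng.normal(size=n)))
        table = feature_correlations(stat, feats)
        assert np.all(np.abs(table["rho"]) < 0.1)

    def test_constant_feature_dropped(self):
        rng = np.random.default_rng(11)
        n = 50
        feats = pd.DataFrame(
            {"ok": rng.normal(size=n), "const": np.ones(n)},
            index=[f"g{i}" for i in range(n)],
        )
        stat = dict(zip(feats.index, rng.normal(size=n)))
        table = feature_correlations(stat, feats)
        assert "const" not in table.index and "ok" in table.index

    def test_too_few_cases_rejected(self):
        feats = pd.DataFrame({"f": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            feature_correlations({"a": 1.0, "b": 2.0}, feats)
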