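import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.stats import chisquare
from sklearn.metrics import adjusted_rand_score

from rhythmscan.core import Detector, RhythmCall
from rhythmscan.downstream import (
    classify_ld_dd_type,
    classify_ld_dd_types,
    hierarchical_cluster,
    ld_dd_fold,
    peak_nadir_amplitude,
    phase_distribution,
    zscore_profiles,
)
from rhythmscan.jtk import run_jtk
from rhythmscan.simulate import SimulationSpec, simulate_ld_dd_pair

from conftest import make_matrix


def _jtk_call(probe, q, phase):
    return RhythmCall(probe_id=probe, detector=Detector.JTK, statistic=q,
                      period_hr=24.0, peak_phase_hr=phase, period_ok=True)


class TestPhaseDistribution:
    def test_hand_counted_bins(self):
        calls = [_jtk_call("a", 0.01, 2.0), _jtk_call("b", 0.01, 2.0),
                 _jtk_call("c", 0.01, 14.0)]
        dist = phase_distribution(calls, bin_width_hr=4.0)
        by_center = dict(zip(dist.bin_centers, dist.percentages))
        assert by_center[0.0] == pytest.approx(200 / 3)   # (22, 2]
        assert by_center[12.0] == pytest.approx(100 / 3)  # (10, 14]
        assert dist.percentages.sum() == pytest.approx(100.0)

    def test_lowest_q_probe_per_gene(self):
        calls = [_jtk_call("p1", 0.01, 4.0), _jtk_call("p2", 0.04, 16.0)]
        gene_map = {"p1": "g", "p2": "g"}
        dist = phase_distribution(calls, gene_map, bin_width_hr=4.0)
        assert dist.counts.sum() == 1
        assert dict(zip(dist.bin_centers, dist.counts))[4.0] == 1

    def test_non_rhythmic_excluded(self):
        calls = [_jtk_call("a", 0.5, 4.0)]
        dist = phase_distribution(calls, q_max=0.05)
        assert dist.counts.sum() == 0

    def test_uniform_phases_approximately_flat(self):
        rng = np.random.default_rng(0)
        calls = [_jtk_call(f"p{i}", 0.001, rng.uniform(0, 24)) for i in range(1200)]
        dist = phase_distribution(calls, bin_width_hr=3.0)
        stat, p = chisquare(dist.counts)
        assert p > 0.01

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            phase_distribution([], bin_width_hr=5.0)


class TestPeakNadirAmplitude:
    def test_cosine_half_period_interval_valid(self, times13):
        B, A = 100.0, 40.0
        x = B + A * np.cos(2 * np.pi * times13 / 24.0)
        m = peak_nadir_amplitude(x, times13)
        assert m.interval_hr == 12.0
        assert m.valid
        assert m.ratio == pytest.approx((B + A) / (B - A))

    def test_adjacent_spike_invalid(self, times13):
        x = np.full(13, 10.0)
        x[3] = 50.0
        x[4] = 2.0
        m = peak_nadir_amplitude(x, times13)
        assert m.interval_hr == 4.0
        assert not m.valid
        assert m.ratio == pytest.approx(25.0)

    def test_zero_nadir_invalid_with_reason(self, times13):
        x = np.full(13, 10.0)
        x[2] = 0.0
        m = peak_nadir_amplitude(x, times13)
        assert not m.valid
        assert "nadir" in m.reason
        assert np.isnan(m.ratio)


class TestLdDdFold:
    def test_simple_arithmetic(self):
        ld = make_matrix(np.full((1, 13), 200.0))
        dd = make_matrix(np.full((1, 13), 50.0))
        df, frac = ld_dd_fold(ld, dd)
        assert df.fold.iloc[0] == pytest.approx(4.0)
        assert df.direction.iloc[0] == "LD-high"
        assert frac == 1.0

    def test_identical_matrices_fold_one(self):
        tc = make_matrix(np.random.default_rng(0).uniform(50, 150, (5, 13)))
        df, frac = ld_dd_fold(tc, tc)
        assert np.allclose(df.fold, 1.0)
        assert frac == 0.0

    def test_missing_probe_excluded(self, caplog):
        ld = make_matrix(np.full((2, 13), 100.0), probe_ids=["a", "b"])
        dd = make_matrix(np.full((1, 13), 100.0), probe_ids=["a"])
        with caplog.at_level("WARNING"):
            df, _ = ld_dd_fold(ld, dd)
        assert df.probe_id.tolist() == ["a"]

    def test_type_iii_folds_exceed_type_i(self):
        spec = SimulationSpec(n_type_I=10, n_type_III=10, rel_amplitude=0.8,
                              period_hr=24.0, noise_sigma=0.02,
                              dd_amplitude_scale=0.25, seed=4)
        ld, dd, truth = simulate_ld_dd_pair(spec)
        df, _ = ld_dd_fold(ld, dd)
        folds = dict(zip(df.probe_id, df.fold))
        f1 = [folds[p] for p in truth.probe_id[truth.klass == "type_I"]]
        f3 = [folds[p] for p in truth.probe_id[truth.klass == "type_III"]]
        assert min(f3) > max(f1)


class TestClassifyLdDd:
    def _typed_pair(self, **kw):
        spec = SimulationSpec(n_type_I=3, n_type_II=3, n_type_III=3,
                              n_arrhythmic=3, rel_amplitude=0.8,
                              period_hr=24.0, noise_sigma=0.0,
                              dd_amplitude_scale=0.25, seed=6, **kw)
        return simulate_ld_dd_pair(spec)

    def test_round_trip_on_noiseless_pairs(self):
        ld, dd, truth = self._typed_pair()
        typing = classify_ld_dd_types(ld, dd, run_jtk(ld), run_jtk(dd))
        got = dict(zip(typing.probe_id, typing.ld_dd_type))
        for _, row in truth.iterrows():
            expected = {"type_I": "I", "type_II": "II", "type_III": "III",
                        "arrhythmic": "other"}[row.klass]
            assert got[row.probe_id] == expected, row.klass

    def test_arrhythmic_is_other(self):
        flat = np.full(13, 50.0)
        assert classify_ld_dd_type(flat, flat, False, False,
                                   np.arange(13) * 4.0) == "other"


class TestHierarchicalCluster:
    def test_identical_profiles_merge_at_zero(self, cosine_profile):
        prof = cosine_profile()
        tc = make_matrix([prof, prof, cosine_profile(peak_hr=12.0)])
        res = hierarchical_cluster(tc)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_in_phase_pair_merges_first(self, cosine_profile):
        tc = make_matrix([
            cosine_profile(peak_hr=0.0, amplitude=40),
            cosine_profile(peak_hr=1.0, amplitude=35),
            cosine_profile(peak_hr=12.0, amplitude=40),
        ])
        res = hierarchical_cluster(tc)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_three_planted_clusters_recovered(self, cosine_profile):
        profiles, labels = [], []
        for g, peak in enumerate((0.0, 8.0, 16.0)):
            for _ in range(6):
                profiles.append(cosine_profile(peak_hr=peak))
                labels.append(g)
        tc = make_matrix(profiles)
        res = hierarchical_cluster(tc)
        pred = hierarchy.fcluster(res.linkage, t=3, criterion="maxclust")
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_permutation_invariance(self, cosine_profile):
        rng = np.random.default_rng(1)
        profiles = [cosine_profile(peak_hr=p, amplitude=a)
                    for p, a in zip(rng.uniform(0, 24, 10), rng.uniform(10, 50, 10))]
        tc = make_matrix(profiles)
        res = hierarchical_cluster(tc)
        order = rng.permutation(10)
        tc2 = make_matrix([profiles[i] for i in order],
                          probe_ids=[tc.probe_ids[i] for i in order])
        res2 = hierarchical_cluster(tc2)
        lab1 = hierarchy.fcluster(res.linkage, t=3, criterion="maxclust")
        lab2 = hierarchy.fcluster(res2.linkage, t=3, criterion="maxclust")
        unshuffled = np.empty(10, dtype=int)
        unshuffled[order] = np.arange(10)
        assert adjusted_rand_score(lab1, lab2[unshuffled]) == 1.0

    def test_low_intensity_probes_excluded(self):
        tc = make_matrix([np.full(13, 5.0), np.full(13, 100.0), np.full(13, 90.0)])
        res = hierarchical_cluster(tc, intensity_floor=20.0)
        assert res.probe_ids == ["p1", "p2"]

    def test_single_leaf_degenerate(self):
        tc = make_matrix([np.full(13, 100.0)])
        res = hierarchical_cluster(tc)
        assert res.linkage is None
        assert res.newick == "p0;"

    def test_newick_contains_all_leaves(self, cosine_profile):
        tc = make_matrix([cosine_profile(peak_hr=p) for p in (0, 6, 12, 18)])
        res = hierarchical_cluster(tc)
        assert res.newick.endswith(";")
        for p in tc.probe_ids:
            assert p in res.newick


class TestZscore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = zscore_profiles(rng.uniform(10, 100, (5, 13)))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(10, 100, (3, 13))
        assert np.allclose(zscore_profiles(x), zscore_profiles(3.5 * x + 12.0))

    def test_constant_profile_zeros(self):
        z = zscore_profiles(np.full((1, 13), 9.0))
        assert np.all(z == 0.0)
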