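import numpy as np
import pandas as pd
import pytest
from scipy import stats

from temporalpopgen.diff_scan import (afd, permutation_q, shared_outliers,
                                      site_fst, window_fst)

from conftest import build_gm
from oracles import wc_components_oracle


class TestSiteFst:
    def test_identical_groups_near_zero(self, rng):
        d = rng.binomial(2, 0.5, size=(80, 200)).astype(np.int8)
        gm = build_gm(d)
        comps = site_fst(gm, gm.samples[:40], gm.samples[40:])
        theta = comps.loc[comps["usable"], "theta"]
        assert abs(theta.mean()) < 0.02  # may be slightly negative

    def test_fixed_difference_near_one(self):
        d = np.vstack([np.zeros((20, 5)), np.full((20, 5), 2)]).astype(np.int8)
        gm = build_gm(d)
        comps = site_fst(gm, gm.samples[:20], gm.samples[20:])
        assert (comps["theta"] > 0.97).all()

    def test_matches_component_oracle_exactly(self):
        """Crafted counts: 10 hom-alt + 1 het vs 10 hom-ref + 1 het."""
        a = np.array([2] * 10 + [1], dtype=np.int8)[:, None]
        b = np.array([0] * 10 + [1], dtype=np.int8)[:, None]
        gm = build_gm(np.vstack([a, b]))
        comps = site_fst(gm, gm.samples[:11], gm.samples[11:])
        oa, ob, oc, otheta = wc_components_oracle(a.ravel(), b.ravel())
        assert comps["a"][0] == pytest.approx(oa, abs=1e-12)
        assert comps["b"][0] == pytest.approx(ob, abs=1e-12)
        assert comps["c"][0] == pytest.approx(oc, abs=1e-12)
        assert comps["theta"][0] == pytest.approx(otheta, abs=1e-12)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(50):
            na, nb = rng.integers(3, 12, size=2)
            d = rng.integers(-1, 3, size=(na + nb, 6)).astype(np.int8)
            gm = build_gm(d)
            comps = site_fst(gm, gm.samples[:na], gm.samples[na:])
            for j in range(6):
                if not comps["usable"][j]:
                    continue
                *_, otheta = wc_components_oracle(d[:na, j], d[na:, j])
                assert comps["theta"][j] == pytest.approx(otheta, abs=1e-9)

    def test_monomorphic_pool_excluded(self):
        d = np.zeros((10, 3), dtype=np.int8)
        d[:, 1] = 1
        gm = build_gm(d)
        comps = site_fst(gm, gm.samples[:5], gm.samples[5:])
        assert not comps["usable"][0]
        assert comps["usable"][1]

    def test_small_group_rejected(self):
        gm = build_gm(np.zeros((4, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            site_fst(gm, gm.samples[:1], gm.samples[1:])


class TestWindowFst:
    def make_components(self, positions, a, b, c):
        return pd.DataFrame({
            "chrom": "LG01", "pos": positions, "a": a, "b": b, "c": c,
            "theta": np.array(a) / (np.array(a) + np.array(b) + np.array(c)),
            "usable": True})

    def test_single_site_window_equals_site_value(self):
        comps = self.make_components([100], [0.2], [0.3], [0.1])
        win = window_fst(comps, window_bp=1000, step_bp=1000)
        assert len(win) == 1
        assert win["fst"][0] == pytest.approx(0.2 / 0.6)

    def test_ratio_of_sums_differs_from_mean_of_ratios(self):
        """Two sites crafted so the weighted value is not the mean ratio:
        sum(a)/sum(abc) = 0.3/1.1, mean of ratios = (0.2/0.2+0.1/0.9)/2."""
        comps = self.make_components([10, 20], [0.1, 0.2], [0.05, 0.6],
                                     [0.05, 0.1])
        win = window_fst(comps, window_bp=100, step_bp=100)
        weighted = (0.1 + 0.2) / (0.1 + 0.05 + 0.05 + 0.2 + 0.6 + 0.1)
        mean_ratio = np.mean([0.1 / 0.2, 0.2 / 0.9])
        assert win["fst"][0] == pytest.approx(weighted)
        assert abs(win["fst"][0] - mean_ratio) > 0.05

    def test_windows_anchored_at_one_with_step(self):
        comps = self.make_components([5, 25_000, 40_000],
                                     [0.1] * 3, [0.1] * 3, [0.1] * 3)
        win = window_fst(comps, window_bp=30_000, step_bp=15_000)
        assert win["start"].tolist() == [1, 15001, 30001]
        assert (win["end"] - win["start"] + 1 == 30_000).all()


class TestPermutationQ:
    def test_null_p_uniform_and_plus_one_rule(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 300),
                         size=(40, 300)).astype(np.int8)
        gm = build_gm(d, pos=rng.permutation(np.arange(1, 60_001, 200))[:300])
        gm = gm.take_sites(np.argsort(gm.sites["pos"].to_numpy()))
        ga, gb = gm.samples[:20], gm.samples[20:]
        comps = site_fst(gm, ga, gb)
        win = window_fst(comps, 2000, 2000)
        out = permutation_q(win, gm, ga, gb, n_perm=100, seed=1,
                            window_bp=2000, step_bp=2000)
        p = out["p"].dropna()
        assert (p >= 1.0 / (100 * len(win) + 1)).all()
        # exchangeable null: moderate uniformity at this scale
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_q_monotone_in_sorted_p(self, rng):
        d = rng.integers(0, 3, size=(30, 100)).astype(np.int8)
        gm = build_gm(d, pos=np.arange(1, 100_000, 1000)[:100])
        ga, gb = gm.samples[:15], gm.samples[15:]
        comps = site_fst(gm, ga, gb)
        win = window_fst(comps, 5000, 5000)
        out = permutation_q(win, gm, ga, gb, n_perm=100, seed=2,
                            window_bp=5000, step_bp=5000)
        sub = out.dropna(subset=["p"]).sort_values("p")
        assert (np.diff(sub["q"]) >= -1e-12).all()
        assert out["q"].dropna().between(0, 1).all()

    def test_determinism_and_nperm_floor(self, rng):
        d = rng.integers(0, 3, size=(20, 40)).astype(np.int8)
        gm = build_gm(d, pos=np.arange(1, 41) * 100)
        ga, gb = gm.samples[:10], gm.samples[10:]
        comps = site_fst(gm, ga, gb)
        win = window_fst(comps, 1000, 1000)
        a = permutation_q(win, gm, ga, gb, n_perm=100, seed=7,
                          window_bp=1000, step_bp=1000)
        b = permutation_q(win, gm, ga, gb, n_perm=100, seed=7,
                          window_bp=1000, step_bp=1000)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            permutation_q(win, gm, ga, gb, n_perm=10)


class TestAfd:
    def test_equal_and_fixed(self):
        d = np.vstack([np.array([[0, 2], [2, 2]])] * 2).astype(np.int8)
        gm = build_gm(d)
        out = afd(gm, gm.samples[:2], gm.samples[2:])
        np.testing.assert_allclose(out["afd"], [0.0, 0.0])
        d2 = np.vstack([np.zeros((3, 1)), np.full((3, 1), 2)]).astype(np.int8)
        gm2 = build_gm(d2)
        assert afd(gm2, gm2.samples[:3], gm2.samples[3:])["afd"][0] == 1.0

    def test_quantile_flags_about_one_in_thousand(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 1000),
                         size=(60, 1000)).astype(np.int8)
        gm = build_gm(d)
        out = afd(gm, gm.samples[:30], gm.samples[30:], quantile=0.999)
        assert 1 <= out["outlier"].sum() <= 5  # order statistics at n=1000


class TestSharedOutliers:
    def test_disjoint_sets_empty(self):
        out = shared_outliers({"a": [("LG01", 1)], "b": [("LG01", 2)]}, 2)
        assert out.empty

    def test_full_support_reported(self):
        sets = {"a": [("LG01", 5)], "b": [("LG01", 5)], "c": [("LG01", 5)]}
        out = shared_outliers(sets, 2)
        assert out["n_comparisons"][0] == 3
        assert out["comparisons"][0] == ["a", "b", "c"]

    def test_matches_bruteforce_intersection(self):
        sets = {
            "ab": [("LG01", 1), ("LG01", 2), ("LG02", 9)],
            "cd": [("LG01", 2), ("LG02", 9), ("LG03", 4)],
            "ef": [("LG02", 9), ("LG03", 4)],
        }
        out = shared_outliers(sets, 2)
        brute = {}
        for label, sites in sets.items():
            for s in sites:
                brute.setdefault(s, set()).add(label)
        expected = {s for s, labs in brute.items() if len(labs) >= 2}
        assert set(zip(out["chrom"], out["pos"])) == expected

    def test_requires_two_comparisons(self):
        with pytest.raises(ValueError):
            shared_outliers({"a": []}, 2)
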