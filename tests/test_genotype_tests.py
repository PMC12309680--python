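import numpy as np
import pandas as pd
import pytest
from scipy import stats

from temporalpopgen.core import MISSING
from temporalpopgen.genotype_tests import (compact_letter_display,
                                           fisher_years, genotype_freq_table,
                                           hb_diplotype, hwe_chisq,
                                           kruskal_dunn)

from conftest import build_gm


class TestHweChisq:
    def test_exact_hwe_zero_statistic(self):
        res = hwe_chisq(25, 50, 25)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_no_hets_statistic_100(self):
        """(50,0,50): expected (25,50,25), chi2 = 25 + 50 + 25 = 100."""
        res = hwe_chisq(50, 0, 50)
        assert res.statistic == pytest.approx(100.0)

    def test_monomorphic_is_null(self):
        res = hwe_chisq(0, 0, 30)
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.flags["monomorphic"]

    def test_low_expected_flag_and_negative_counts(self):
        assert hwe_chisq(2, 3, 1).flags["low_expected"]
        with pytest.raises(ValueError):
            hwe_chisq(-1, 0, 5)

    def test_nominal_rejection_rate_under_hwe(self, rng):
        """Multinomial draws from exact HWE proportions reject at ~alpha."""
        rej = 0
        reps = 400
        for _ in range(reps):
            counts = rng.multinomial(100, [0.25, 0.5, 0.25])
            if hwe_chisq(*counts).p < 0.05:
                rej += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rej <= hi


class TestFisherYears:
    def test_2x2_hand_value(self):
        """[[5,0],[0,5]]: p = 2 / C(10,5) = 2/252."""
        table = pd.DataFrame([[5, 0], [0, 5]], index=["y1", "y2"],
                             columns=["n_A", "n_B"])
        res = fisher_years(table)
        assert res.p == pytest.approx(2.0 / 252.0, rel=1e-9)
        sp = stats.fisher_exact([[5, 0], [0, 5]])[1]
        assert res.p == pytest.approx(sp, rel=1e-9)

    def test_identical_rows_share_letter(self):
        table = pd.DataFrame([[10, 20, 10]] * 3, index=["a", "b", "c"],
                             columns=["n_X", "n_Y", "n_Z"])
        res = fisher_years(table)
        assert res.p == pytest.approx(1.0)
        assert len(set(res.letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self):
        table = pd.DataFrame([[40, 5, 5], [5, 5, 40]], index=["early", "late"],
                             columns=["n_A", "n_H", "n_D"])
        res = fisher_years(table)
        assert res.p < 0.001
        assert res.letters["early"] != res.letters["late"]

    def test_monte_carlo_stable_across_seeds(self):
        """MC p on a fixed 3x3 toy is stable to 2 decimals at 1e5 draws."""
        table = pd.DataFrame([[12, 8, 4], [6, 10, 9], [3, 7, 12]],
                             index=list("abc"), columns=["n_X", "n_Y", "n_Z"])
        p1 = fisher_years(table, seed=1, enumerate_limit=0).p
        p2 = fisher_years(table, seed=999, enumerate_limit=0).p
        assert abs(p1 - p2) < 0.01

    def test_mc_agrees_with_enumeration_on_2x3(self):
        table = pd.DataFrame([[8, 3, 1], [2, 6, 7]], index=["a", "b"],
                             columns=["n_X", "n_Y", "n_Z"])
        exact = fisher_years(table).p
        mc = fisher_years(table, enumerate_limit=0, seed=4).p
        assert mc == pytest.approx(exact, abs=0.01)

    def test_empty_group_dropped_with_warning(self):
        table = pd.DataFrame([[5, 5], [0, 0], [2, 8]], index=["a", "b", "c"],
                             columns=["n_X", "n_Y"])
        with pytest.warns(UserWarning, match="empty"):
            res = fisher_years(table)
        assert set(res.letters) == {"a", "c"}


class TestCompactLetterDisplay:
    def test_sharing_iff_nonsignificant(self, rng):
        groups = list("abcde")
        p = pd.DataFrame(1.0, index=groups, columns=groups)
        for i, gi in enumerate(groups):
            for gj in groups[i + 1:]:
                val = rng.uniform(0, 0.12)
                p.loc[gi, gj] = p.loc[gj, gi] = val
        letters = compact_letter_display(groups, p, alpha=0.05)
        for i, gi in enumerate(groups):
            for gj in groups[i + 1:]:
                share = bool(set(letters[gi]) & set(letters[gj]))
                assert share == (p.loc[gi, gj] >= 0.05)


class TestGenotypeFreqTable:
    def test_frequencies_sum_to_one(self):
        calls = pd.DataFrame({
            "catch_year": [2000] * 4 + [2010] * 3,
            "call": ["HET", "HET", "DERIVED", None,
                     "ANCESTRAL", "HET", "DERIVED"]})
        table = genotype_freq_table(calls)
        fcols = [c for c in table.columns if c.startswith("f_")]
        np.testing.assert_allclose(table[fcols].sum(axis=1), 1.0)
        assert table.loc[2000, "n_HET"] == 2  # missing call dropped


class TestHbDiplotype:
    def make_gm(self, d55, d62):
        d = np.array([d55, d62], dtype=np.int8).T
        return build_gm(d, pos=[55, 62])

    def test_classes(self):
        gm = self.make_gm([0, 1, 2, 2, MISSING], [0, 1, 2, 1, 0])
        out = hb_diplotype(gm, ("LG01", 55), ("LG01", 62))
        assert out.tolist() == ["Val-Ala", "HET-HET", "Met-Lys", "other", None]

    def test_polarization_flip(self):
        gm = self.make_gm([0], [0])
        out = hb_diplotype(gm, ("LG01", 55), ("LG01", 62),
                           ref_is_val_ala=False)
        assert out.tolist() == ["Met-Lys"]

    def test_unknown_site_raises(self):
        gm = self.make_gm([0], [0])
        with pytest.raises(ValueError, match="not found"):
            hb_diplotype(gm, ("LG01", 99), ("LG01", 62))


class TestKruskalDunn:
    def test_two_group_separation_matches_rank_oracle(self):
        """(1,2,3) vs (10,11,12): H at its maximum for a 3/3 split."""
        res = kruskal_dunn({"a": [1, 2, 3], "b": [10, 11, 12]})
        # brute-force rank computation: ranks 1..6, no ties
        r1, r2 = 6.0, 15.0
        H = 12 / (6 * 7) * (r1 ** 2 / 3 + r2 ** 2 / 3) - 3 * 7
        assert res.statistic == pytest.approx(H)
        scipy_h = stats.kruskal([1, 2, 3], [10, 11, 12])[0]
        assert res.statistic == pytest.approx(scipy_h)

    def test_degenerate_ties_guard(self):
        res = kruskal_dunn({"a": [5, 5], "b": [5, 5, 5]})
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_null_rejection_rate(self, rng):
        rej = 0
        reps = 300
        for _ in range(reps):
            vals = rng.normal(size=30)
            res = kruskal_dunn({"a": vals[:10], "b": vals[10:20],
                                "c": vals[20:]})
            if res.p < 0.05:
                rej += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rej <= hi

    def test_dunn_pairwise_adjusted_and_letters(self):
        res = kruskal_dunn({"a": [1, 2, 3, 4], "b": [1.5, 2.5, 3.5, 4.5],
                            "c": [30, 31, 32, 33]})
        assert res.adjusted_p.loc["a", "b"] > 0.05
        assert res.adjusted_p.loc["a", "c"] < 0.05
        assert set(res.letters["a"]) & set(res.letters["b"])
        assert not set(res.letters["a"]) & set(res.letters["c"])

    def test_empty_group_dropped(self):
        with pytest.warns(UserWarning, match="empty"):
            res = kruskal_dunn({"a": [1, 2], "b": [], "c": [3, 4]})
        assert set(res.letters) == {"a", "c"}
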