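"""Cohort statistics: filters, rank tests, diversity, ordination, DA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from _oracles import wilcoxon_enumeration_p
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from strainspec.simulate import simulate_genus_table
from strainspec.stats import (
    alternation_ratio,
    bh_fdr,
    bray_curtis,
    clr_mc_differential_abundance,
    filter_genus_table,
    ortholog_da_report,
    pcoa,
    permanova,
    shannon,
    spearman,
    wilcoxon_rank_sum,
    within_group_distance_test,
)


class TestFilterGenusTable:
    def _table(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(50, 500, size=(6, 4))
        table = pd.DataFrame(counts, columns=[f"g{i}" for i in range(4)],
                             index=[f"s{i}" for i in range(6)]).astype(float)
        table *= 12  # comfortably above the 10,000-read sample floor
        return table

    def test_shallow_sample_removed(self):
        table = self._table()
        table.loc["s0"] = [2000, 3000, 2999, 2000]  # 9,999 reads total
        filtered, log = filter_genus_table(table)
        assert "s0" not in filtered.index
        assert any("9999" in line for line in log)

    def test_low_prevalence_genus_removed(self):
        table = self._table()
        table["rare"] = [0, 0, 0, 0, 600, 600]  # detected in exactly 2 samples
        filtered, _ = filter_genus_table(table)
        assert "rare" not in filtered.columns

    def test_mean_abundance_threshold(self):
        # one genus at 0.009% mean relative abundance, one at 0.011%
        base = pd.DataFrame(10_000.0, index=[f"s{i}" for i in range(5)],
                            columns=["g0", "g1"])
        base["low"] = 0.00009 * 20_000
        base["ok"] = 0.00011 * 20_000
        base[["g0", "g1"]] = (20_000 - base["low"] - base["ok"]).iloc[0] / 2
        filtered, _ = filter_genus_table(base)
        assert "low" not in filtered.columns and "ok" in filtered.columns

    def test_empty_result_rejected(self):
        table = pd.DataFrame({"g0": [1.0, 1.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError):
            filter_genus_table(table)


class TestWilcoxon:
    def test_worked_extreme_example(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3]) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(1, 7)])
    def test_exact_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_enumeration_p(x, y), abs=1e-12
            )

    def test_exact_close_to_asymptotic_at_n10(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, size=10)
        exact = wilcoxon_rank_sum(x, y)
        approx = wilcoxon_rank_sum(x, y, exact_threshold=0)
        assert abs(exact - approx) < 0.005


class TestBH:
    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_degenerate_cases(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_q_at_least_p_and_rank_monotone(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_tied_small_sample_matches_permutation_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0]
        rho, p = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12:
                count += 1
        assert rho == pytest.approx(obs)
        assert p == pytest.approx(count / total)


class TestBrayCurtis:
    def test_worked_values(self):
        t = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0]],
                         index=list("abcd"))
        d = bray_curtis(t)
        assert d.loc["a", "b"] == pytest.approx(0.5)
        assert d.loc["a", "c"] == 0.0
        assert d.loc["b", "d"] == 1.0  # disjoint supports

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.random((10, 6)))
        d = bray_curtis(t).to_numpy()
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_all_zero_pair_warns_and_is_zero(self):
        t = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"))
        with pytest.warns(UserWarning):
            d = bray_curtis(t)
        assert d.loc["a", "b"] == 0.0


class TestWithinGroupDistance:
    def test_diffuse_group_detected(self):
        rng = np.random.default_rng(5)
        tight = rng.normal(5, 0.05, (12, 4))
        diffuse = np.abs(rng.normal(5, 3.0, (12, 4)))
        t = pd.DataFrame(np.vstack([tight, diffuse]))
        groups = pd.Series(["tight"] * 12 + ["diffuse"] * 12, index=t.index)
        res = within_group_distance_test(bray_curtis(t), groups, reference="tight")
        assert res.loc[0, "p_value"] < 0.05
        assert res.loc[0, "median_group"] > res.loc[0, "median_reference"]

    def test_singleton_group_rejected(self):
        t = pd.DataFrame(np.random.default_rng(0).random((4, 3)))
        groups = pd.Series(["a", "a", "a", "b"], index=t.index)
        with pytest.raises(ValueError):
            within_group_distance_test(bray_curtis(t), groups, reference="a")


class TestPCoA:
    def test_collinear_points_single_axis(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        assert len(res.eigenvalues) == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(9, 4))
        from scipy.spatial.distance import pdist, squareform
        d = pd.DataFrame(squareform(pdist(x)))
        res = pcoa(d)
        got = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(got, d.to_numpy(), atol=1e-9)

    def test_identical_samples_zero_coordinates(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        res = pcoa(d)
        assert res.coordinates.shape[1] == 0

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            pcoa(d)

    def test_matches_reference_implementation(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(11)
        t = pd.DataFrame(rng.random((8, 5)))
        d = bray_curtis(t)
        mine = pcoa(d)
        import skbio
        theirs = skbio_ord.pcoa(skbio.DistanceMatrix(d.to_numpy()))
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues),
            np.sort(theirs.eigvals.to_numpy()[theirs.eigvals.to_numpy() > 1e-9]),
            atol=1e-8,
        )


class TestPermanova:
    def test_separated_clusters_minimum_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(2, 0.05, (12, 3))
        b = rng.normal(8, 0.05, (12, 3))
        t = pd.DataFrame(np.vstack([a, b]))
        d = bray_curtis(t)
        groups = pd.Series(["a"] * 12 + ["b"] * 12, index=d.index)
        f, r2, p = permanova(d, groups, n_permutations=199, seed=0)
        assert p == pytest.approx(1 / 200)
        assert 0 <= r2 <= 1

    def test_matches_reference_implementation(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        import skbio
        rng = np.random.default_rng(6)
        t = pd.DataFrame(rng.random((12, 4)))
        d = bray_curtis(t)
        groups = ["a"] * 6 + ["b"] * 6
        f, r2, _ = permanova(d, pd.Series(groups, index=d.index), n_permutations=99, seed=1)
        theirs = skbio_dist.permanova(skbio.DistanceMatrix(d.to_numpy()), groups,
                                      permutations=99)
        assert f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_bad_permutation_count_rejected(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        groups = pd.Series(["a", "a", "b", "b"], index=d.index)
        with pytest.raises(ValueError):
            permanova(d, groups, n_permutations=0)


class TestShannon:
    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 1, 1], 2.0),
        ([5, 0, 0], 0.0),
        ([2, 1, 1], 1.5),
    ])
    def test_worked_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0, 0])


class TestCLRMonteCarlo:
    def test_flat_composition_no_signal(self):
        t = pd.DataFrame(100, index=[f"s{i}" for i in range(10)],
                         columns=[f"g{i}" for i in range(5)])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=t.index)
        res = clr_mc_differential_abundance(t, groups, case_label="b", seed=0)
        assert (res["p_value"] > 0.5).all()

    def test_planted_threefold_genus_flagged(self):
        """A 3-fold planted genus at n=20/15 is flagged (p<0.05) in at
        least 90% of 200 seeded tables."""
        flagged = 0
        for seed in range(200):
            table, meta = simulate_genus_table(
                n_per_group=(20, 15), planted_effects={"g__007": 3.0}, seed=seed
            )
            res = clr_mc_differential_abundance(
                table, meta["group"], case_label="MCI", n_instances=64, seed=seed
            )
            flagged += bool(res.loc["g__007", "p_value"] < 0.05)
        assert flagged >= 180

    def test_all_zero_sample_rejected(self):
        t = pd.DataFrame([[0, 0], [1, 2], [3, 4], [1, 1], [2, 2], [3, 3]])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=t.index)
        with pytest.raises(ValueError):
            clr_mc_differential_abundance(t, groups)

    def test_fold_change_sign_matches_planted_direction(self):
        table, meta = simulate_genus_table(
            n_per_group=(20, 15), planted_effects={"g__003": 4.0}, seed=5
        )
        res = clr_mc_differential_abundance(table, meta["group"], case_label="MCI", seed=5)
        assert res.loc["g__003", "log2_fold_change"] > 0  # enriched in the case group


class TestOrthologDA:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame(rng.lognormal(3, 1, (20, 6)),
                         index=[f"s{i}" for i in range(20)],
                         columns=[f"OG{i}" for i in range(6)])
        groups = pd.Series(["healthy"] * 10 + ["MCI"] * 10, index=t.index)
        return t, groups

    def test_label_swap_negates_fold_changes(self):
        t, groups = self._table()
        a = ortholog_da_report(t, groups, case_label="MCI")
        b = ortholog_da_report(t, groups, case_label="healthy")
        np.testing.assert_allclose(a["log2_fold_change"], -b["log2_fold_change"])
        np.testing.assert_allclose(a["p_value"], b["p_value"])

    def test_null_table_nominal_rate(self):
        rates = []
        for seed in range(30):
            t, groups = self._table(seed)
            res = ortholog_da_report(t, groups, case_label="MCI")
            rates.append(res["significant"].mean())
        assert np.mean(rates) < 0.12

    def test_missing_ortholog_listed_untested(self):
        t, groups = self._table()
        res = ortholog_da_report(t, groups, case_label="MCI", og_ids=["OG0", "OG_absent"])
        assert res.loc["OG_absent", "tested"] == False  # noqa: E712
        assert bool(res.loc["OG0", "tested"])


class TestAlternation:
    @pytest.mark.parametrize("seq,total,ratio", [
        ("ABCABC", 6, 1.0),
        ("ABAB", 4, 0.0),
        ("ABC", 3, 1.0),
    ])
    def test_worked_values(self, seq, total, ratio):
        assert alternation_ratio(seq) == (total, ratio)

    @pytest.mark.parametrize("bad", ["AB", "AABC", "ABD"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            alternation_ratio(bad)

    @given(st.lists(st.sampled_from("ABC"), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_ratio_in_unit_interval(self, arms):
        seq = [arms[0]]
        for a in arms[1:]:
            if a != seq[-1]:
                seq.append(a)
        if len(seq) < 3:
            seq = ["A", "B", "C"]
        _, ratio = alternation_ratio(seq)
        assert 0.0 <= ratio <= 1.0
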