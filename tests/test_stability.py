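import numpy as np
import pandas as pd
import pytest

from _oracles import (
    brute_delta_ct,
    brute_genorm_initial_m,
    brute_normfinder_grouped,
    brute_normfinder_ungrouped,
)
from refstab import (
    BestKeeper,
    CtMatrix,
    CtValidationError,
    DeltaCtStability,
    GeNorm,
    NormFinder,
    bestkeeper,
    delta_ct_stability,
    genorm,
    normfinder,
    optimal_reference_count,
    relative_quantities,
)
from refstab.stability import PairwiseVariationSeries


def _matrix(rows: dict, groups=None) -> CtMatrix:
    n = len(next(iter(rows.values())))
    ct = pd.DataFrame(rows, index=[f"s{j}" for j in range(n)]).T
    group_of = None
    if groups is not None:
        group_of = {f"s{j}": g for j, g in enumerate(groups)}
    return CtMatrix(ct, group_of=group_of)


class TestRelativeQuantities:
    def test_doubling_series(self):
        m = _matrix({"A": [20, 21, 22, 23], "B": [25, 26, 27, 28]})
        q = relative_quantities(m).q
        assert list(q.loc["A"]) == pytest.approx([1, 0.5, 0.25, 0.125])

    def test_constant_row_is_all_ones(self):
        m = _matrix({"A": [20, 20, 20], "B": [25, 26, 27]})
        assert (relative_quantities(m).q.loc["A"] == 1).all()

    def test_non_default_base(self):
        m = _matrix({"A": [20, 21, 20], "B": [25, 26, 27]})
        q = relative_quantities(m, efficiency_base=1.9).q
        assert q.at["A", "s1"] == pytest.approx(1 / 1.9)

    def test_per_gene_max_is_one(self):
        rng = np.random.default_rng(0)
        m = _matrix({f"g{i}": rng.uniform(15, 35, 5) for i in range(4)})
        assert relative_quantities(m).q.max(axis=1).tolist() == pytest.approx(
            [1, 1, 1, 1]
        )

    def test_invalid_base_rejected(self):
        m = _matrix({"A": [20, 21, 22], "B": [25, 26, 27]})
        with pytest.raises(ValueError, match="efficiency_base"):
            relative_quantities(m, efficiency_base=1.0)


class TestDeltaCt:
    def test_toy_hand_computed_values(self, toy_matrix):
        table = delta_ct_stability(toy_matrix)
        assert table.stability["A"] == pytest.approx(0.47871, abs=5e-6)
        assert table.stability["B"] == pytest.approx(0.47871, abs=5e-6)
        assert table.stability["C"] == pytest.approx(0.95743, abs=5e-6)
        assert list(table.rank[["A", "B", "C"]]) == [1, 2, 3]

    def test_identical_genes_have_zero_stability(self):
        m = _matrix({"A": [20, 21, 22], "B": [20, 21, 22], "C": [20, 22, 25]})
        table = delta_ct_stability(m)
        # A and B are identical: their mutual SD term is 0 and the rest agree
        assert table.stability["A"] == pytest.approx(table.stability["B"], abs=1e-12)
        two_same = _matrix({"A": [20.0, 21.0, 22.0], "B": [20.0, 21.0, 22.0]})
        assert (delta_ct_stability(two_same).stability == 0).all()

    def test_matches_bruteforce_on_random_matrices(self, make_random_matrix):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = make_random_matrix(rng, int(rng.integers(2, 8)), int(rng.integers(3, 12)))
            expected = brute_delta_ct({g: list(m.ct.loc[g]) for g in m.genes})
            got = delta_ct_stability(m).stability
            for g in m.genes:
                assert got[g] == pytest.approx(expected[g], abs=1e-12)


class TestGeNorm:
    def test_toy_initial_m_and_exclusion(self, toy_matrix):
        res = genorm(toy_matrix)
        assert res.initial_m["A"] == pytest.approx(0.47871, abs=5e-6)
        assert res.initial_m["C"] == pytest.approx(0.95743, abs=5e-6)
        assert res.exclusion_order == ["C"]
        assert res.final_pair == ("A", "B")
        # final pair shares the exclusion-step M (their mutual V = 0 here)
        assert res.stability["A"] == res.stability["B"] == 0.0
        assert res.pairwise_variation.v[2] == pytest.approx(0.31914, abs=5e-6)

    def test_proportional_genes_have_zero_m(self):
        m = _matrix({"A": [20, 21, 22], "B": [23, 24, 25], "C": [20, 22, 25]})
        res = genorm(m)
        assert res.initial_m["A"] == res.initial_m["B"]
        two = _matrix({"A": [20, 21, 22], "B": [23, 24, 25], "X": [20, 21, 22]})
        assert genorm(two).initial_m["A"] == genorm(two).initial_m["X"]

    def test_constant_matrix_gives_all_zero_m(self):
        m = _matrix({"A": [20.0] * 4, "B": [25.0] * 4, "C": [30.0] * 4})
        res = genorm(m)
        assert (res.initial_m == 0).all()
        assert (res.stability == 0).all()

    def test_initial_m_matches_bruteforce(self, make_random_matrix):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = make_random_matrix(rng, 5, 8)
            expected = brute_genorm_initial_m(
                {g: list(m.ct.loc[g]) for g in m.genes}
            )
            got = genorm(m).initial_m
            for g in m.genes:
                assert got[g] == pytest.approx(expected[g], abs=1e-10)

    def test_m_invariant_to_gene_and_sample_shifts(self, make_random_matrix):
        rng = np.random.default_rng(3)
        m = make_random_matrix(rng, 5, 10)
        shifted = CtMatrix(
            m.ct.add(rng.uniform(-3, 3, size=5), axis=0)
            .add(rng.uniform(-2, 2, size=10), axis=1)
        )
        pd.testing.assert_series_equal(
            genorm(m).initial_m, genorm(shifted).initial_m, atol=1e-9
        )

    def test_exclusion_tie_removes_later_gene(self):
        # A/B and C/D are two identical-profile pairs; all M are equal at
        # the first step, so the canonical-order rule removes the last gene.
        m = _matrix(
            {
                "A": [20, 21, 22, 23],
                "B": [21, 22, 23, 24],
                "C": [20, 22, 21, 23],
                "D": [21, 23, 22, 24],
            }
        )
        res = genorm(m)
        assert res.exclusion_order[0] == "D"

    def test_unsuitable_flag_uses_m_threshold(self):
        m = _matrix(
            {
                "A": [20, 20.1, 19.9, 20.0],
                "B": [20, 20.0, 20.1, 19.9],
                "C": [20, 26, 15, 29],
            }
        )
        res = genorm(m)
        assert "C" in res.unsuitable
        assert "A" not in res.unsuitable


class TestOptimalReferenceCount:
    def test_smallest_n_below_cutoff(self):
        pv = PairwiseVariationSeries(
            {2: 0.123, 3: 0.2, 4: 0.1}, 0.15, 2, True
        )
        assert optimal_reference_count(pv) == (2, True)

    def test_strict_inequality_at_boundary(self):
        # constructed series: exactly 0.15 does not qualify, 0.149999 does
        below = PairwiseVariationSeries({2: 0.149999}, 0.15, 2, True)
        assert optimal_reference_count(below) == (2, True)

    def test_no_cutoff_returns_k_with_flag(self):
        pv = PairwiseVariationSeries({2: 0.3, 3: 0.2}, 0.15, 4, False)
        n, found = optimal_reference_count(pv)
        assert (n, found) == (4, False)

    def test_flag_computed_by_genorm(self, make_random_matrix):
        rng = np.random.default_rng(5)
        noisy = make_random_matrix(rng, 4, 8)
        res = genorm(noisy)
        n, found = optimal_reference_count(res)
        assert not found and n == 4  # uniform(15,35) noise: V far above 0.15


class TestNormFinder:
    def test_toy_ungrouped_hand_computed(self, toy_matrix):
        res = normfinder(toy_matrix)
        assert res.stability["A"] == pytest.approx(0.0, abs=1e-5)
        assert res.stability["B"] == pytest.approx(0.0, abs=1e-5)
        assert res.stability["C"] == pytest.approx(0.95743, abs=5e-6)

    def test_constant_genes_all_zero(self):
        m = _matrix({"A": [20.0] * 4, "B": [25.0] * 4, "C": [30.0] * 4})
        assert (normfinder(m).stability == 0).all()

    def test_needs_three_genes(self):
        m = _matrix({"A": [20, 21, 22], "B": [25, 26, 27]})
        with pytest.raises(CtValidationError, match="3 genes"):
            normfinder(m)

    def test_grouped_needs_two_samples_per_group(self):
        m = _matrix(
            {"A": [20, 21, 22], "B": [25, 26, 27], "C": [30, 31, 32]},
            groups=["x", "x", "y"],
        )
        with pytest.raises(CtValidationError, match="2 samples per group"):
            normfinder(m, use_groups=True)

    def test_ungrouped_invariant_to_shifts(self, make_random_matrix):
        rng = np.random.default_rng(13)
        m = make_random_matrix(rng, 6, 9)
        shifted = CtMatrix(
            m.ct.add(rng.uniform(-3, 3, size=6), axis=0)
            .add(rng.uniform(-2, 2, size=9), axis=1)
        )
        got, ref = normfinder(shifted).stability, normfinder(m).stability
        pd.testing.assert_series_equal(got, ref, atol=1e-9)

    def test_ungrouped_matches_bruteforce(self, make_random_matrix):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = make_random_matrix(rng, int(rng.integers(3, 9)), int(rng.integers(3, 12)))
            expected = brute_normfinder_ungrouped(
                {g: list(m.ct.loc[g]) for g in m.genes}
            )
            got = normfinder(m).stability
            for g in m.genes:
                assert got[g] == pytest.approx(expected[g], abs=1e-12)

    def test_grouped_matches_bruteforce(self, make_random_matrix):
        rng = np.random.default_rng(19)
        for _ in range(10):
            m = make_random_matrix(rng, 5, 8, with_groups=True)
            groups = list(m.groups())
            expected = brute_normfinder_grouped(
                {g: list(m.ct.loc[g]) for g in m.genes}, groups
            )
            got = normfinder(m, use_groups=True).stability
            for g in m.genes:
                assert got[g] == pytest.approx(expected[g], abs=1e-12)

    def test_grouped_flags_shifted_gene_least_stable(self):
        # one gene with a +2-cycle group-mean shift, low noise
        rng = np.random.default_rng(23)
        n_g = 6
        rows = {}
        for i in range(5):
            base = 20.0 + 2 * i
            noise = rng.normal(0, 0.05, size=2 * n_g)
            shift = np.r_[np.zeros(n_g), np.full(n_g, 2.0)] if i == 2 else 0.0
            rows[f"g{i}"] = base + noise + shift
        m = _matrix(rows, groups=["a"] * n_g + ["b"] * n_g)
        res = normfinder(m, use_groups=True)
        assert res.stability.idxmax() == "g2"
        assert res.rank["g2"] == 5


class TestBestKeeper:
    def test_hand_computed_mad_and_cv(self):
        m = _matrix({"A": [20, 20.5, 21], "B": [25, 26, 27]})
        res = bestkeeper(m)
        assert res.summary.at["A", "mean_ct"] == pytest.approx(20.5)
        assert res.summary.at["A", "sd"] == pytest.approx(0.33333, abs=5e-6)
        assert res.summary.at["A", "cv"] == pytest.approx(1.62602, abs=5e-6)

    def test_constant_gene_zero_sd_cv(self):
        m = _matrix({"A": [20.0] * 3, "B": [25, 26, 27]})
        res = bestkeeper(m)
        assert res.summary.at["A", "sd"] == 0.0
        assert res.summary.at["A", "cv"] == 0.0

    def test_summary_orderings(self, make_random_matrix):
        rng = np.random.default_rng(29)
        m = make_random_matrix(rng, 5, 10)
        s = bestkeeper(m).summary
        assert (s["min_ct"] <= s["mean_ct"]).all()
        assert (s["mean_ct"] <= s["max_ct"]).all()
        assert (s["min_ct"] <= s["geo_mean_ct"]).all()

    def test_sd_invariant_to_sample_permutation(self, make_random_matrix):
        rng = np.random.default_rng(31)
        m = make_random_matrix(rng, 4, 8)
        perm = list(rng.permutation(m.samples))
        shuffled = CtMatrix(m.ct[perm])
        pd.testing.assert_series_equal(
            bestkeeper(m).stability, bestkeeper(shuffled).stability
        )

    def test_sd_scales_linearly(self, make_random_matrix):
        rng = np.random.default_rng(37)
        m = make_random_matrix(rng, 4, 8)
        doubled = CtMatrix(m.ct * 2.0)
        pd.testing.assert_series_equal(
            bestkeeper(doubled).stability, 2.0 * bestkeeper(m).stability,
            atol=1e-12,
        )

    def test_std_flag_switches_estimator(self):
        m = _matrix({"A": [20, 20.5, 21], "B": [25, 26, 27]})
        res = bestkeeper(m, sd_method="std")
        assert res.summary.at["A", "sd"] == pytest.approx(0.5)


class TestCrossMethod:
    def test_delta_ct_equals_initial_genorm_m_base2(self, make_random_matrix):
        rng = np.random.default_rng(41)
        for _ in range(25):
            m = make_random_matrix(
                rng, int(rng.integers(3, 12)), int(rng.integers(4, 20))
            )
            d = delta_ct_stability(m).stability
            g = genorm(m).initial_m
            assert np.max(np.abs(d.to_numpy() - g.to_numpy())) < 1e-12


class TestEstimatorInterface:
    def test_accepts_samples_by_genes_dataframe(self, toy_matrix):
        X = toy_matrix.ct.T  # samples x genes, sklearn orientation
        est = DeltaCtStability().fit(X)
        assert list(est.genes_) == ["A", "B", "C"]
        assert est.stability_[2] == pytest.approx(0.95743, abs=5e-6)

    def test_accepts_plain_array(self):
        X = np.array([[20.0, 25.0], [21.0, 26.0], [22.0, 27.0]])
        est = BestKeeper().fit(X)
        assert list(est.genes_) == ["gene1", "gene2"]

    def test_get_params_roundtrip(self):
        est = GeNorm(efficiency_base=1.9, v_threshold=0.2)
        params = est.get_params()
        clone = GeNorm(**params)
        assert clone.efficiency_base == 1.9 and clone.v_threshold == 0.2

    def test_groups_passed_as_y(self):
        X = np.tile([[20.0, 25.0, 30.0]], (6, 1)) + np.random.default_rng(1).normal(
            0, 0.1, size=(6, 3)
        )
        est = NormFinder(use_groups=True).fit(X, y=["a", "a", "a", "b", "b", "b"])
        assert est.group_labels_ == ["a", "b"]
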