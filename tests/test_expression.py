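"""Expression analysis: FPKM, the two DE tests, intersection, fractions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hifburden import (
    GeneSet,
    compare_fractions,
    de_test_nb,
    de_test_welch,
    fpkm,
    highfold_filter,
    intersect_de,
    regulon_fraction,
    size_factors,
)
from hifburden.expression import FractionResult
from tests._oracles import hypergeom_tail_exact
from tests.conftest import build_two_group_experiment


class TestFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [100, 999_900]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 1000], index=["g1", "g2"])
        out = fpkm(counts, lengths)
        # library size 1e6, length 1 kb: count 100 -> FPKM 100 (+ offset)
        assert out.loc["g1", "s"] == pytest.approx(100.0001)

    def test_offset_keeps_zeros_positive(self):
        counts = pd.DataFrame({"s": [0, 10]}, index=["g1", "g2"])
        lengths = pd.Series([500, 500], index=["g1", "g2"])
        assert (fpkm(counts, lengths) > 0).all().all()

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=200)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        lengths = pd.Series(rng.integers(200, 5000, 200), index=counts.index)
        out = fpkm(counts, lengths)
        assert np.allclose(out["a"], out["b"], rtol=1e-4)

    def test_zero_library_is_error(self):
        counts = pd.DataFrame({"s": [0, 0]})
        with pytest.raises(ValueError, match="library size"):
            fpkm(counts, pd.Series([100, 100]))


class TestWelchTest:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(100, size=(50, 3))
        exp, test, ref = build_two_group_experiment(np.hstack([arr, arr]), 3)
        res = de_test_welch(exp, test, ref)
        assert np.allclose(res.lfc, 0.0)
        assert (res.p == 1.0).all()  # zero variance across mirrored groups

    def test_matches_direct_welch_formula(self):
        rng = np.random.default_rng(2)
        arr = rng.negative_binomial(20, 0.2, size=(100, 6))
        exp, test, ref = build_two_group_experiment(arr, 3)
        res = de_test_welch(exp, test, ref)
        logv = np.log2(fpkm(exp.counts, exp.gene_lengths))
        x, y = logv[test].to_numpy(), logv[ref].to_numpy()
        vx, vy = x.var(axis=1, ddof=1) / 3, y.var(axis=1, ddof=1) / 3
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        p = 2 * stats.t.sf(np.abs(t), df)
        assert np.allclose(res.p, p, rtol=1e-9)
        assert np.allclose(res.lfc, x.mean(axis=1) - y.mean(axis=1))

    def test_power_at_fourfold_change(self):
        # 500 DE genes (lfc 2) among 25,000 null genes, n = 3 vs 3,
        # dispersion 0.1: per-gene rejection rate at raw p < 0.05
        rng = np.random.default_rng(3)
        n_genes, n_de = 25_500, 500
        mus0 = np.exp(rng.normal(5, 0.8, n_genes))
        mus1 = mus0.copy()
        mus1[:n_de] *= 4
        r = 10.0
        arr = np.stack(
            [rng.negative_binomial(r, r / (r + mus1)) for _ in range(3)]
            + [rng.negative_binomial(r, r / (r + mus0)) for _ in range(3)],
            axis=1,
        )
        exp, test, ref = build_two_group_experiment(arr, 3)
        res = de_test_welch(exp, test, ref)
        power = (res.p.iloc[:n_de] < 0.05).mean()
        null_rate = (res.p.iloc[n_de:] < 0.05).mean()
        assert power > 0.8
        assert null_rate < 0.07


class TestNBTest:
    def test_size_factor_scaling_identity(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(np.exp(rng.normal(5, 1, 400))).astype(int)
        arr = np.stack([base, base, 2 * base, 2 * base], axis=1)
        exp, test, ref = build_two_group_experiment(arr, 2)
        sf = size_factors(exp.counts)
        assert sf.iloc[2] / sf.iloc[0] == pytest.approx(2.0, rel=1e-9)
        res = de_test_nb(exp, test, ref)
        assert np.allclose(res.lfc, 0.0, atol=1e-9)

    def test_null_type_i_error(self):
        rng = np.random.default_rng(5)
        mus = np.exp(rng.normal(5, 1, 2000))
        r = 20.0  # dispersion 0.05
        arr = np.stack(
            [rng.negative_binomial(r, r / (r + mus)) for _ in range(6)], axis=1
        )
        exp, test, ref = build_two_group_experiment(arr, 3)
        res = de_test_nb(exp, test, ref)
        assert (res.p < 0.05).mean() <= 0.07

    def test_poisson_limit_matches_exact_test(self):
        # Poisson counts, n = 10 per side, large means: the Wald p
        # approximates the exact conditional binomial comparison
        rng = np.random.default_rng(6)
        mus0 = np.full(2000, 400.0)
        mus1 = mus0.copy()
        mus1[:100] *= 1.5
        arr = np.stack(
            [rng.poisson(mus1) for _ in range(10)]
            + [rng.poisson(mus0) for _ in range(10)],
            axis=1,
        )
        exp, test, ref = build_two_group_experiment(arr, 10)
        res = de_test_nb(exp, test, ref)
        t1 = exp.counts[test].sum(axis=1).iloc[:100]
        t0 = exp.counts[ref].sum(axis=1).iloc[:100]
        exact = np.array(
            [stats.binomtest(int(k), int(k + m), 0.5).pvalue
             for k, m in zip(t1, t0)]
        )
        agree = ((res.p.iloc[:100] < 0.05).to_numpy() == (exact < 0.05)).mean()
        assert agree > 0.97

    def test_all_zero_gene_reported_p_one(self):
        rng = np.random.default_rng(7)
        arr = rng.poisson(50, size=(20, 6))
        arr[0] = 0
        exp, test, ref = build_two_group_experiment(arr, 3)
        res = de_test_nb(exp, test, ref)
        assert res.p.iloc[0] == 1.0
        assert res.lfc.iloc[0] == 0.0


class TestIntersection:
    @staticmethod
    def _frame(p, lfc):
        genes = [f"g{i}" for i in range(len(p))]
        from statsmodels.stats.multitest import multipletests

        return pd.DataFrame(
            {
                "lfc": lfc,
                "p": p,
                "p_adj": multipletests(p, method="fdr_bh")[1],
                "direction": np.sign(lfc).astype(int),
            },
            index=genes,
        )

    def test_one_sided_significance_gives_empty(self):
        a = self._frame([1e-6, 1e-6], [1.0, -1.0])
        b = self._frame([0.9, 0.9], [1.0, -1.0])
        assert intersect_de(a, b).total == 0

    def test_self_intersection_is_significant_set(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        p[:10] = 1e-8
        res = self._frame(p, rng.normal(size=100))
        inter = intersect_de(res, res)
        assert set(inter.genes) == set(res.index[res.p_adj < 0.05])
        assert inter.total == inter.n_up + inter.n_down

    def test_discordant_direction_dropped_and_counted(self):
        a = self._frame([1e-6], [2.0])
        b = self._frame([1e-6], [-2.0])
        inter = intersect_de(a, b)
        assert inter.total == 0 and inter.n_discordant == 1
        both = intersect_de(a, b, require_same_direction=False)
        assert both.total == 1

    def test_mismatched_universe_is_error(self):
        a = self._frame([0.5], [1.0])
        b = self._frame([0.5, 0.5], [1.0, 1.0])
        with pytest.raises(ValueError, match="universe"):
            intersect_de(a, b)

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        res = self._frame(p, rng.normal(size=500))
        order = np.argsort(res.p.to_numpy())
        adjusted = res.p_adj.to_numpy()[order]
        assert (np.diff(adjusted) >= -1e-12).all()


class TestRegulonFraction:
    def test_published_control_fraction(self):
        universe = [f"g{i}" for i in range(2000)]
        regulon = GeneSet.from_iterable("reg", universe[:836])
        de = universe[:44] + universe[1000:1105]  # 44 of 149 in regulon
        result = regulon_fraction(de, regulon, universe)
        assert result.n_overlap == 44 and result.n_de == 149
        assert result.as_percent == 29.5
        assert result.render().startswith("29.5%")

    def test_disjoint_gives_zero(self):
        universe = [f"g{i}" for i in range(100)]
        regulon = GeneSet.from_iterable("reg", universe[:10])
        result = regulon_fraction(universe[50:60], regulon, universe)
        assert result.fraction == 0.0

    def test_empty_de_undefined(self):
        universe = ["a", "b"]
        result = regulon_fraction([], GeneSet.from_iterable("r", ["a"]), universe)
        assert math.isnan(result.fraction) and result.p_enrichment == 1.0

    def test_hypergeometric_matches_enumeration(self):
        universe = [f"g{i}" for i in range(30)]
        regulon = GeneSet.from_iterable("reg", universe[:12])
        for n_de, k in [(10, 4), (10, 8), (5, 5), (15, 6)]:
            de = universe[:k] + universe[12 : 12 + n_de - k]
            result = regulon_fraction(de, regulon, universe)
            oracle = float(hypergeom_tail_exact(k, 30, 12, n_de))
            assert result.p_enrichment == pytest.approx(oracle, rel=1e-9)

    def test_subset_violation_is_error(self):
        with pytest.raises(ValueError, match="subset"):
            regulon_fraction(["x"], GeneSet.from_iterable("r", ["a"]), ["a"])


class TestCompareFractions:
    @staticmethod
    def _fr(k, n):
        return FractionResult(n_de=n, n_overlap=k, universe_size=8000,
                              regulon_size=836, p_enrichment=0.5)

    def test_published_ratio(self):
        comp = compare_fractions(self._fr(55, 354), self._fr(44, 149))
        assert comp.ratio == pytest.approx(0.525, abs=0.005)

    def test_equal_fractions_ratio_one(self):
        comp = compare_fractions(self._fr(30, 100), self._fr(30, 100))
        assert comp.ratio == pytest.approx(1.0)

    def test_z_test_tracks_fisher_exact(self):
        from hifburden import ContingencyTable2x2, fisher_exact_two_sided

        comp = compare_fractions(self._fr(60, 363), self._fr(43, 154))
        fet = fisher_exact_two_sided(
            ContingencyTable2x2(60, 43, 363 - 60, 154 - 43)
        )
        assert comp.p_value == pytest.approx(fet, abs=0.02)

    def test_zero_reference_undefined(self):
        comp = compare_fractions(self._fr(5, 100), self._fr(0, 100))
        assert math.isnan(comp.ratio)


class TestHighFoldFilter:
    def test_strict_threefold_boundary(self):
        frame = pd.DataFrame(
            {"lfc": [math.log2(3.0), math.log2(3.0) + 1e-9, 2.0, -2.0]},
            index=["at", "above", "up4", "down4"],
        )
        assert highfold_filter(frame, min_fold=3) == ["above", "up4"]
        assert highfold_filter(frame, min_fold=3, direction="down") == ["down4"]

    def test_truth_thresholding_on_simulated_folds(self):
        rng = np.random.default_rng(10)
        lfc = rng.normal(0, 2, 500)
        frame = pd.DataFrame({"lfc": lfc}, index=[f"g{i}" for i in range(500)])
        selected = set(highfold_filter(frame, min_fold=3))
        expected = {f"g{i}" for i in range(500) if 2.0 ** lfc[i] > 3.0}
        assert selected == expected
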