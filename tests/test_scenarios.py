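"""Stratification scenarios, penetrance model, type-I-error / power
evaluation and the benchmark orchestration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import rarestrat as rs


@pytest.fixture(scope="module")
def labels3():
    return np.repeat(["north", "middle", "south"], [100, 300, 400])


class TestNullPhenotypes:
    def test_no_ps_proportional_allocation(self, labels3):
        y = rs.assign_null_phenotypes(labels3, rs.no_ps(), replicate_seed=1)
        assert y.sum() == round(0.15 * 800)
        for sp, size in (("north", 100), ("middle", 300), ("south", 400)):
            frac = y[labels3 == sp].mean()
            assert frac == pytest.approx(0.15, abs=0.01)  # rounding only

    def test_high_ps_single_subpopulation(self, labels3):
        spec = rs.ScenarioSpec("HighPS", 0.10, (0.0, 0.0, 1.0))
        y = rs.assign_null_phenotypes(labels3, spec, replicate_seed=2)
        assert y.sum() == 80
        assert set(labels3[y == 1]) == {"south"}

    def test_seeding(self, labels3):
        spec = rs.moderate_ps(3)
        y1 = rs.assign_null_phenotypes(labels3, spec, replicate_seed=5)
        y2 = rs.assign_null_phenotypes(labels3, spec, replicate_seed=5)
        y3 = rs.assign_null_phenotypes(labels3, spec, replicate_seed=6)
        np.testing.assert_array_equal(y1, y2)
        assert (y1 != y3).any()

    def test_infeasible_allocation_reports_shortfall(self, labels3):
        # weights align with sorted labels (middle, north, south)
        spec = rs.ScenarioSpec("bad", 0.8, (0.0, 1.0, 0.0))  # 640 cases from 100 north
        with pytest.raises(ValueError, match="north"):
            rs.assign_null_phenotypes(labels3, spec, replicate_seed=0)

    def test_phenotype_independent_of_genotype_within_subpop(self, small_cohort):
        """Given labels, case assignment is simple random sampling, so the
        carrier-case count of any variant is exactly hypergeometric: its
        standardized value over replicates has mean 0 and variance 1."""
        labels = small_cohort.subpop_labels
        mask = labels == "middle"
        g = small_cohort.genotypes[mask]
        carriers = g > 0
        counts = carriers.sum(axis=0)
        cols = np.flatnonzero((counts >= 5) & (counts <= carriers.shape[0] - 5))
        n_sub = carriers.shape[0]
        zs = []
        for rep in range(200):
            y = rs.assign_null_phenotypes(labels, rs.no_ps(), replicate_seed=100 + rep)
            k = int(y[mask].sum())
            a = carriers[y[mask] == 1].sum(axis=0)[cols]
            m = counts[cols]
            mean = k * m / n_sub
            var = k * m * (n_sub - m) * (n_sub - k) / (n_sub**2 * (n_sub - 1))
            zs.append((a - mean) / np.sqrt(var))
        z = np.concatenate(zs)
        assert abs(z.mean()) < 0.05
        assert z.var() == pytest.approx(1.0, abs=0.15)


class TestSmallSampleDesign:
    def test_matched_design_single_subpopulation(self, labels3):
        design = rs.SmallSampleDesign(50, "south", 100, "south")
        subset, y = rs.build_small_sample_design(labels3, design, seed=3)
        assert subset.size == 150 and y.sum() == 50
        assert set(labels3[subset]) == {"south"}
        assert len(set(subset)) == 150  # no duplicated individual

    def test_worldwide_control_panel(self, labels3):
        design = rs.SmallSampleDesign(50, "south", 400, None)
        subset, y = rs.build_small_sample_design(labels3, design, seed=4)
        cases, controls = subset[y == 1], subset[y == 0]
        assert set(labels3[cases]) == {"south"}
        assert controls.size == 400
        assert not set(cases) & set(controls)

    def test_insufficient_pool_rejected(self, labels3):
        design = rs.SmallSampleDesign(150, "north", 10, "north")
        with pytest.raises(ValueError, match="cases"):
            rs.build_small_sample_design(labels3, design, seed=1)


class TestPenetrance:
    def test_worked_example(self):
        pen = rs.compute_penetrance(0.2, 0.05, 3.0)
        assert pen.f_noncarrier == pytest.approx(0.0357143, abs=1e-7)
        assert pen.f_carrier == pytest.approx(0.1071429, abs=1e-7)

    def test_rr_one_is_null(self):
        pen = rs.compute_penetrance(0.3, 0.12, 1.0)
        assert pen.f_carrier == pen.f_noncarrier == pytest.approx(0.12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        p=st.floats(0.01, 0.99),
        k=st.floats(0.01, 0.6),
        rr=st.floats(1.0, 4.0),
    )
    def test_mixture_and_rr_identities(self, p, k, rr):
        try:
            pen = rs.compute_penetrance(p, k, rr)
        except ValueError:
            assert rr * k / (p * rr + 1 - p) > 1.0
            return
        assert p * pen.f_carrier + (1 - p) * pen.f_noncarrier == pytest.approx(k, abs=1e-12)
        assert pen.f_carrier / pen.f_noncarrier == pytest.approx(rr, rel=1e-12)
        assert 0 <= pen.f_noncarrier <= pen.f_carrier <= 1

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            rs.compute_penetrance(0.01, 0.6, 4.0)


class TestPowerGenes:
    def test_selection_properties(self, small_cohort):
        genes = rs.select_power_genes(small_cohort, n_genes=5, seed=1)
        passing = set(rs.gene_filter(small_cohort, min_carriers=10))
        for pg in genes:
            assert pg.gene in passing
            assert pg.carrier_count >= 10
            assert set(pg.causal_indices) <= set(pg.variant_indices)

    def test_causal_rounding_half_up(self, small_cohort):
        genes = rs.select_power_genes(small_cohort, n_genes=5, causal_fraction=0.5, seed=2)
        for pg in genes:
            m = len(pg.variant_indices)
            assert len(pg.causal_indices) == int(np.floor(m * 0.5 + 0.5))

    def test_causal_fraction_one_marks_all(self, small_cohort):
        genes = rs.select_power_genes(small_cohort, n_genes=3, causal_fraction=1.0, seed=3)
        for pg in genes:
            assert len(pg.causal_indices) == len(pg.variant_indices)

    def test_too_few_eligible_genes_reported(self, small_cohort):
        with pytest.raises(ValueError, match="eligible"):
            rs.select_power_genes(small_cohort, n_genes=10_000)


class TestAltPhenotypes:
    def test_rr_one_independent_of_carrier(self, labels3, rng):
        carrier = rng.random(800) < 0.2
        y = rs.simulate_alt_phenotypes(labels3, carrier, rs.no_ps(), 1.0, 11)
        # carrier and non-carrier case rates agree up to sampling noise
        r_c, r_n = y[carrier].mean(), y[~carrier].mean()
        assert abs(r_c - r_n) < 0.08

    def test_case_rate_ratio_matches_rr(self, rng):
        labels = np.repeat(["a"], 2000)
        carrier = rng.random(2000) < 0.2
        rates = []
        for rep in range(20):
            y = rs.simulate_alt_phenotypes(labels, carrier, rs.no_ps(), 3.0, 50 + rep)
            rates.append((y[carrier].mean(), y[~carrier].mean()))
        r_c = np.mean([r[0] for r in rates])
        r_n = np.mean([r[1] for r in rates])
        assert r_c / r_n == pytest.approx(3.0, rel=0.12)

    def test_expected_case_fraction_preserved(self, labels3, rng):
        carrier = rng.random(800) < 0.25
        fracs = [
            rs.simulate_alt_phenotypes(labels3, carrier, rs.high_ps(3), 4.0, s).mean()
            for s in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(0.15, abs=0.01)

    def test_high_ps_cases_confined(self, labels3, rng):
        carrier = rng.random(800) < 0.25
        y = rs.simulate_alt_phenotypes(labels3, carrier, rs.high_ps(3), 4.0, 77)
        assert set(labels3[y == 1]) <= {"middle"}  # alphabetically first label


class TestEvaluation:
    def test_printed_prediction_interval_bounds(self):
        """alpha = 0.001, 10 methods: PI [0.00079, 0.00121] for both
        G = 176,190 and G = 178,540."""
        for g_total in (17_619 * 10, 17_854 * 10):
            p = np.linspace(1e-6, 1, g_total)  # placeholder sample of size G
            res = rs.evaluate_type1(p, alpha=0.001, n_methods=10)
            assert round(res.pi_lower, 5) == 0.00079
            assert round(res.pi_upper, 5) == 0.00121

    def test_interval_formula_single_method(self):
        p = np.linspace(1e-6, 1, 10_000)
        res = rs.evaluate_type1(p, alpha=0.01, n_methods=1)
        half = 1.959964 * np.sqrt(0.01 * 0.99 / 10_000)
        assert res.pi_lower == pytest.approx(0.01 - half, abs=1e-6)
        assert res.pi_upper == pytest.approx(0.01 + half, abs=1e-6)

    def test_all_ones_conservative(self):
        res = rs.evaluate_type1(np.ones(1000), alpha=0.01, n_methods=2)
        assert res.fp == 0.0 and res.verdict == "conservative"

    def test_missing_pvalues_excluded(self):
        p = np.array([0.001, np.nan, 0.5, np.nan])
        res = rs.evaluate_type1(p, alpha=0.01, n_methods=1)
        assert res.G == 2 and res.n_excluded == 2
        assert res.fp == 0.5

    def test_power_arithmetic(self):
        p = np.concatenate([np.zeros(2500), np.ones(2500)])
        est = rs.evaluate_power(p, alpha=0.001)
        assert est.power == 0.5 and est.n_tests == 5000
        assert rs.evaluate_power(np.zeros(10), 0.05).power == 1.0


@pytest.fixture(scope="module")
def bench_setup():
    model = rs.PopulationModel(
        subpop_sizes=(150, 150), fst=0.1, n_genes=60, seed=71, subpop_names=("A", "B")
    )
    ds = rs.simulate_genotype_dataset(model)
    pre = rs.pretreat(ds, B=500, perm_seed=9)
    return ds, pre


class TestBenchmark:

    def test_same_seed_identical_tables(self, bench_setup):
        ds, pre = bench_setup
        spec = rs.no_ps()
        r1 = rs.run_benchmark(ds, spec, replicates=2, seed=13, pretreatment=pre)
        r2 = rs.run_benchmark(ds, spec, replicates=2, seed=13, pretreatment=pre)
        assert r1.pvalues.equals(r2.pvalues)

    def test_unstructured_cast_calibrated(self):
        model = rs.PopulationModel(subpop_sizes=(400,), fst=0.01, n_genes=250, seed=41)
        ds = rs.simulate_genotype_dataset(model)
        res = rs.run_benchmark(ds, rs.no_ps(), methods=("CAST",), replicates=5, seed=15)
        ev = res.evaluate(0.01, n_methods=1).iloc[0]
        assert ev["verdict"] == "within"

    def test_high_ps_inflates_cast_but_not_locperm(self, bench_setup):
        ds, pre = bench_setup
        spec = rs.high_ps(2)
        res = rs.run_benchmark(
            ds, spec, methods=("CAST", "LocPerm"), replicates=10, seed=17, pretreatment=pre
        )
        ev = res.evaluate(0.01).set_index("method")
        assert ev.loc["CAST", "fp"] > ev.loc["CAST", "pi_upper"]
        assert ev.loc["LocPerm", "verdict"] == "within"

    def test_wss_benchmark_path(self, bench_setup):
        ds, _ = bench_setup
        res = rs.run_benchmark(ds, rs.no_ps(), methods=("WSS",), replicates=2, seed=29)
        p = res.pvalues["p"].to_numpy()
        ok = np.isfinite(p)
        assert ok.mean() > 0.95  # a stray separation flag is tolerated
        assert ((p[ok] >= 0) & (p[ok] <= 1)).all()
        # matches the per-gene public API on a sampled gene
        y = rs.assign_null_phenotypes(ds.subpop_labels, rs.no_ps(), replicate_seed=30)
        gene = res.pvalues["gene"].iloc[0]
        sel = rs.select_gene_variants(ds, gene)
        single = rs.logistic_lrt(y, rs.wss_score(sel))
        scan = rs.run_benchmark(
            ds, rs.no_ps(), methods=("WSS",), replicates=1, seed=29
        )
        row = scan.pvalues[(scan.pvalues.gene == gene)].iloc[0]
        assert row["p"] == pytest.approx(single.p, abs=1e-5)  # float32 score cache

    def test_power_monotone_in_rr(self, bench_setup):
        ds, pre = bench_setup
        genes = rs.select_power_genes(ds, n_genes=3, seed=19)
        table = rs.run_power(
            ds, rs.no_ps(), genes, methods=("CAST",), rrs=(1, 3), replicates=30,
            seed=23, pretreatment=pre,
        )
        p1 = rs.evaluate_power(table[table.rr == 1].p, 0.01).power
        p3 = rs.evaluate_power(table[table.rr == 3].p, 0.01).power
        assert p3 > p1
        assert p1 < 0.1
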