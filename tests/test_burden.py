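"""Exact 2x2 inference, carrier tables and the burden screen."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from turnerx.burden import (
    ContingencyTable2x2,
    PhenotypeGroups,
    bonferroni,
    classify_effect,
    cmle_odds_ratio,
    common_af_window,
    fisher_exact_two_sided,
    gene_level_carriers,
    in_par,
    run_burden,
    variant_level_carriers,
)
from turnerx.types import CohortTable

from conftest import make_samples, make_variants


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Integer-exact enumeration of the point-probability two-sided rule."""
    n1, K, N = a + b, a + c, a + b + c + d
    if n1 == 0 or c + d == 0 or K == 0 or b + d == 0:
        return 1.0
    kmin, kmax = max(0, n1 - (N - K)), min(n1, K)
    weights = {k: comb(K, k) * comb(N - K, n1 - k) for k in range(kmin, kmax + 1)}
    total = comb(N, n1)
    thr = weights[a] * (1.0 + 1e-7)
    return sum(w for w in weights.values() if w <= thr) / total


def cmle_grid_oracle(a: int, b: int, c: int, d: int) -> float:
    """Maximize the conditional noncentral-hypergeometric likelihood numerically."""
    n1, K, N = a + b, a + c, a + b + c + d
    kmin, kmax = max(0, n1 - (N - K)), min(n1, K)
    k = np.arange(kmin, kmax + 1)
    logw = (gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
            + gammaln(N - K + 1) - gammaln(n1 - k + 1) - gammaln(N - K - n1 + k + 1))

    def neg_loglik(t):
        terms = logw + k * t
        m = terms.max()
        return -(logw[k == a][0] + a * t - (m + np.log(np.exp(terms - m).sum())))

    res = minimize_scalar(neg_loglik, bounds=(-30, 30), method="bounded",
                          options={"xatol": 1e-12})
    return math.exp(res.x)


def random_tables(n, seed, max_margin=30, nondegenerate=True):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        a, b, c, d = (int(x) for x in rng.integers(0, max_margin // 2 + 1, 4))
        t = ContingencyTable2x2(a, b, c, d)
        if nondegenerate and t.is_degenerate():
            continue
        out.append(t)
    return out


class TestFisherExact:
    @pytest.mark.parametrize("table,printed", [
        ((10, 6, 5, 31), "0.0007"),   # hypertension-enriched gene
        ((9, 8, 3, 32), "0.0008"),    # cardiac-anomaly-enriched gene
        ((10, 9, 7, 46), "0.001"),
        ((9, 10, 6, 47), "0.002"),
    ])
    def test_reconstructed_gene_tables(self, table, printed):
        p = fisher_exact_two_sided(ContingencyTable2x2(*table))
        assert f"{p:.1g}" == printed

    def test_symmetric_table_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(0, 0, 3, 4), (3, 4, 0, 0), (0, 3, 0, 4), (3, 0, 4, 0)])
    def test_degenerate_margin_is_one(self, table):
        assert fisher_exact_two_sided(ContingencyTable2x2(*table)) == 1.0

    def test_matches_enumeration_oracle(self):
        for t in random_tables(300, seed=0):
            p = fisher_exact_two_sided(t)
            p_or = fisher_oracle(t.a, t.b, t.c, t.d)
            assert abs(p - p_or) < 1e-12, (t, p, p_or)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_invariant_to_row_and_column_swap(self, cells):
        a, b, c, d = cells
        t = ContingencyTable2x2(a, b, c, d)
        p = fisher_exact_two_sided(t)
        assert fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_two_sided(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p, rel=1e-9)


class TestCmleOddsRatio:
    @pytest.mark.parametrize("table,expected", [
        ((10, 6, 5, 31), 9.73),
        ((9, 8, 3, 32), 11.26),
    ])
    def test_reconstructed_gene_tables(self, table, expected):
        or_hat, _ = cmle_odds_ratio(ContingencyTable2x2(*table))
        assert round(or_hat, 2) == expected

    def test_matches_grid_search_oracle(self):
        for t in random_tables(60, seed=1):
            or_hat, _ = cmle_odds_ratio(t)
            if or_hat in (0.0, math.inf):
                continue
            oracle = cmle_grid_oracle(t.a, t.b, t.c, t.d)
            assert or_hat == pytest.approx(oracle, rel=1e-6)

    def test_matches_scipy_conditional(self):
        from scipy.stats.contingency import odds_ratio
        for t in random_tables(40, seed=2):
            or_hat, ci = cmle_odds_ratio(t)
            ref = odds_ratio(t.as_array(), kind="conditional")
            ref_ci = ref.confidence_interval(0.95)
            assert or_hat == pytest.approx(ref.statistic, rel=1e-5, abs=1e-10)
            assert ci[0] == pytest.approx(ref_ci.low, rel=1e-4, abs=1e-8)
            assert ci[1] == pytest.approx(ref_ci.high, rel=1e-4,
                                          abs=1e-8) or (math.isinf(ci[1])
                                                        and math.isinf(ref_ci.high))

    def test_boundary_cells(self):
        or0, ci0 = cmle_odds_ratio(ContingencyTable2x2(0, 5, 3, 2))
        assert or0 == 0.0 and ci0[0] == 0.0 and ci0[1] > 0
        orinf, ciinf = cmle_odds_ratio(ContingencyTable2x2(5, 0, 0, 5))
        assert math.isinf(orinf) and math.isinf(ciinf[1]) and ciinf[0] > 0

    def test_degenerate_undefined(self):
        or_hat, ci = cmle_odds_ratio(ContingencyTable2x2(0, 0, 3, 4))
        assert math.isnan(or_hat)

    def test_sign_consistent_with_effect_size(self):
        for t in random_tables(100, seed=3):
            or_hat, _ = cmle_odds_ratio(t)
            delta = t.effect_size
            if math.isnan(or_hat) or abs(delta) < 1e-12:
                continue
            if (t.a and t.d) or (t.b and t.c):
                if or_hat not in (0.0, math.inf) and or_hat != 1.0:
                    assert (delta > 0) == (or_hat > 1), (t, delta, or_hat)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.01, 5, 0.05), (0.5, 3, 1.0), (0.2, 1, 0.2)])
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=st.floats(1e-9, 1.0), m1=st.integers(1, 1000), m2=st.integers(1, 1000))
    def test_monotone_and_dominates_p(self, p, m1, m2):
        assert bonferroni(p, m1) >= p - 1e-15
        if m1 <= m2:
            assert bonferroni(p, m1) <= bonferroni(p, m2) + 1e-15


class TestAfWindow:
    def test_boundary_and_missing(self):
        v = make_variants([
            {"sample_id": "S", "chrom": "X", "pos": 1, "pop_af": 0.09},
            {"sample_id": "S", "chrom": "X", "pos": 2, "pop_af": 0.10},
            {"sample_id": "S", "chrom": "X", "pos": 3, "pop_af": 0.90},
            {"sample_id": "S", "chrom": "X", "pos": 4, "pop_af": 0.91},
            {"sample_id": "S", "chrom": "X", "pos": 5, "pop_af": np.nan},
        ])
        kept = common_af_window(v)
        assert list(kept["pos"]) == [2, 3]

    def test_grid_matches_predicate(self):
        afs = np.round(np.arange(0.0, 1.0001, 0.05), 3)
        v = make_variants([{"sample_id": "S", "chrom": "X", "pos": i + 1, "pop_af": float(af)}
                           for i, af in enumerate(afs)])
        kept = common_af_window(v, 0.1, 0.9)
        expected = [i + 1 for i, af in enumerate(afs) if 0.1 <= af <= 0.9]
        assert list(kept["pos"]) == expected


def _grouped_cohort():
    """16 with-hypertension / 36 without among 52 monosomy samples."""
    phen = {}
    for i in range(52):
        phen[f"TS_monosomy_{i + 1:03d}"] = {"hypertension": 1 if i < 16 else 0}
    samples = make_samples({"TS_monosomy": 52}, phenotypes=phen)
    return samples


class TestCarrierTables:
    def test_known_proportions_give_expected_table(self):
        samples = _grouped_cohort()
        rows = []
        # 10 of 16 with-condition and 5 of 36 without carry >=1 variant in GENEA
        for i in list(range(10)) + list(range(16, 21)):
            rows.append({"sample_id": f"TS_monosomy_{i + 1:03d}", "chrom": "X",
                         "pos": 100 + i, "gene": "GENEA", "pop_af": 0.5})
        cohort = CohortTable(variants=make_variants(rows), samples=samples)
        groups = PhenotypeGroups.from_cohort(cohort, "hypertension")
        tables = gene_level_carriers(cohort.variants, groups)
        t = tables["GENEA"]
        assert (t.a, t.b, t.c, t.d) == (10, 6, 5, 31)
        assert t.prop_with == pytest.approx(0.63, abs=0.0051)
        assert t.prop_without == pytest.approx(0.14, abs=0.0051)

    def test_multiple_variants_count_sample_once(self):
        samples = _grouped_cohort()
        rows = [{"sample_id": "TS_monosomy_001", "chrom": "X", "pos": p,
                 "gene": "GENEB", "pop_af": 0.4} for p in (1, 2, 3)]
        cohort = CohortTable(variants=make_variants(rows), samples=samples)
        groups = PhenotypeGroups.from_cohort(cohort, "hypertension")
        t = gene_level_carriers(cohort.variants, groups)["GENEB"]
        assert t.a == 1

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(8)
        samples = _grouped_cohort()
        ids = samples["sample_id"].tolist()
        rows = [{"sample_id": ids[int(rng.integers(0, len(ids)))], "chrom": "X",
                 "pos": int(rng.integers(1, 40)),
                 "gene": f"G{rng.integers(1, 6)}", "pop_af": 0.5}
                for _ in range(120)]
        v = make_variants(rows).drop_duplicates(
            subset=["sample_id", "chrom", "pos", "ref", "alt"]).reset_index(drop=True)
        cohort = CohortTable(variants=v, samples=samples)
        groups = PhenotypeGroups.from_cohort(cohort, "hypertension")
        for level, keyer in (("gene", lambda r: r["gene"]),
                             ("variant", lambda r: f"{r['chrom']}|{r['pos']}|{r['ref']}|{r['alt']}")):
            tables = (gene_level_carriers(v, groups) if level == "gene"
                      else variant_level_carriers(v, groups))
            units = {}
            for _, r in v.iterrows():
                units.setdefault(keyer(r), set()).add(r["sample_id"])
            for unit, carriers in units.items():
                t = tables[unit]
                assert t.a == len(carriers & groups.with_ids)
                assert t.c == len(carriers & groups.without_ids)
                assert t.a + t.b == len(groups.with_ids)
                assert t.c + t.d == len(groups.without_ids)

    def test_variant_absent_from_groups_not_reported(self):
        samples = make_samples({"TS_monosomy": 2, "XX_control": 1},
                               phenotypes={"TS_monosomy_001": {"cca": 1},
                                           "TS_monosomy_002": {"cca": 0}})
        v = make_variants([{"sample_id": "XX_control_001", "chrom": "X", "pos": 9,
                            "gene": "GX", "pop_af": 0.5}])
        cohort = CohortTable(variants=v, samples=samples)
        groups = PhenotypeGroups.from_cohort(cohort, "cca")
        assert variant_level_carriers(
            v[v["sample_id"].isin(groups.with_ids | groups.without_ids)], groups) == {}


class TestRunBurden:
    def test_equals_stepwise_composition(self):
        samples = _grouped_cohort()
        rng = np.random.default_rng(9)
        ids = samples["sample_id"].tolist()
        rows = [{"sample_id": ids[int(rng.integers(0, len(ids)))], "chrom": "X",
                 "pos": int(rng.integers(1, 60)), "gene": f"G{rng.integers(1, 5)}",
                 "pop_af": float(rng.uniform(0.05, 0.95))} for _ in range(150)]
        v = make_variants(rows).drop_duplicates(
            subset=["sample_id", "chrom", "pos", "ref", "alt"]).reset_index(drop=True)
        cohort = CohortTable(variants=v, samples=samples)
        results = run_burden(cohort, "hypertension", compute_or=False)
        # independent stepwise composition
        groups = PhenotypeGroups.from_cohort(cohort, "hypertension")
        qualifying = common_af_window(v[v["chrom"] == "X"])
        tables = {u: t for u, t in gene_level_carriers(qualifying, groups).items()
                  if t.a + t.c > 0}
        assert {r.unit_id for r in results} == set(tables)
        for r in results:
            t = tables[r.unit_id]
            assert r.p_fisher == pytest.approx(fisher_exact_two_sided(t))
            assert r.p_adj == pytest.approx(bonferroni(r.p_fisher, len(tables)))
            assert r.effect_size == pytest.approx(t.effect_size)
            assert r.m_tests == len(tables)
        # sorted by |effect size| descending
        effs = [abs(r.effect_size) for r in results]
        assert effs == sorted(effs, reverse=True)

    def test_empty_analysis_set_fatal(self):
        samples = make_samples({"TS_monosomy": 2})  # all phenotypes unknown
        cohort = CohortTable(variants=make_variants([]), samples=samples)
        with pytest.raises(ValueError, match="empty analysis set"):
            run_burden(cohort, "diabetes")

    def test_flag_threshold_is_strict(self):
        assert classify_effect(0.35) == "none"
        assert classify_effect(0.3500001) == "risk"
        assert classify_effect(-0.35) == "none"
        assert classify_effect(-0.36) == "protective"


def test_par_region_membership():
    assert in_par(1_601_004)          # short-arm pseudoautosomal gene
    assert in_par(155_701_383)
    assert not in_par(3_000_000)
    assert not in_par(10_000)
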