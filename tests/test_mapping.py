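"""Map functions, two-point estimation, order search and heterogeneity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from arcsim import (
    ColonyGenotype,
    ConfigError,
    MarkerPanel,
    SimulationConfig,
    collapse_prefix_groups,
    founder_haplotype,
    heterogeneity_test,
    infer_testcross_parents,
    inverse_map_function,
    map_function,
    multipoint_loglik,
    order_search,
    score_recombinants,
    simulate_cross,
    two_point,
)
from arcsim.mapping import DesignError, _canonical


class TestMapFunctions:
    def test_zero_distance(self):
        for kind in ("haldane", "kosambi"):
            assert map_function(0.0, kind) == 0.0
            assert inverse_map_function(0.0, kind) == 0.0

    @pytest.mark.parametrize(
        "d, expected_r",
        [(1.6, 0.0157467089604012), (30.5, 0.2283245654627501)],
    )
    def test_haldane_inverse_closed_form(self, d, expected_r):
        assert math.isclose(inverse_map_function(d, "haldane"), expected_r, rel_tol=1e-12)

    @pytest.mark.parametrize("kind", ["haldane", "kosambi"])
    def test_round_trip_identity(self, kind):
        for r in np.linspace(0.0, 0.49, 200):
            d = map_function(float(r), kind)
            assert abs(inverse_map_function(d, kind) - r) < 1e-10

    def test_unbounded_distance_rejected(self):
        with pytest.raises(ConfigError):
            map_function(0.5)
        with pytest.raises(ConfigError):
            map_function(0.6, "kosambi")

    def test_kosambi_shorter_than_haldane(self):
        # partial interference compresses distances for the same r
        assert map_function(0.2, "kosambi") < map_function(0.2, "haldane")


class TestTwoPoint:
    def test_no_recombinants(self):
        est = two_point(0, 100)
        assert est.r_hat == 0.0
        assert est.d_cM == 0.0
        assert est.lod == pytest.approx(100 * math.log10(2))

    def test_quarter_recombinants_haldane(self):
        est = two_point(25, 100, "haldane")
        assert est.r_hat == 0.25
        assert est.d_cM == pytest.approx(34.657359, abs=1e-5)

    def test_free_recombination(self):
        est = two_point(50, 100)
        assert est.r_hat == 0.5
        assert est.lod == pytest.approx(0.0, abs=1e-12)
        assert math.isinf(est.d_cM)

    def test_no_information_raises(self):
        with pytest.raises(DesignError):
            two_point(0, 0)

    def test_se_is_binomial(self):
        est = two_point(30, 300)
        assert est.se == pytest.approx(math.sqrt(0.1 * 0.9 / 300))


class TestScoreRecombinants:
    def test_all_parental(self, panel, founders, ff, fd, config):
        cfg = SimulationConfig(seed=2, map_distances_cM=(0.0, 0.0, 0.0))
        _, table = simulate_cross(ff, fd, 80, panel, cfg)
        R, N = score_recombinants(table, fd, ff, "194m6", "174m4")
        assert (R, N) == (0, 80)

    def test_missing_call_excluded(self, panel, founders, ff, fd, config):
        _, table = simulate_cross(ff, fd, 10, panel, config)
        table.loc[0, "174m4"] = "-"
        R, N = score_recombinants(table, fd, ff, "194m6", "174m4")
        assert N == 9

    def test_monte_carlo_matches_closed_form(self, founders):
        two = MarkerPanel(("194m6", "174m4"))
        f2, d2 = founder_haplotype("f", two), founder_haplotype("d", two)
        parent = ColonyGenotype("fd", (f2, d2))
        tester = ColonyGenotype("ff", (f2, f2))
        cfg = SimulationConfig(seed=31, map_distances_cM=(30.5,))
        n = 10_000
        _, table = simulate_cross(tester, parent, n, two, cfg)
        R, N = score_recombinants(table, parent, tester, "194m6", "174m4")
        r = inverse_map_function(30.5)
        assert N == n
        assert abs(R / N - r) < 3 * math.sqrt(r * (1 - r) / n)

    def test_phase_inference_agrees_with_known_parents(self, panel, ff, fd, config):
        _, table = simulate_cross(ff, fd, 400, panel, config)
        informative, tester = infer_testcross_parents(table, list(panel.markers))
        for a, b in [("194m6", "18m1"), ("194m6", "174m4")]:
            assert score_recombinants(table, informative, tester, a, b) == \
                score_recombinants(table, fd, ff, a, b)


class TestPrefixCollapsing:
    def make_table(self, rows):
        return pd.DataFrame(rows)

    def test_agreeing_markers_collapse(self):
        panel = MarkerPanel(("194m6", "194c17", "174m4"))
        t = self.make_table(
            {"individual": ["a"], "194m6": ["f/f"], "194c17": ["f/f"], "174m4": ["d/f"]}
        )
        out, diag = collapse_prefix_groups(t, panel)
        assert list(out.columns) == ["individual", "194", "174"]
        assert out.loc[0, "194"] == "f/f"
        assert diag == {"194": 0, "174": 0}

    def test_disagreement_set_missing_and_logged(self):
        panel = MarkerPanel(("194m6", "194c17", "174m4"))
        t = self.make_table(
            {"individual": ["a"], "194m6": ["f/f"], "194c17": ["d/f"], "174m4": ["d/f"]}
        )
        out, diag = collapse_prefix_groups(t, panel)
        assert out.loc[0, "194"] == "-"
        assert diag["194"] == 1

    def test_unique_prefixes_unchanged(self, panel):
        t = self.make_table(
            {
                "individual": ["a"],
                "194m6": ["f/f"],
                "18m1": ["d/f"],
                "28m6": ["f/f"],
                "174m4": ["d/f"],
            }
        )
        out, _ = collapse_prefix_groups(t, panel)
        assert list(out["194"]) == ["f/f"]
        assert list(out["174"]) == ["d/f"]


class TestMultipointAndOrder:
    def test_two_marker_panel_single_order(self, founders, ff, fd):
        two = MarkerPanel(("194m6", "174m4"))
        f2, d2 = founder_haplotype("f", two), founder_haplotype("d", two)
        parent = ColonyGenotype("fd", (f2, d2))
        tester = ColonyGenotype("ff", (f2, f2))
        cfg = SimulationConfig(seed=3, map_distances_cM=(20.0,))
        _, table = simulate_cross(tester, parent, 100, two, cfg)
        ranking = order_search(table, two, parent, tester)
        assert len(ranking.orders) == 1
        assert ranking.rel_log10_likelihood == (0.0,)

    def test_two_markers_reduce_to_two_point_likelihood(self, panel, ff, fd, config):
        _, table = simulate_cross(ff, fd, 200, panel, config)
        R, N = score_recombinants(table, fd, ff, "194m6", "18m1")
        ll = multipoint_loglik(table, ("194m6", "18m1"), fd, ff)
        r = R / N
        manual = (R * math.log10(r) if R else 0.0) + (
            (N - R) * math.log10(1 - r) if N - R else 0.0
        )
        assert ll == pytest.approx(manual)

    def test_zero_recombinants_all_orders_tie(self, panel, ff, fd):
        cfg = SimulationConfig(seed=4, map_distances_cM=(0.0, 0.0, 0.0))
        _, table = simulate_cross(ff, fd, 60, panel, cfg)
        ranking = order_search(table, panel, fd, ff)
        assert all(v == 0.0 for v in ranking.rel_log10_likelihood)
        assert len(ranking.ties) == len(ranking.orders)

    def test_generating_order_recovered(self, panel, ff, fd):
        cfg = SimulationConfig(seed=6, map_distances_cM=(12.0, 6.0, 12.0))
        _, table = simulate_cross(ff, fd, 500, panel, cfg)
        ranking = order_search(table, panel, fd, ff)
        assert ranking.best == _canonical(panel.markers)
        assert all(v <= 0 for v in ranking.rel_log10_likelihood)

    def test_reversal_orders_deduplicated(self, panel, ff, fd, config):
        _, table = simulate_cross(ff, fd, 50, panel, config)
        ranking = order_search(table, panel, fd, ff)
        assert len(ranking.orders) == math.factorial(4) // 2
        seen = {o for o in ranking.orders}
        assert not any(o[::-1] in seen and o[::-1] != o for o in seen)

    def test_odds_ratio_convention(self):
        from arcsim import OrderRanking

        ranking = OrderRanking(
            orders=(("a", "b"), ("b", "a")), rel_log10_likelihood=(0.0, -1.74)
        )
        assert ranking.odds_against(1) == pytest.approx(10**1.74)
        assert ranking.odds_against(1) == pytest.approx(54.954, abs=1e-3)

    def test_too_many_markers_rejected(self, ff, fd):
        panel9 = MarkerPanel(tuple(f"{i}m1" for i in range(1, 10)))
        with pytest.raises(DesignError):
            order_search(pd.DataFrame(), panel9, fd, ff)


class TestHeterogeneity:
    def test_identical_crosses_show_no_heterogeneity(self):
        res = heterogeneity_test([(20, 100), (20, 100)])
        assert res.g_het == pytest.approx(0.0, abs=1e-12)
        assert res.p_het == pytest.approx(1.0)

    def test_matches_contingency_g_test(self):
        """g_het equals the 2x2 G-test of independence on the
        recombinant/parental table (independent scipy oracle)."""
        res = heterogeneity_test([(10, 100), (40, 100)])
        g, p, dof, _ = chi2_contingency(
            [[10, 90], [40, 60]], lambda_="log-likelihood", correction=False
        )
        assert res.g_het == pytest.approx(g, rel=1e-12)
        assert res.p_het == pytest.approx(p, rel=1e-9)
        assert res.df_het == dof
        assert res.p_het < 0.01

    def test_k_crosses_df(self):
        res = heterogeneity_test([(5, 50)] * 6)
        assert res.df_het == 5

    def test_degenerate_all_zero_recombinants(self):
        res = heterogeneity_test([(0, 50), (0, 80)])
        assert res.g_het == 0.0
        assert res.p_het == 1.0

    def test_g_decomposition_additivity(self):
        """g_pooled + g_het equals the independently computed total G of all
        crosses against the 1:1 null, on random inputs."""
        from arcsim.mapping import _g_binom

        rng = np.random.default_rng(12)
        for _ in range(200):
            k = rng.integers(2, 6)
            Ns = rng.integers(10, 500, size=k)
            Rs = [int(rng.integers(1, n)) for n in Ns]
            per_cross = list(zip(Rs, [int(n) for n in Ns]))
            res = heterogeneity_test(per_cross)
            g_total_direct = sum(_g_binom(R, N, 0.5) for R, N in per_cross)
            assert res.g_total == pytest.approx(g_total_direct, rel=1e-10)
            assert res.g_total == pytest.approx(res.g_pooled + res.g_het, rel=1e-12)
            assert res.g_het >= -1e-12

    def test_needs_two_crosses(self):
        with pytest.raises(DesignError):
            heterogeneity_test([(5, 50)])
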