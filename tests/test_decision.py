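"""Incremental analysis, tornado DSA, PSA/CEAC, scenarios, subgroups."""

import numpy as np
import pytest

from psmcea.decision import (
    ParameterSpec,
    StrategyResult,
    icer_table,
    net_monetary_benefit,
    run_subgroup,
    sample_psa_parameters,
)

LENV_PEMB = "lenvatinib_pembrolizumab"
LENV_EVER = "lenvatinib_everolimus"
SUNITINIB = "sunitinib"


class TestIcerTable:
    def test_published_row_arithmetic(self):
        """Delta cost 1,253,130 over delta QALY 0.47 gives 2,666,234 (the
        published 2,657,025 reflects an unrounded denominator)."""
        rows = icer_table(
            [
                StrategyResult("ref", 762_572.0, 2.13, 2.83),
                StrategyResult("cmp", 762_572.0 + 1_253_130.0, 2.13 + 0.47, 3.44),
            ],
            "ref",
        )
        assert rows[0].icer == pytest.approx(2_666_234.0425531915, rel=1e-12)

    def test_simple_division(self):
        rows = icer_table(
            [StrategyResult("a", 0.0, 1.0, 1.0), StrategyResult("b", 100.0, 1.5, 1.5)],
            "a",
        )
        assert rows[0].icer == pytest.approx(200.0)

    def test_dominance_labels(self):
        rows = icer_table(
            [
                StrategyResult("ref", 100.0, 1.0, 1.0),
                StrategyResult("cheap_better", 99.0, 1.1, 1.1),
                StrategyResult("dear_worse", 200.0, 0.9, 0.9),
            ],
            "ref",
        )
        labels = {r.comparator: r.label for r in rows}
        assert labels["cheap_better"] == "dominant"
        assert labels["dear_worse"] == "dominated"

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            icer_table(
                [StrategyResult("a", 0, 1, 1), StrategyResult("a", 1, 2, 2)], "a"
            )

    def test_antisymmetric_under_pair_swap(self):
        a = StrategyResult("a", 100.0, 1.0, 1.0)
        b = StrategyResult("b", 400.0, 1.5, 1.5)
        fwd = icer_table([a, b], "a")[0]
        rev = icer_table([a, b], "b")[0]
        assert fwd.delta_cost == -rev.delta_cost
        assert fwd.delta_qaly == -rev.delta_qaly
        assert fwd.icer == pytest.approx(rev.icer)


class TestNMB:
    def test_published_row(self):
        r = StrategyResult("sunitinib", 762_572.0, 2.13, 2.83)
        assert net_monetary_benefit(r, 217_341.0) == pytest.approx(-299_635.67, abs=0.01)

    def test_degenerate_cases(self):
        r = StrategyResult("s", 500.0, 1.0, 1.0)
        assert net_monetary_benefit(r, 0.0) == -500.0
        assert net_monetary_benefit(StrategyResult("s", 0.0, 1.0, 1.0), 321.0) == 321.0


class TestMomentMatching:
    def test_gamma_hand_computed(self):
        p = ParameterSpec("pembro", 179.18, 143.34, 215.02, "gamma", ("x",))
        m = p.moment_matched()
        assert p.sd == pytest.approx(18.28571428571429, abs=1e-9)
        assert m["shape"] == pytest.approx(96.01856369628905, abs=1e-6)
        assert m["scale"] == pytest.approx(1.8660974826363188, abs=1e-9)

    def test_beta_hand_computed(self):
        p = ParameterSpec("u_pfs", 0.82, 0.656, 0.984, "beta", ("x",))
        m = p.moment_matched()
        assert p.sd == pytest.approx(0.08367346938775509, abs=1e-12)
        assert m["alpha"] + m["beta"] == pytest.approx(20.081951219512206, abs=1e-6)
        assert m["alpha"] == pytest.approx(16.4672, abs=1e-4)

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpec("bad", 1.5, 1.0, 2.0, "beta", ("x",))

    def test_fixed_parameters_not_sampled(self):
        params = [
            ParameterSpec("cost", 100.0, 80.0, 120.0, "gamma", ("a",)),
            ParameterSpec("discount_rate", 0.05, 0.0, 0.08, "fixed", ("b",)),
        ]
        draws = sample_psa_parameters(params, 50, seed=1)
        assert list(draws.columns) == ["cost"]

    def test_sample_means_match_base_values(self):
        """Law of large numbers: draw means within 3 MC standard errors."""
        params = [
            ParameterSpec("pembro", 179.18, 143.34, 215.02, "gamma", ("a",)),
            ParameterSpec("u_pfs", 0.82, 0.656, 0.984, "beta", ("b",)),
            ParameterSpec("prop", 0.71, 0.57, 0.85, "beta", ("c",)),
        ]
        n = 10_000
        draws = sample_psa_parameters(params, n, seed=5)
        for p in params:
            se = p.sd / np.sqrt(n)
            assert abs(draws[p.name].mean() - p.base) < 3 * se

    def test_deterministic_given_seed(self):
        params = [ParameterSpec("c", 100.0, 80.0, 120.0, "gamma", ("a",))]
        a = sample_psa_parameters(params, 20, seed=9)
        b = sample_psa_parameters(params, 20, seed=9)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


class TestModelAnalyses:
    def test_zero_width_parameter_sorts_last(self, base_results):
        flat = ParameterSpec("flat", 353.0, 353.0, 353.0, "gamma",
                             ("shared.bsc_cost_per_cycle",))
        params = list(base_results.model.params.values()) + [flat]
        entries = base_results.one_way_dsa(
            pair=(LENV_PEMB, SUNITINIB), params=params
        )
        flat_entry = next(e for e in entries if e.name == "flat")
        assert flat_entry.width == 0.0
        assert entries[-1].width == 0.0  # zero-width bars sort to the bottom
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_icer_monotone_in_comparator_only_price(self, base_results):
        """Raising the pembrolizumab price can only raise the LP-vs-SU ICER."""
        model = base_results.model
        icers = []
        for price in (143.34, 179.18, 215.02):
            results = model.run(overrides={"price_pembrolizumab_per_mg": price})
            rows = icer_table(list(results.values()), SUNITINIB)
            icers.append(next(r.icer for r in rows if r.comparator == LENV_PEMB))
        assert icers[0] < icers[1] < icers[2]

    def test_degenerate_psa_all_fixed(self, base_results):
        """Zero-width distributions: every iteration identical, CEAC in {0,1}."""
        fixed = [ParameterSpec("u_pd", 0.66, 0.66, 0.66, "beta",
                               tuple(base_results.model.parameter("u_pd").paths))]
        from psmcea.decision import run_psa_and_ceac

        psa = run_psa_and_ceac(
            base_results.model.run, fixed, SUNITINIB, n_iter=20,
            wtp_grid=[0.0, 500_000.0], seed=3,
        )
        for col in psa.ceac.columns.drop("wtp"):
            assert set(np.unique(psa.ceac[col])) <= {0.0, 1.0}

    def test_ceac_probabilities_partition(self, base_results):
        psa = base_results.run_psa(n_iter=200, seed=11)
        probs = psa.ceac.drop(columns="wtp").to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        # the reference (cheapest at base) is the favourite at zero wtp
        at_zero = psa.ceac.loc[psa.ceac.wtp == 0.0].drop(columns="wtp").iloc[0]
        assert at_zero.idxmax() == SUNITINIB
        assert at_zero[SUNITINIB] > 0.5

    def test_psa_reproducible_and_quadrants_partition(self, base_results):
        a = base_results.run_psa(n_iter=100, seed=13)
        b = base_results.run_psa(n_iter=100, seed=13)
        assert a.samples.equals(b.samples)
        for shares in a.quadrants.values():
            assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_scenarios_price_identity_and_affinity(self, base_results):
        sc = base_results.scenarios(pair=(LENV_PEMB, SUNITINIB))
        price = sc["pembrolizumab_price"]
        assert price[0]["reduction"] == 0.0
        assert price[0]["icer_delta_vs_base"] == pytest.approx(0.0, abs=1e-9)
        icers = [p["icer"] for p in price]
        steps = np.diff(icers)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_horizon_scenarios_monotone_outcomes(self, base_results):
        sc = base_results.scenarios(pair=(LENV_PEMB, SUNITINIB))
        for strat in (SUNITINIB, LENV_PEMB, LENV_EVER):
            q5 = sc["horizon"]["5y"][strat]["qaly"]
            q20 = sc["horizon"]["20y"][strat]["qaly"]
            assert q20 >= q5
            frac = sc["horizon"]["20y"][strat]["cost_fraction_first_5y"]
            assert 0.0 < frac <= 1.0

    def test_subgroup_unit_hazard_ratios_recover_reference_curves(self, base_results):
        out = run_subgroup(base_results.model, "null", 1.0, 1.0, comparator=LENV_PEMB)
        comp = out["results"][LENV_PEMB]
        ref = out["results"][SUNITINIB]
        # identical curves: outcome differences stem only from utilities
        assert comp["ly"] == pytest.approx(ref["ly"], rel=1e-12)

    def test_subgroup_lower_os_hazard_more_qalys(self, base_results):
        better = run_subgroup(base_results.model, "x", 0.39, 0.5, comparator=LENV_PEMB)
        worse = run_subgroup(base_results.model, "y", 0.39, 0.9, comparator=LENV_PEMB)
        assert (
            better["results"][LENV_PEMB]["qaly"] > worse["results"][LENV_PEMB]["qaly"]
        )

    def test_unknown_parameter_path_raises(self, base_results):
        from psmcea.model import ConfigPathError

        with pytest.raises(ConfigPathError):
            base_results.model.run(overrides={"no_such_parameter": 1.0})
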