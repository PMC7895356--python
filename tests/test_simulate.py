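"""Cohort simulator: determinism, conservation, closed-form agreement,
attribution and intervention semantics."""

from __future__ import annotations

import numpy as np
import pytest

from nata.analytic import analytic_top_probability, p_naf_exponential
from nata.errors import NataError
from nata.model import ConstantRate, GateKind, NafNode, NonAdherenceTree
from nata.simulate import (
    SimulationConfig,
    apply_improvement,
    contributions,
    simulate,
    simulate_replicates,
    summarize_uncertainty,
)

from conftest import make_random_tree


def single_leaf_tree(rate: float) -> NonAdherenceTree:
    return NonAdherenceTree(
        nodes={
            "T": NafNode(id="T", kind="top", gate=GateKind.OR, children=("X",)),
            "X": NafNode(id="X", rate_model=ConstantRate(rate)),
        },
        top_id="T",
    )


class TestBasicBehaviour:
    def test_seed_determinism(self, covid):
        config = SimulationConfig(patients=300, days=5, seed=42)
        a = simulate(covid, config)
        b = simulate(covid, config)
        assert a == b

    def test_different_seeds_differ(self, covid):
        a = simulate(covid, SimulationConfig(patients=500, seed=1))
        b = simulate(covid, SimulationConfig(patients=500, seed=2))
        assert a.nac_by_day != b.nac_by_day

    def test_zero_rates_nobody_discontinues(self):
        tree = single_leaf_tree(0.0)
        res = simulate(tree, SimulationConfig(patients=200, days=10, seed=0))
        assert res.non_adherent == 0
        assert res.attributed == {}
        assert all(p == 0.0 for p in res.p_na_by_day)
        with pytest.raises(NataError, match="undefined"):
            contributions(res)

    def test_nac_monotone_and_conserved(self, covid):
        res = simulate(covid, SimulationConfig(patients=800, seed=3))
        assert list(res.nac_by_day) == sorted(res.nac_by_day)
        assert res.adherent + res.non_adherent == res.patients
        assert len(res.nac_by_day) == res.days
        assert sum(res.attributed.values()) == res.non_adherent

    def test_single_constant_leaf_matches_exponential_cdf(self):
        tree = single_leaf_tree(0.006)
        n = 4000
        res = simulate(tree, SimulationConfig(patients=n, days=10, seed=5))
        expected = p_naf_exponential(0.006, 10)
        se = np.sqrt(expected * (1 - expected) / n)
        assert res.final_p_na == pytest.approx(expected, abs=3 * se)

    def test_timestep_must_divide_day(self):
        with pytest.raises(ValueError):
            SimulationConfig(timestep_hours=7.0)

    def test_step_size_robustness(self, covid):
        """Halving the step changes the final mean by well under half a point."""
        coarse = [
            simulate(covid, SimulationConfig(timestep_hours=2.0, seed=s)).final_p_na
            for s in range(8)
        ]
        fine = [
            simulate(covid, SimulationConfig(timestep_hours=1.0, seed=s)).final_p_na
            for s in range(8)
        ]
        assert abs(np.mean(coarse) - np.mean(fine)) < 0.015


class TestAgreementWithAnalyticEngine:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_constant_rate_trees(self, seed):
        """Monte Carlo and closed form agree within 3 binomial SE."""
        rng = np.random.default_rng(100 + seed)
        tree = make_random_tree(rng, max_leaves=6, rate_range=(5e-3, 5e-2))
        expected = analytic_top_probability(tree, 10)
        n = 1000
        res = simulate(tree, SimulationConfig(patients=n, days=10, seed=seed))
        se = np.sqrt(max(expected * (1 - expected), 1e-9) / n)
        assert res.final_p_na == pytest.approx(expected, abs=3 * se)


class TestSummary:
    def test_bernoulli_summary_arithmetic(self, covid):
        res = simulate(covid, SimulationConfig(seed=9))
        s = summarize_uncertainty(res)
        p = res.final_p_na
        assert s["mean"] == p
        assert s["sd"] == pytest.approx(np.sqrt(p * (1 - p)))
        half = 1.645 * np.sqrt(p * (1 - p) / res.patients)
        assert s["ci5"] == pytest.approx(p - half)
        assert s["ci95"] == pytest.approx(p + half)

    def test_degenerate_p_zero(self):
        res = simulate(single_leaf_tree(0.0), SimulationConfig(patients=50, seed=0))
        s = summarize_uncertainty(res)
        assert s == {"mean": 0.0, "sd": 0.0, "ci5": 0.0, "ci95": 0.0}

    def test_printed_summary_values(self):
        """At p=0.22, n=1000 the Bernoulli sd is ~0.41 and the 90% band ~[0.20, 0.24];
        at p=0.187 the sd is ~0.39."""
        assert np.sqrt(0.22 * 0.78) == pytest.approx(0.414, abs=5e-3)
        assert np.sqrt(0.187 * 0.813) == pytest.approx(0.39, abs=5e-3)
        half = 1.645 * np.sqrt(0.22 * 0.78 / 1000)
        assert 0.22 - half == pytest.approx(0.198, abs=2e-3)
        assert 0.22 + half == pytest.approx(0.242, abs=2e-3)


class TestAttribution:
    def test_single_leaf_gets_everything(self):
        res = simulate(single_leaf_tree(0.05), SimulationConfig(patients=500, seed=1))
        c = contributions(res)
        assert c["factors"] == {"X": 100.0}

    def test_two_equal_rates_split_evenly(self):
        tree = NonAdherenceTree(
            nodes={
                "T": NafNode(id="T", kind="top", gate=GateKind.OR,
                             children=("A", "B")),
                "A": NafNode(id="A", rate_model=ConstantRate(0.02)),
                "B": NafNode(id="B", rate_model=ConstantRate(0.02)),
            },
            top_id="T",
        )
        res = simulate(tree, SimulationConfig(patients=4000, days=10, seed=8))
        c = contributions(res)["factors"]
        events = sum(res.attributed.values())
        se_pct = 100 * np.sqrt(0.25 / events)
        assert c["A"] == pytest.approx(50.0, abs=3 * se_pct)

    def test_shares_sum_to_100(self, covid):
        res = simulate(covid, SimulationConfig(seed=4))
        c = contributions(res)
        assert sum(c["factors"].values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(c["dimensions"].values()) == pytest.approx(100.0, abs=1e-9)

    def test_dimension_rollup_sums_descendants(self, covid):
        res = simulate(covid, SimulationConfig(seed=4))
        c = contributions(res)
        patrel = sum(c["factors"].get(f, 0.0) for f in ("NoMed", "Forgot", "Other"))
        assert c["dimensions"]["PatRel"] == pytest.approx(patrel)


class TestImprovement:
    REDUCE = {"SidEff": 0.2, "Forgot": 0.2, "NoSym": 0.2, "Other": 0.2}

    def test_returns_new_tree_with_scaled_rates(self, covid):
        improved = apply_improvement(covid, self.REDUCE)
        assert improved is not covid
        for factor in self.REDUCE:
            assert improved.node(factor).rate_model.rate == pytest.approx(
                covid.node(factor).rate_model.rate * 0.8
            )
        # untouched leaves keep their models
        assert improved.node("HeaAcc").rate_model == covid.node("HeaAcc").rate_model

    def test_zero_reduction_is_noop_under_same_seed(self, covid):
        same = apply_improvement(covid, {"SidEff": 0.0})
        config = SimulationConfig(patients=400, seed=12)
        assert simulate(same, config) == simulate(covid, config)

    def test_unknown_factor_rejected(self, covid):
        with pytest.raises(KeyError):
            apply_improvement(covid, {"Nope": 0.5})
        with pytest.raises(KeyError):
            apply_improvement(covid, {"PatRel": 0.5})  # not basic

    def test_full_reduction_leaves_only_supply_pathway(self, covid):
        all_off = apply_improvement(
            covid,
            {leaf.id: 1.0 for leaf in covid.iter_basic()
             if leaf.id not in ("IctSys", "ManSys")},
        )
        res = simulate(all_off, SimulationConfig(patients=1000, seed=2))
        # joint downtime of the two supply systems is ~1e-10 per dosing step,
        # so essentially nobody discontinues; any event must be supply-attributed
        assert res.non_adherent <= 1
        assert set(res.attributed) <= {"IctSys", "ManSys"}

    def test_paired_reduction_never_increases_p_na(self, covid):
        improved = apply_improvement(covid, self.REDUCE)
        for seed in range(5):
            base = simulate(covid, SimulationConfig(seed=seed))
            treat = simulate(improved, SimulationConfig(seed=seed))
            se = np.sqrt(0.22 * 0.78 / base.patients)
            assert treat.final_p_na <= base.final_p_na + 3 * se


class TestReplicates:
    def test_replicates_are_independent_and_reproducible(self, covid):
        config = SimulationConfig(patients=300, days=5, seed=7, replicates=3)
        runs_a = simulate_replicates(covid, config)
        runs_b = simulate_replicates(covid, config)
        assert runs_a == runs_b
        assert len({r.seed for r in runs_a}) == 3
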