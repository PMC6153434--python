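"""Kill-probability laws, oxygen-dependent metabolism and survival
accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hapabm as H
from hapabm.core import CellPopulation, KillModel, MetabolismSpec
from hapabm.pkpd import (combine_kills, hazard_increment, kill_probability,
                         metabolism_rate, oxygen_dependent_kmet,
                         surviving_fraction)


class TestOxygenDependentKmet:
    def test_anoxic_limit_equals_kmet0(self):
        spec = MetabolismSpec(K_met0=14 / 60, K_O2=0.126)
        assert oxygen_dependent_kmet(spec, 0.0) == pytest.approx(14 / 60)

    def test_half_inhibition_at_K_O2(self):
        spec = MetabolismSpec(K_met0=1.0, K_O2=0.126)
        assert oxygen_dependent_kmet(spec, 0.126) == pytest.approx(0.5)

    def test_value_at_bolus_oxygen(self):
        # K_met0 = 14 min^-1, K_O2 = 0.126 uM, O2 = 2.5 uM
        # -> 14 * 0.126 / 2.626 = 0.672 min^-1
        spec = MetabolismSpec(K_met0=14.0, K_O2=0.126)  # per min here
        assert oxygen_dependent_kmet(spec, 2.5) == pytest.approx(0.672, abs=5e-4)

    @given(st.floats(min_value=0, max_value=300))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_oxygen(self, o2):
        spec = MetabolismSpec(K_met0=1.0, K_O2=1.2)
        assert oxygen_dependent_kmet(spec, o2) <= 1.0
        assert oxygen_dependent_kmet(spec, o2 + 1.0) < \
            oxygen_dependent_kmet(spec, o2)

    def test_negative_oxygen_rejected(self):
        with pytest.raises(ValueError):
            oxygen_dependent_kmet(MetabolismSpec(1.0, 1.0), -1.0)


class TestMetabolismRate:
    def test_zero_concentration_gives_zero(self):
        assert metabolism_rate(1.3 / 60, 0.0) == 0.0

    def test_arithmetic(self):
        # C = 20 uM, K_met = 1.3 min^-1 -> 26 uM/min
        assert metabolism_rate(1.3, 20.0) == pytest.approx(26.0)


class TestKillLaws:
    def test_concentration_mode_closed_form(self):
        # K_c = 0.092 mM^-1 s^-1 = 9.2e-5 uM^-1 s^-1, C = 10 uM, 1 h:
        # survival = exp(-9.2e-5 * 10 * 3600) = exp(-3.312) ~= 0.0364
        km = KillModel("concentration", 9.2e-5, "M1")
        h = hazard_increment(km, 10.0, 3600.0)
        assert np.exp(-h) == pytest.approx(np.exp(-3.312), rel=1e-9)
        assert np.exp(-h) == pytest.approx(0.0364, abs=1e-4)

    def test_metabolism_mode_closed_form(self):
        # K_c = 1 mM^-1, K_met = 1.3 min^-1, C = 20 uM, 60 min:
        # survival = exp(-1e-3 * (1.3/60) * 20 * 3600) = 0.2101
        km = KillModel("metabolism_rate", 1e-3, "P")
        mrate = metabolism_rate(1.3 / 60, 20.0)
        h = hazard_increment(km, mrate, 3600.0)
        assert np.exp(-h) == pytest.approx(0.2101, rel=1e-3)

    def test_hazard_additivity_under_subdivision(self):
        km = KillModel("concentration", 9.2e-5, "M1")
        whole = hazard_increment(km, 10.0, 3600.0)
        parts = sum(hazard_increment(km, 10.0, 3600.0 / 96)
                    for _ in range(96))
        assert parts == pytest.approx(whole, rel=1e-9)

    def test_kill_probability_in_unit_interval(self):
        km = KillModel("concentration", 9.2e-5, "M1")
        p = kill_probability(km, 1.0, 3600.0)
        assert 0.0 < p < 1.0
        assert kill_probability(km, 0.0, 3600.0) == 0.0


class TestCombineKills:
    @pytest.mark.parametrize("p1,p2,expected", [
        (0.0, 0.7, 0.7),
        (0.5, 0.5, 0.75),
        (0.9, 0.99, 0.999),
    ])
    def test_independent_action_values(self, p1, p2, expected):
        assert combine_kills(p1, p2) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_commutative_and_bounded(self, p1, p2):
        c = combine_kills(p1, p2)
        assert c == pytest.approx(combine_kills(p2, p1), rel=1e-12)
        assert max(p1, p2) - 1e-12 <= c <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_kills(-0.1, 0.5)
        with pytest.raises(ValueError):
            combine_kills(0.5, 1.5)


class TestSurvivingFraction:
    def _population(self, log_survivals, toy_lines):
        cells = CellPopulation(list(toy_lines))
        n = len(log_survivals)
        cells.add_cells(np.arange(n), np.zeros(n, dtype=int),
                        np.full(n, 2500.0))
        cells.log_survival[:] = log_survivals
        return cells

    def test_no_drug_gives_unity(self, toy_lines):
        cells = self._population([0.0, 0.0, 0.0], toy_lines)
        assert surviving_fraction(cells) == 1.0

    def test_mean_of_survival_probabilities(self, toy_lines):
        cells = self._population([0.0, -np.inf], toy_lines)
        assert surviving_fraction(cells) == pytest.approx(0.5)

    def test_bernoulli_mode_matches_expectation(self, toy_lines):
        rng = np.random.default_rng(42)
        logs = np.log(np.full(1000, 0.3))
        cells = self._population(logs, toy_lines)
        expect = surviving_fraction(cells)
        draws = [surviving_fraction(cells, mode="bernoulli", rng=rng)
                 for _ in range(50)]
        se = np.sqrt(0.3 * 0.7 / 1000)
        assert np.mean(draws) == pytest.approx(expect, abs=3 * se)

    def test_empty_filter_rejected(self, toy_lines):
        cells = self._population([0.0], toy_lines)
        with pytest.raises(ValueError, match="no viable cells"):
            surviving_fraction(cells, lineage="TGT")


class TestProdrugModels:
    def test_sn30000_is_no_bystander(self, reg):
        m = H.build_model("sn30000", reg)
        assert len(m.kill_models) == 1
        assert m.kill_models[0].mode == "metabolism_rate"

    def test_pr104a_dichloro_has_two_concentration_kills(self, reg):
        m = H.build_model("pr104a-dichloro", reg)
        modes = {k.mode for k in m.kill_models}
        assert modes == {"concentration"}
        assert {k.acts_on for k in m.kill_models} == {"PR104_M1", "PR104_M2"}

    def test_chain_is_acyclic_and_short(self, reg):
        for name in ("sn30000", "pr104a-hm", "pr104a-dichloro"):
            m = H.build_model(name, reg)
            seen = []
            s = m.solutes[0]
            by_name = {x.name: x for x in m.solutes}
            while s is not None and s.name not in seen:
                seen.append(s.name)
                s = by_name.get(s.child) if s.child else None
            assert len(seen) <= 3

    def test_activator_metabolises_faster_than_target(self, reg):
        for name in ("sn30000", "pr104a-dichloro"):
            m = H.build_model(name, reg)
            assert m.metabolism["POR-R"].K_met0 > m.metabolism["PORko-G"].K_met0

    def test_zero_kc_counterfactual(self, reg):
        m = H.build_model("pr104a-dichloro", reg)
        m0 = m.zero_kc("PR104_M2")
        kcs = {k.acts_on: k.K_c for k in m0.kill_models}
        assert kcs["PR104_M2"] == 0.0
        assert kcs["PR104_M1"] > 0.0

    def test_unknown_model_name_rejected(self, reg):
        with pytest.raises(ValueError, match="unknown model"):
            H.build_model("nonexistent", reg)
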