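"""Rate laws, conservation, initialization and plateau behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tauphos as tp
from tauphos.model import initialize, rhs, simulate, stoichiometry

from conftest import make_random_mechanism_model, make_sequential_pair_model


def single_site_model(k=1.0, alpha=0.5, kinase_conc=0.1, km=1.0, tau=2.0):
    sites = [tp.SiteSpec(name="S1", alpha={("GSK3B", 0): alpha},
                         kcat={("GSK3B", 0): k})]
    enzymes = {"GSK3B": tp.EnzymeSpec("GSK3B", kinase_conc, km, "kinase")}
    return tp.PhosphoModel(sites=sites, enzymes=enzymes, tau_total=tau)


class TestPhosphorylationRate:
    def test_zero_substrate_gives_zero_rate(self):
        m = single_site_model()
        state = tp.MacroState(r_closed=np.array([2.0]), r_open=np.array([0.0]),
                              p=np.array([0.0]))
        rate = tp.phosphorylation_rate(m.site("S1"), state,
                                       m.enzymes["GSK3B"], m)
        assert rate == 0.0

    def test_single_open_site_michaelis_menten_value(self):
        # k=1/min, [kinase]=0.1 μM, R=1 μM, K_M=1 μM → 0.1·1/(1+1) = 0.05
        m = single_site_model(k=1.0, kinase_conc=0.1, km=1.0)
        state = tp.MacroState(r_closed=np.array([1.0]), r_open=np.array([1.0]),
                              p=np.array([0.0]))
        rate = tp.phosphorylation_rate(m.site("S1"), state,
                                       m.enzymes["GSK3B"], m)
        assert rate == pytest.approx(0.05, rel=1e-12)

    def test_substrate_competition_reduces_per_site_rate(self):
        sites = [tp.SiteSpec(name=n, alpha={("GSK3B", 0): 0.5},
                             kcat={("GSK3B", 0): 1.0}) for n in ("A", "B")]
        enzymes = {"GSK3B": tp.EnzymeSpec("GSK3B", 0.1, 1.0, "kinase")}
        m2 = tp.PhosphoModel(sites=sites, enzymes=enzymes, tau_total=2.0)
        state2 = tp.MacroState(r_closed=np.zeros(2), r_open=np.array([1.0, 1.0]),
                               p=np.zeros(2))
        rate_with = tp.phosphorylation_rate(m2.site("A"), state2,
                                            m2.enzymes["GSK3B"], m2)
        m1 = single_site_model(k=1.0, kinase_conc=0.1)
        state1 = tp.MacroState(r_closed=np.zeros(1), r_open=np.array([1.0]),
                               p=np.zeros(1))
        rate_alone = tp.phosphorylation_rate(m1.site("S1"), state1,
                                             m1.enzymes["GSK3B"], m1)
        assert rate_with < rate_alone
        # shared denominator: 0.1·1/(1+2) vs 0.1·1/(1+1)
        assert rate_with == pytest.approx(0.1 / 3.0, rel=1e-12)

    def test_negative_state_rejected(self):
        m = single_site_model()
        state = tp.MacroState(r_closed=np.array([2.0]),
                              r_open=np.array([-0.1]), p=np.array([0.0]))
        with pytest.raises(ValueError):
            tp.phosphorylation_rate(m.site("S1"), state, m.enzymes["GSK3B"], m)

    def test_unknown_site_rejected(self):
        m = single_site_model()
        rogue = tp.SiteSpec(name="S999", alpha={}, kcat={("GSK3B", 0): 1.0})
        state = tp.MacroState(r_closed=np.array([1.0]), r_open=np.array([1.0]),
                              p=np.array([0.0]))
        with pytest.raises(KeyError):
            tp.phosphorylation_rate(rogue, state, m.enzymes["GSK3B"], m)


class TestSequentialSubstrate:
    def test_unprimed_limit_is_zero(self):
        m = make_sequential_pair_model()
        state = tp.MacroState(r_closed=np.array([1.0, 1.4]),
                              r_open=np.array([1.0, 0.6]),
                              p=np.array([0.0, 0.0]))
        assert tp.sequential_substrate(m.site("S396"), state, m) == 0.0

    def test_fully_primed_limit_equals_open_pool(self):
        m = make_sequential_pair_model()
        state = tp.MacroState(r_closed=np.array([0.0, 1.4]),
                              r_open=np.array([0.0, 0.6]),
                              p=np.array([2.0, 0.0]))  # P_404 = S_total
        assert tp.sequential_substrate(m.site("S396"), state, m) \
            == pytest.approx(0.6)

    def test_product_formula_value(self):
        # S(a396=0)=2, P_404=5, S_total=10 → 2·5/10 = 1
        sites = [tp.SiteSpec(name="S404", alpha={}, kcat={("GSK3B", 0): 1.0}),
                 tp.SiteSpec(name="S396", alpha={}, kcat={("GSK3B", 0): 1.0},
                             prerequisite={"GSK3B": "S404"})]
        m = tp.PhosphoModel(sites=sites,
                            enzymes={"GSK3B": tp.EnzymeSpec("GSK3B", 0.1, 1.0,
                                                            "kinase")},
                            tau_total=10.0)
        state = tp.MacroState(r_closed=np.array([0.0, 8.0]),
                              r_open=np.array([5.0, 2.0]),
                              p=np.array([5.0, 0.0]))
        assert tp.sequential_substrate(m.site("S396"), state, m) \
            == pytest.approx(1.0)


class TestDephosphorylationRate:
    def test_zero_phospho_gives_zero(self):
        m = make_random_mechanism_model()
        state = initialize(m)
        rate = tp.dephosphorylation_rate(m.sites[0], state, m.enzymes["PP2A"], m)
        assert rate == 0.0

    def test_half_saturation_value(self):
        # k=0.2, [PP2A]=1 μM, P=K_M=11.6 μM → 0.2·11.6/23.2 = 0.1
        sites = [tp.SiteSpec(name="S1", alpha={}, kcat={}, kcat_pp2a=0.2)]
        m = tp.PhosphoModel(sites=sites,
                            enzymes={"PP2A": tp.EnzymeSpec("PP2A", 1.0, 11.6,
                                                           "phosphatase")},
                            tau_total=20.0)
        state = tp.MacroState(r_closed=np.array([8.4]), r_open=np.array([0.0]),
                              p=np.array([11.6]))
        rate = tp.dephosphorylation_rate(m.site("S1"), state,
                                         m.enzymes["PP2A"], m)
        assert rate == pytest.approx(0.1, rel=1e-12)

    def test_linear_in_enzyme_level(self):
        m = make_random_mechanism_model(seed=4)
        state = tp.MacroState(r_closed=np.full(3, 0.5), r_open=np.full(3, 0.5),
                              p=np.full(3, 1.0))
        r1 = tp.dephosphorylation_rate(m.sites[1], state, m.enzymes["PP2A"], m)
        m.enzymes["PP2A"].concentration *= 2
        r2 = tp.dephosphorylation_rate(m.sites[1], state, m.enzymes["PP2A"], m)
        assert r2 == pytest.approx(2 * r1)


class TestRhs:
    def test_frozen_system_has_zero_derivative(self):
        m = make_random_mechanism_model(seed=1)
        for e in m.enzymes.values():
            e.concentration = 0.0
        state = initialize(m)
        d = rhs(state, m, ("GSK3B", "PP2A"))
        assert np.allclose(d.r_closed, 0) and np.allclose(d.r_open, 0) \
            and np.allclose(d.p, 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           ro=st.floats(0.01, 1.0), pp=st.floats(0.0, 1.0))
    def test_per_site_derivatives_sum_to_zero(self, seed, ro, pp):
        m = make_random_mechanism_model(seed=seed)
        n = m.n_sites
        state = tp.MacroState(r_closed=np.full(n, max(2.0 - ro - pp, 0.0)),
                              r_open=np.full(n, ro), p=np.full(n, pp))
        d = rhs(state, m, ("GSK3B", "PP2A"))
        assert np.allclose(d.r_closed + d.r_open + d.p, 0, atol=1e-14)

    def test_sequential_site_frozen_without_priming(self):
        m = make_sequential_pair_model()
        state = initialize(m)  # P_404 = 0
        d = rhs(state, m, ("GSK3B",))
        assert d.p[m.site_index("S396")] == 0.0
        assert d.p[m.site_index("S404")] > 0.0


class TestInitialize:
    def test_fully_open_leaves_no_closed_pool(self):
        m = single_site_model(alpha=1.0)
        s = initialize(m)
        assert s.r_closed[0] == 0.0 and s.r_open[0] == m.tau_total

    def test_partial_openness_split(self):
        m = single_site_model(alpha=0.3, tau=1.0)
        s = initialize(m)
        assert s.r_open[0] == pytest.approx(0.3)
        assert s.r_closed[0] == pytest.approx(0.7)
        assert s.p[0] == 0.0

    def test_pka_switch_changes_alpha_selection(self):
        m = tp.tau_model()
        s0 = initialize(m.with_condition("GSK3B", 0))
        s1 = initialize(m.with_condition("GSK3B", 1))
        i = m.site_index("S404")
        assert s1.r_open[i] > s0.r_open[i]
        assert np.all(s0.p == 0) and np.all(s1.p == 0)


class TestSimulate:
    def test_mass_conservation_along_trajectory(self, packaged_model):
        traj = simulate(packaged_model, np.linspace(0, 240, 25))
        totals = traj.r_closed + traj.r_open + traj.p
        assert np.allclose(totals, packaged_model.tau_total, rtol=1e-8)

    def test_nonnegative_and_monotone_without_phosphatase(self, compact_model):
        traj = simulate(compact_model, np.linspace(0, 240, 49))
        assert np.all(traj.p >= 0) and np.all(traj.r_open >= -1e-12)
        assert np.all(np.diff(traj.p, axis=0) >= -1e-9)
        # bounded by the openness cap α_i·tau
        alpha = np.array([s.get_alpha("GSK3B", 0) for s in compact_model.sites])
        assert np.all(traj.p <= alpha * compact_model.tau_total + 1e-8)

    def test_full_opening_drives_complete_phosphorylation(self):
        # long-term regime: all α=1 and no phosphatase → P_i → tau
        m = make_random_mechanism_model(seed=2, with_pp2a=False)
        for s in m.sites:
            s.alpha[("GSK3B", 0)] = 1.0
        traj = simulate(m, [0.0, 5e4, 2e5])
        assert np.allclose(traj.p[-1], m.tau_total, rtol=1e-3)

    def test_monotone_in_kinase_level_and_kcat(self):
        base = make_random_mechanism_model(seed=3, with_pp2a=False)
        t = [0.0, 30.0]
        p_by_conc = []
        for conc in (0.1, 0.3, 0.9):
            m = base.copy()
            m.enzymes["GSK3B"].concentration = conc
            p_by_conc.append(simulate(m, t).p[-1, 0])
        assert p_by_conc[0] < p_by_conc[1] < p_by_conc[2]
        p_by_k = []
        for k in (0.2, 0.6, 1.8):
            m = base.copy()
            m.sites[0].kcat[("GSK3B", 0)] = k
            p_by_k.append(simulate(m, t).p[-1, 0])
        assert p_by_k[0] < p_by_k[1] < p_by_k[2]

    def test_bad_grid_rejected(self, compact_model):
        with pytest.raises(ValueError):
            simulate(compact_model, [10.0, 5.0])


class TestStoichiometry:
    def test_zero_without_phosphorylation(self, compact_model):
        assert stoichiometry(initialize(compact_model), compact_model) == 0.0

    def test_plateau_equals_sum_alpha(self):
        # plateau with α = (0.5, 0.25) → N = 0.75
        sites = [tp.SiteSpec(name="A", alpha={("GSK3B", 0): 0.5},
                             kcat={("GSK3B", 0): 1.0}),
                 tp.SiteSpec(name="B", alpha={("GSK3B", 0): 0.25},
                             kcat={("GSK3B", 0): 0.7})]
        m = tp.PhosphoModel(sites=sites,
                            enzymes={"GSK3B": tp.EnzymeSpec("GSK3B", 0.5, 1.0,
                                                            "kinase")},
                            tau_total=2.0)
        traj = simulate(m, [0.0, 1e4, 1e5])
        assert stoichiometry(traj.state_at(-1), m) == pytest.approx(0.75, rel=1e-4)
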