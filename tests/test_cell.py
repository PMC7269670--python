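"""Cell assembly, passive cable physics, and the phenotype-switch contract."""

import numpy as np
import pytest

import isasim.channels as ch
from isasim.cell import (
    CellConfig,
    MorphologyStandIn,
    PassiveParams,
    build_cell,
    template_morphology,
    total_conductance_ratio,
)
from isasim.engine import CurrentClampStim, holding_current_for, simulate


class TestMorphology:
    def test_discretisation_limit_enforced(self):
        with pytest.raises(ValueError, match="discretisation"):
            MorphologyStandIn(soma=(20, 20), dendrites=((300.0, 3.0, 5),))

    def test_dimensions_must_be_positive(self):
        with pytest.raises(ValueError):
            MorphologyStandIn(soma=(0.0, 20.0))
        with pytest.raises(ValueError):
            MorphologyStandIn(soma=(20, 20), dendrites=((100.0, -1.0, 10),))

    def test_areas_add_up(self):
        m = template_morphology()
        assert m.total_area_um2 == pytest.approx(m.soma_area_um2 + m.dendrite_area_um2)
        assert m.n_compartments == 1 + sum(n for _, _, n in m.dendrites)


class TestBuildCell:
    def test_published_densities(self, rs_cell, tor_cell):
        assert rs_cell.soma_channels["isa_rs"] == pytest.approx(297e-5)
        assert tor_cell.soma_channels["isa_rs"] == pytest.approx(128e-5)
        assert tor_cell.soma_channels["isa_tor"] == pytest.approx(44e-5)
        # total somatic I_SA: 1.72 vs 2.97 mS/cm2
        tor_total = tor_cell.soma_channels["isa_rs"] + tor_cell.soma_channels["isa_tor"]
        assert tor_total == pytest.approx(1.72e-3)

    def test_phenotype_switch_is_isa_pure(self):
        for seed in (None, 11):
            rs = build_cell("RS", seed=seed)
            tor = build_cell("TOR", seed=seed)
            assert rs.passive == tor.passive
            assert rs.e_leak_soma == tor.e_leak_soma
            assert rs.e_leak_dend == tor.e_leak_dend
            for table in ("soma_channels", "dend_channels"):
                a, b = getattr(rs, table), getattr(tor, table)
                non_isa_a = {k: v for k, v in a.items() if not k.startswith("isa")}
                non_isa_b = {k: v for k, v in b.items() if not k.startswith("isa")}
                assert non_isa_a == non_isa_b

    def test_seeded_jitter_reproducible_and_bounded(self):
        a = build_cell("TOR", seed=5)
        b = build_cell("TOR", seed=5)
        assert a.soma_channels == b.soma_channels
        c = build_cell("TOR", seed=6)
        assert a.soma_channels != c.soma_channels

    def test_resting_potential_in_measured_range(self, rs_cell, tor_cell):
        for cell in (rs_cell, tor_cell):
            assert cell.resting_potential == pytest.approx(-64.7, abs=2.0)

    def test_invalid_phenotype(self):
        with pytest.raises(ValueError):
            build_cell("bursting")


class TestConductanceRatio:
    def test_mean_density_ratio_is_0579(self, rs_cell, tor_cell):
        assert total_conductance_ratio(tor_cell, rs_cell) == pytest.approx(0.579, abs=0.005)

    def test_identity_and_zero(self, rs_cell, tor_cell):
        assert total_conductance_ratio(rs_cell, rs_cell) == pytest.approx(1.0)
        empty = tor_cell.with_channels(
            soma={k: (0.0 if k.startswith("isa") else v) for k, v in tor_cell.soma_channels.items()},
            dend={k: (0.0 if k.startswith("isa") else v) for k, v in tor_cell.dend_channels.items()},
        )
        assert total_conductance_ratio(empty, rs_cell) == 0.0

    def test_mismatched_morphologies_rejected(self, rs_cell):
        other = build_cell("TOR", morphology=template_morphology(length_um=360.0))
        with pytest.raises(ValueError):
            total_conductance_ratio(other, rs_cell)


def _passive_single_compartment():
    m = MorphologyStandIn(soma=(20.0, 20.0))
    pp = PassiveParams()
    return CellConfig(
        morphology=m, passive=pp,
        soma_channels={"leak": pp.g_leak}, dend_channels={"leak": pp.g_leak},
        phenotype="RS", e_leak_soma=-65.0, e_leak_dend=-65.0, resting_potential=-65.0,
    )


class TestIntegration:
    def test_settles_to_configured_rest(self, rs_cell, tor_cell):
        for cell in (rs_cell, tor_cell):
            ts = simulate(cell, None, duration=2000.0, record_dt=1.0)
            assert ts["v_soma"].y[-1] == pytest.approx(cell.resting_potential, abs=0.5)

    def test_passive_rc_step_matches_analytic(self):
        """Closed-form RC charging oracle for the single-compartment cable."""
        cell = _passive_single_compartment()
        ts = simulate(cell, CurrentClampStim(epochs=[(50.0, 250.0, 0.02)]),
                      duration=300.0, record_dt=0.05)
        t, v = ts["v_soma"].t, ts["v_soma"].y
        area = cell.morphology.soma_area_um2 * 1e-8
        g = cell.passive.g_leak * area * 1e6  # uS
        tau = cell.passive.cm * area * 1e3 / g  # ms
        dv = 0.02 / g
        m = (t >= 50.0) & (t < 250.0)
        pred = -65.0 + dv * (1 - np.exp(-(t[m] - 50.0) / tau))
        assert np.max(np.abs(v[m] - pred)) / dv < 0.005

    def test_charge_conservation_passive(self):
        """Injected charge = capacitive + leak charge (0.5%)."""
        cell = build_cell("RS").with_channels(
            soma={"leak": 5.4e-5}, dend={"leak": 5.4e-5})
        amp, t0, t1 = 0.05, 20.0, 820.0
        ts = simulate(cell, CurrentClampStim(epochs=[(t0, t1, amp)]),
                      duration=900.0, record_dt=0.05, v_init=cell.e_leak_soma)
        t = ts["i_leak"].t
        m = (t >= t0) & (t < t1)
        q_in = amp * (t1 - t0)  # nA*ms = pC
        q_leak = np.trapezoid(ts["i_leak"].y[m], t[m])
        from isasim.engine import cell_arrays

        arr = cell_arrays(cell, 0.025)
        v_final = ts.meta["final_v"]
        # v at t1 approximately equals final stored state only if duration==t1;
        # use the recorded somatic value and the analytic uniformity of the
        # passive cell instead: all compartments share the soma trajectory.
        dv = ts["v_soma"].y[np.searchsorted(t, t1) - 1] - cell.e_leak_soma
        q_cap = float(np.sum(arr["cap"])) * dv * 1e0  # nF*mV = pC
        assert q_cap + q_leak == pytest.approx(q_in, rel=0.005)

    def test_dt_halving_convergence(self, tor_cell):
        """Subthreshold response changes by < 0.1 mV RMS when dt is halved."""
        ih = holding_current_for(tor_cell, -80.0)
        stim = CurrentClampStim(epochs=[(0.0, 500.0, ih), (500.0, 900.0, 0.1)])
        runs = {}
        for dt in (0.025, 0.0125):
            ts = simulate(tor_cell, stim, duration=900.0, dt=dt, v_init=-80.0,
                          record_dt=0.1)
            runs[dt] = ts["v_soma"].y
        rms = np.sqrt(np.mean((runs[0.025] - runs[0.0125]) ** 2))
        assert rms < 0.1

    def test_divergence_aborts_with_diagnostic(self):
        cell = _passive_single_compartment()
        with pytest.raises(RuntimeError, match="divergence"):
            simulate(cell, CurrentClampStim(epochs=[(0.0, 100.0, 1e4)]), duration=100.0)

    def test_dt_precondition(self, rs_cell):
        with pytest.raises(ValueError):
            simulate(rs_cell, None, duration=10.0, dt=0.05)


class TestGatingRelaxationOracle:
    def test_isa_gates_follow_closed_form_exponentials(self):
        """Voltage-step gating must match m(t) = m_inf + (m0−m_inf)e^(−t/tau).

        A single small compartment under near-ideal clamp is stepped from −80
        to −40 mV; the recorded I_SA current is compared against the analytic
        density * m(t) * h(t) * (V − E_K) product to 0.1%.
        """
        from isasim.cell import nucleated_patch_cell
        from isasim.engine import VoltageClampStim

        cell = nucleated_patch_cell("tor")
        stim = VoltageClampStim(epochs=((-80.0, 200.0), (-40.0, 200.0)),
                                rs_mohm=0.001)
        ts = simulate(cell, stim, duration=400.0, record_dt=0.05)
        t = ts["i_sa"].t
        m = (t >= 201.0) & (t < 390.0)
        # the staggered scheme lets gates see a command change one step late
        tt = t[m] - 200.0 - 0.025
        gp = ch.ISA_PROFILES[("tor", "nucleated")]
        m0, h0 = gp.m_inf(-80.0), gp.h_inf(-80.0)
        m_inf, h_inf = gp.m_inf(-40.0), gp.h_inf(-40.0)
        tau_h = gp.tau_h_fn()(-40.0)
        m_t = m_inf + (m0 - m_inf) * np.exp(-tt / gp.tau_act)
        h_t = h_inf + (h0 - h_inf) * np.exp(-tt / tau_h)
        dens = cell.soma_channels["isa_tor"]
        area = cell.morphology.total_area_um2 * 1e-8
        pred_nA = dens * area * 1e6 * m_t * h_t * (-40.0 - ch.E_K)  # uS * mV = nA
        rel = np.abs(ts["i_sa"].y[m] - pred_nA) / np.max(pred_nA)
        assert np.max(rel) < 0.001


class TestSwcReader:
    def test_swc_maps_to_stand_in(self, tmp_path):
        swc = """# synthetic three-branch reconstruction
1 1 0 0 0 8.0 -1
2 3 10 0 0 1.5 1
3 3 110 0 0 1.5 2
4 3 210 0 0 1.0 3
5 3 0 10 0 2.0 1
6 3 0 160 0 2.0 5
7 2 0 0 10 0.5 1
8 2 0 0 110 0.5 7
"""
        p = tmp_path / "cell.swc"
        p.write_text(swc)
        from isasim.cell import morphology_from_swc

        m = morphology_from_swc(p)
        assert len(m.dendrites) == 2  # the axon (type 2) is ignored
        lengths = sorted(d[0] for d in m.dendrites)
        assert lengths[0] == pytest.approx(150.0)
        assert lengths[1] == pytest.approx(200.0)
        # soma cylinder preserves the spherical surface area
        import math

        assert math.pi * m.soma[0] * m.soma[1] == pytest.approx(4 * math.pi * 8.0**2)

    def test_swc_without_soma_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 3 0 0 0 1.0 -1\n")
        with pytest.raises(ValueError, match="soma"):
            from isasim.cell import morphology_from_swc

            morphology_from_swc(p)
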