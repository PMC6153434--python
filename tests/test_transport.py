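"""Transport solvers: analytic oracles, conservation, monolayer and MCL
models."""

import numpy as np
import pytest

import hapabm as H
from hapabm.core import CultureGeometry, SoluteSpec
from hapabm.transport import (FineGridTransport, SolverSettings,
                              membrane_exchange, michaelis_menten_O2_rate,
                              simulate_mcl, simulate_monolayer)


class TestMichaelisMenten:
    def test_zero_concentration(self):
        assert michaelis_menten_O2_rate(0.0, 6e-17, 1.3) == 0.0

    def test_half_saturation(self):
        assert michaelis_menten_O2_rate(1.3, 6e-17, 1.3) == \
            pytest.approx(3e-17)

    def test_direct_evaluation(self):
        # C = 4, K_m = 1.3, V_max = 6e-17 -> 6e-17 * 4/5.3 = 4.528e-17
        assert michaelis_menten_O2_rate(4.0, 6e-17, 1.3) == \
            pytest.approx(4.528e-17, rel=1e-3)

    def test_monotone_increasing(self):
        c = np.linspace(0, 50, 100)
        r = michaelis_menten_O2_rate(c, 6e-17, 1.3)
        assert np.all(np.diff(r) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            michaelis_menten_O2_rate(-1.0, 6e-17, 1.3)


class TestMembraneExchange:
    def test_equilibrium(self):
        dci, dce = membrane_exchange(5.0, 5.0, 0.1, 0.1, 1.0)
        assert dci == 0.0 and dce == 0.0

    def test_uptake_rate(self):
        dci, dce = membrane_exchange(10.0, 0.0, 0.1, 0.1, 1.0)
        assert dci == pytest.approx(1.0)
        assert dce == pytest.approx(-1.0)

    def test_lipophilic_partitioning_steady_state(self):
        # K_in/K_out = 2 -> steady state C_i/C_e = 2
        K_in, K_out = 0.02, 0.01
        C_e = 4.0
        C_i_ss = K_in * C_e / K_out
        dci, _ = membrane_exchange(C_e, C_i_ss, K_in, K_out, 1.0)
        assert dci == pytest.approx(0.0, abs=1e-15)
        assert C_i_ss / C_e == pytest.approx(2.0)

    def test_moles_conserved_by_construction(self):
        dci, dce = membrane_exchange(3.0, 7.0, 0.05, 0.02, 2.5)
        assert dci * 1.0 + dce * 2.5 == pytest.approx(0.0, abs=1e-15)


def _uniform_solver(D=400.0, k_decay=0.0, radius=40.0, dt=5.0):
    grid = H.build_lattice(2500.0, radius)
    sol = SoluteSpec("X", D, D, k_decay_medium=k_decay)
    return grid, FineGridTransport(grid, None, None, solutes=(sol,),
                                   settings=SolverSettings(dt_max=dt))


class TestFineGrid:
    def test_uniform_field_unchanged_by_diffusion(self):
        grid, sv = _uniform_solver()
        sv.state.C_e["X"][:] = 7.5
        sv.run(600.0)
        assert np.allclose(sv.state.C_e["X"], 7.5, rtol=1e-9)

    def test_medium_decay_tracks_closed_form(self):
        k = 1e-4
        grid, sv = _uniform_solver(k_decay=k, dt=2.0)
        sv.state.C_e["X"][:] = 10.0
        a0 = sv.total_amount("X")
        sv.run(3600.0)
        expected = np.exp(-k * 3600.0)
        assert sv.total_amount("X") / a0 == pytest.approx(expected, rel=1e-4)

    def test_dt_above_dt_max_rejected(self):
        grid, sv = _uniform_solver()
        with pytest.raises(ValueError, match="dt_max"):
            sv.step(100.0)

    def test_spherical_consumption_profile_matches_closed_form(self):
        # steady state of D lap C = k C inside radius R, C = C_R at surface:
        # C(r)/C_R = (R/r) sinh(r/lambda) / sinh(R/lambda), lambda = sqrt(D/k)
        R, lam, D = 200.0, 100.0, 1000.0
        k = D / lam ** 2
        grid = H.build_lattice(2500.0, R + 17.1)
        dx = grid.dx
        r = grid.radii()
        f_in = np.clip((R - r) / dx + 0.5, 0.0, 1.0)
        sol = SoluteSpec("X", D, D)
        sv = FineGridTransport(grid, None, None, solutes=(sol,),
                               settings=SolverSettings(dt_max=2.0),
                               site_sink=k * f_in,
                               clamp=(r >= R + 0.5 * dx, 1.0))
        sv.state.C_e["X"][:] = 1.0
        sv.run(200.0)
        C = sv.state.C_e["X"]
        sel = np.abs(r - R) < 1.5 * dx
        C_R = np.polyval(np.polyfit(r[sel] - R, C[sel], 2), 0.0)
        ana = np.where(r > 1e-9,
                       (R / np.maximum(r, 1e-9))
                       * np.sinh(np.minimum(r, R) / lam) / np.sinh(R / lam),
                       R / lam / np.sinh(R / lam))
        interior = r <= R - 0.5 * dx
        rel = np.abs(C[interior] / C_R - ana[interior]) / ana[interior]
        assert rel.max() < 0.02
        centre = C[int(np.argmin(r))] / C_R
        assert centre == pytest.approx(0.5515, abs=0.01)

    def test_closed_system_chain_conserves_moles(self, small_populated_grid,
                                                 toy_chain_model):
        grid, cells = small_populated_grid
        sv = FineGridTransport(grid, cells, toy_chain_model, geometry=None)
        sv.set_uniform_medium("P", 100.0)
        total = lambda: sum(sv.total_amount(s) for s in ("P", "M1", "M2"))
        t0 = total()
        sv.run(1800.0)
        assert abs(total() - t0) / t0 < 1e-6

    def test_metabolite_stoichiometry(self, small_populated_grid,
                                      toy_chain_model):
        # moles(prodrug consumed) = moles(metabolites formed) cumulatively
        grid, cells = small_populated_grid
        sv = FineGridTransport(grid, cells, toy_chain_model, geometry=None)
        sv.set_uniform_medium("P", 50.0)
        p0 = sv.total_amount("P")
        sv.run(1800.0)
        consumed = p0 - sv.total_amount("P")
        formed = sv.total_amount("M1") + sv.total_amount("M2")
        assert formed == pytest.approx(consumed, rel=1e-6)

    def test_nonnegativity_of_all_fields(self, small_populated_grid,
                                         toy_chain_model):
        grid, cells = small_populated_grid
        sv = FineGridTransport(grid, cells, toy_chain_model, geometry=None)
        sv.set_uniform_medium("P", 100.0)
        sv.run(900.0)
        for n in ("P", "M1", "M2"):
            assert sv.state.C_e[n].min() >= 0.0
            assert sv.state.C_i[n].min() >= 0.0

    def test_octant_symmetry_of_centered_problem(self):
        grid, sv = _uniform_solver(radius=50.0)
        r = grid.radii()
        sv.state.C_e["X"][:] = np.where(r < 30.0, 0.0, 1.0)
        sv.run(60.0)
        f = sv.state.C_e["X"].reshape(grid.dims)
        for axis in range(3):
            assert np.allclose(f, np.flip(f, axis=axis), atol=1e-9)


class TestMediumColumnCoupling:
    def _geometry(self):
        return CultureGeometry(kind="spheroid", medium_volume=80e9,
                               well_area=0.328e8)

    def test_no_cells_uniform_stays_uniform(self):
        grid = H.build_lattice(2500.0, 40.0)
        sol = SoluteSpec("O2", 2000, 1700)
        sv = FineGridTransport(grid, None, None, geometry=self._geometry(),
                               solutes=(sol,))
        sv.set_uniform_medium("O2", 2.5, include_interstitium=True)
        sv.run(600.0, gas_O2=2.5)
        assert np.allclose(sv.state.C_e["O2"], 2.5, rtol=1e-6)
        assert np.allclose(sv.state.C_med["O2"], 2.5, rtol=1e-6)

    def test_zero_gas_absorbs_oxygen_monotonically(self):
        grid = H.build_lattice(2500.0, 40.0)
        sol = SoluteSpec("O2", 2000, 1700)
        sv = FineGridTransport(grid, None, None, geometry=self._geometry(),
                               solutes=(sol,))
        sv.set_uniform_medium("O2", 2.5, include_interstitium=True)
        totals = [sv.total_amount("O2")]
        for _ in range(20):
            sv.run(120.0, gas_O2=0.0)
            totals.append(sv.total_amount("O2"))
        diffs = np.diff(totals)
        assert np.all(diffs < 0)
        # the top of the column approaches the gas value
        assert sv.state.C_med["O2"][-1] < 1.0

    def test_closed_drug_conserved_through_column(self):
        grid = H.build_lattice(2500.0, 40.0)
        sol = SoluteSpec("X", 400, 100)
        sv = FineGridTransport(grid, None, None, geometry=self._geometry(),
                               solutes=(sol,))
        sv.set_uniform_medium("X", 30.0)
        a0 = sv.total_amount("X")
        sv.run(1800.0)
        assert sv.total_amount("X") == pytest.approx(a0, rel=1e-9)


class TestMonolayer:
    def test_well_mixed_limit_uniform_in_depth(self, reg):
        model = H.build_model("sn30000", reg)
        fast = []
        for s in model.solutes:
            from dataclasses import replace
            fast.append(replace(s, D_medium=4e5, D_tissue=4e5))
        from dataclasses import replace as drep
        model = drep(model, solutes=tuple(fast))
        geom = CultureGeometry(kind="monolayer", medium_volume=0.15e12,
                               well_area=0.32e8)
        res = simulate_monolayer(model, {"PORko-G": 100000}, geom, 10.0,
                                 1800.0)
        prof = res.C_medium["SN30000"][-1]
        assert prof.max() - prof.min() < 0.01 * prof.mean()

    def test_no_drug_no_kill(self, reg):
        model = H.build_model("sn30000", reg)
        geom = CultureGeometry(kind="monolayer", medium_volume=0.15e12,
                               well_area=0.32e8)
        res = simulate_monolayer(model, {"PORko-G": 100000}, geom, 0.0, 600.0)
        assert res.survival("PORko-G") == pytest.approx(1.0)

    def test_oxygen_bolus_cleared_faster_at_higher_density(self, reg):
        model = H.build_model("pr104a-dichloro", reg)
        geom = CultureGeometry(kind="monolayer", medium_volume=0.15e12,
                               well_area=0.32e8)
        o2p = {"Vmax": 6e-17, "Km": 1.3, "D_medium": 2000.0}
        lo = simulate_monolayer(model, {"PORko-G": 10000}, geom, 1.0, 3600.0,
                                o2_bolus=2.5, o2_params=o2p)
        hi = simulate_monolayer(model, {"PORko-G": 300000}, geom, 1.0, 3600.0,
                                o2_bolus=2.5, o2_params=o2p)
        assert hi.O2_medium[-1, 0] < lo.O2_medium[-1, 0]

    def test_zero_metabolism_leaves_prodrug_constant(self, reg):
        reg2 = reg.patch({f"solute.SN30000.kmet0.{ln}": 0.0
                          for ln in ("POR-R", "POR-G", "PORko-R", "PORko-G",
                                     "HCT116")})
        model = H.build_model("sn30000", reg2)
        geom = CultureGeometry(kind="monolayer", medium_volume=0.15e12,
                               well_area=0.32e8)
        res = simulate_monolayer(model, {"PORko-G": 100000}, geom, 10.0,
                                 3600.0)
        total0 = res.C_medium["SN30000"][0].mean()
        total1 = res.C_medium["SN30000"][-1].mean()
        assert total1 == pytest.approx(total0, rel=5e-3)
        assert res.survival("PORko-G") == pytest.approx(1.0, abs=1e-9)


class TestMCL:
    def _geom(self):
        return CultureGeometry(kind="mcl", donor_volume=8.5e12,
                               receiver_volume=8.5e12, mcl_thickness=150.0,
                               mcl_area=0.3e8)

    def test_acellular_flux_matches_ficks_law(self, reg):
        model = H.build_model("sn30000", reg)
        geom = self._geom()
        res = simulate_mcl(model, 0.0, "POR-R", "PORko-G", geom, 100.0,
                           5 * 3600.0, acellular=True)
        i = int(np.argmin(np.abs(res.t - 4.5 * 3600)))
        Cd, Cr = res.donor["SN30000"][i], res.receiver["SN30000"][i]
        inst_flux = 100.0 * geom.mcl_area * (Cd - Cr) / 150.0 * 1e-15
        sel = res.t > 4 * 3600
        slope = np.polyfit(res.t[sel], res.receiver_amount["SN30000"][sel],
                           1)[0]
        assert slope == pytest.approx(inst_flux, rel=0.02)

    def test_activators_reduce_receiver_auc_and_raise_metabolites(self, reg):
        model = H.build_model("sn30000", reg)
        geom = self._geom()
        aucs, mets = [], []
        for frac in (0.0, 1.0):
            res = simulate_mcl(model, frac, "POR-R", "PORko-G", geom, 100.0,
                               3 * 3600.0)
            aucs.append(res.receiver_auc("SN30000", 100.0))
            mets.append(res.donor_amount["SN_oxide"][-1]
                        + res.receiver_amount["SN_oxide"][-1])
        assert aucs[1] < aucs[0]
        assert mets[1] > mets[0]

    def test_no_metabolism_no_metabolites(self, reg):
        reg2 = reg.patch({f"solute.SN30000.kmet0.{ln}": 0.0
                          for ln in ("POR-R", "POR-G", "PORko-R", "PORko-G",
                                     "HCT116")})
        model = H.build_model("sn30000", reg2)
        res = simulate_mcl(model, 0.5, "POR-R", "PORko-G", self._geom(),
                           100.0, 3600.0)
        assert res.donor_amount["SN_oxide"][-1] == pytest.approx(0.0, abs=1e-12)

    def test_total_moles_conserved_without_losses(self, reg):
        model = H.build_model("sn30000", reg)
        res = simulate_mcl(model, 0.5, "POR-R", "PORko-G", self._geom(),
                           100.0, 2 * 3600.0)
        tot = res.total_amount["SN30000"] + res.total_amount["SN_oxide"]
        assert abs(tot[-1] - tot[0]) / tot[0] < 1e-3

    def test_invalid_fraction_rejected(self, reg):
        model = H.build_model("sn30000", reg)
        with pytest.raises(ValueError):
            simulate_mcl(model, 1.5, "POR-R", "PORko-G", self._geom(),
                         100.0, 3600.0)
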