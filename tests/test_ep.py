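"""Monodomain electrophysiology: cell model, diffusion, conduction velocity."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from lvemech.ep import (CellState, MitchellSchaefferModel, MonodomainParams,
                        StimulusProtocol, _bar_cv, calibrate_conductivities,
                        conductivity_tensor, measure_conduction_velocity,
                        solve_monodomain, step_cell)
from lvemech.synthetic import wedge_fixture


class TestCellModel:
    def test_resting_stability(self):
        model = MitchellSchaefferModel()
        state = CellState(u=model.initial_state(1), model=model)
        for _ in range(10000):  # 100 ms at dt 0.01
            state = step_cell(state, 0.0, 0.01)
        assert abs(state.V[0] - model.V_rest) < 0.01

    def test_suprathreshold_upstroke(self):
        model = MitchellSchaefferModel()
        state = CellState(u=model.initial_state(1), model=model)
        t = 0.0
        while t < 5.0:
            stim = 0.5 if t < 1.0 else 0.0
            state = step_cell(state, stim, 0.01)
            t += 0.01
            if state.V[0] > 0:
                break
        assert state.V[0] > 0.0
        assert t < 5.0

    def test_apd_near_50ms(self):
        model = MitchellSchaefferModel()
        state = CellState(u=model.initial_state(1), model=model)
        t, crossings = 0.0, []
        while t < 200.0:
            stim = 0.5 if t < 1.0 else 0.0
            prev = state.V[0]
            state = step_cell(state, stim, 0.01)
            t += 0.01
            if (prev < -20 <= state.V[0]) or (prev >= -20 > state.V[0]):
                crossings.append(t)
        assert len(crossings) >= 2
        apd = crossings[1] - crossings[0]
        assert 35 < apd < 70

    def test_step_halving_first_order_convergence(self):
        model = MitchellSchaefferModel()

        def run(dt):
            state = CellState(u=model.initial_state(1), model=model)
            t = 0.0
            while t < 80.0 - dt / 2:
                stim = 0.5 if t < 1.0 else 0.0
                state = step_cell(state, stim, dt)
                t += dt
            return state.u.copy()

        u1 = run(0.01)
        u2 = run(0.005)
        assert np.abs(u1 - u2).max() / np.abs(u2).max() < 0.01

    def test_non_finite_state_rejected(self):
        model = MitchellSchaefferModel()
        state = CellState(u=np.array([[np.inf, 1.0]]), model=model)
        with pytest.raises(FloatingPointError):
            step_cell(state, 0.0, 0.01)


class TestConductivityTensor:
    def test_isotropic_limit(self):
        p = MonodomainParams(sigma_f=2.0, sigma_s=2.0, sigma_n=2.0)
        D = conductivity_tensor(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                                np.array([0, 0, 1.0]), p)
        assert np.allclose(D, 2.0 * np.eye(3), atol=1e-14)

    def test_fibre_entry_and_eigenvalues(self):
        p = MonodomainParams(sigma_f=3.0, sigma_s=1.0, sigma_n=0.5)
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        D0 = conductivity_tensor(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                                 np.array([0, 0, 1.0]), p)
        assert D0[0, 0] == pytest.approx(3.0)
        D = conductivity_tensor(Q[:, 0], Q[:, 1], Q[:, 2], p)
        ev = np.sort(np.linalg.eigvalsh(D))
        assert np.allclose(ev, [0.5, 1.0, 3.0], atol=1e-10)

    def test_non_orthonormal_rejected(self):
        p = MonodomainParams()
        with pytest.raises(ValueError):
            conductivity_tensor(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]),
                                np.array([0, 0, 1.0]), p)


@pytest.fixture(scope="module")
def wedge():
    return wedge_fixture(10, 10, 10, 0.6)


class TestMonodomain:
    def test_zero_stimulus_stays_at_rest(self, wedge):
        mesh, structure = wedge
        stim = StimulusProtocol(select=lambda X: X[:, 0] < 0.1,
                                amplitude=1e-12, duration=1.0)
        res = solve_monodomain(mesh, structure, MonodomainParams(), stim, 10.0,
                               warn_unactivated=False)
        assert not res.activated.any()
        assert np.abs(res.voltage_samples[-1] + 80.0).max() < 0.1

    def test_planar_wavefront_in_midsection(self, wedge):
        mesh, structure = wedge
        stim = StimulusProtocol(select=lambda X: X[:, 0] < 0.07,
                                amplitude=100000.0, duration=1.0)
        res = solve_monodomain(mesh, structure, MonodomainParams(), stim, 25.0,
                               warn_unactivated=False)
        assert res.activated.all()
        x = mesh.nodes[:, 0]
        mid = (x > 0.15) & (x < 0.45)
        fit = np.polyfit(x[mid], res.t_act[mid], 1)
        pred = np.polyval(fit, x[mid])
        ss_res = np.sum((res.t_act[mid] - pred) ** 2)
        ss_tot = np.sum((res.t_act[mid] - res.t_act[mid].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_splitting_consistency_with_negligible_diffusion(self):
        mesh, structure = wedge_fixture(3, 3, 3, 0.3)
        p = MonodomainParams(sigma_f=1e-9, sigma_s=1e-9, sigma_n=1e-9)
        stim = StimulusProtocol(select=lambda X: np.ones(len(X), dtype=bool),
                                amplitude=70000.0, duration=1.0)
        res = solve_monodomain(mesh, structure, p, stim, 30.0,
                               sample_interval=5.0, warn_unactivated=False)
        model = MitchellSchaefferModel()
        state = CellState(u=model.initial_state(1), model=model)
        single = [state.V[0]]
        t = 0.0
        stim_norm = 70000.0 / (p.chi * p.C_m * model.amplitude)
        for k in range(3000):
            state = step_cell(state, stim_norm if t < 1.0 else 0.0, 0.01)
            t += 0.01
            if (k + 1) % 500 == 0:
                single.append(state.V[0])
        v_nodes = res.voltage_samples  # (nt, n)
        spread = np.abs(v_nodes - v_nodes[:, :1]).max()
        assert spread < 1e-6 * 100.0  # all nodes identical
        assert np.abs(v_nodes[:, 0] - np.array(single)).max() < 0.5

    def test_rotation_invariance_of_activation(self):
        mesh, structure = wedge_fixture(8, 8, 8, 0.6)
        p = MonodomainParams()
        stim = StimulusProtocol(select=lambda X: X[:, 0] < 0.1,
                                amplitude=100000.0, duration=1.0)
        res = solve_monodomain(mesh, structure, p, stim, 25.0,
                               warn_unactivated=False)
        ang = 0.7
        Q = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        rot = mesh.copy_with_nodes(mesh.nodes @ Q.T)
        from lvemech.microstructure import StructureField
        rst = StructureField(f=structure.f @ Q.T, s=structure.s @ Q.T,
                             n_vec=structure.n_vec @ Q.T)
        nodes0 = mesh.nodes
        stim_rot = StimulusProtocol(
            select=lambda X: (X @ Q)[:, 0] < 0.1,
            amplitude=100000.0, duration=1.0)
        res_rot = solve_monodomain(rot, rst, p, stim_rot, 25.0,
                                   warn_unactivated=False)
        rng = res.t_act[res.activated].max() - res.t_act[res.activated].min()
        both = res.activated & res_rot.activated
        rms = np.sqrt(np.mean((res.t_act[both] - res_rot.t_act[both]) ** 2))
        assert rms < 0.01 * rng

    def test_temporal_convergence(self):
        mesh, structure = wedge_fixture(8, 8, 8, 0.6)
        stim = StimulusProtocol(select=lambda X: X[:, 0] < 0.1,
                                amplitude=100000.0, duration=1.0)
        p1 = MonodomainParams(dt_pde=0.1)
        p2 = MonodomainParams(dt_pde=0.05)
        r1 = solve_monodomain(mesh, structure, p1, stim, 25.0,
                              warn_unactivated=False)
        r2 = solve_monodomain(mesh, structure, p2, stim, 25.0,
                              warn_unactivated=False)
        rel = np.nanmax(np.abs(r1.t_act - r2.t_act)) / np.nanmax(r2.t_act)
        assert rel < 0.02

    def test_quadratic_mesh_rejected(self, quad_mesh):
        mesh, structure = quad_mesh
        with pytest.raises(ValueError, match="linear"):
            solve_monodomain(mesh, structure, MonodomainParams(),
                             StimulusProtocol(), 1.0)

    def test_apical_stimulus_propagates_baseward(self):
        from lvemech import (FibreModelSpec, SheetModelSpec, build_lv_mesh,
                             build_structure_field, material_axes,
                             transmural_depth)
        from lvemech.geometry import rat_pre_p_spec
        from lvemech.mesh import linearize, refine
        from scipy.spatial import cKDTree
        from lvemech.microstructure import StructureField
        mesh = build_lv_mesh(rat_pre_p_spec(), 0.12, divisions=(2, 12, 6))
        w = transmural_depth(mesh)
        fr = material_axes(mesh)
        st = build_structure_field(mesh, fr, w, FibreModelSpec(R=70, n=1),
                                   SheetModelSpec())
        ep_mesh = refine(mesh)
        _, idx = cKDTree(mesh.element_centroids()).query(
            ep_mesh.element_centroids())
        st_ep = StructureField(f=st.f[idx], s=st.s[idx], n_vec=st.n_vec[idx])
        res = solve_monodomain(ep_mesh, st_ep, MonodomainParams(),
                               StimulusProtocol(), 50.0,
                               warn_unactivated=False)
        assert res.activated.all()
        epi = np.unique(ep_mesh.surfaces["epicardium"])
        pts = ep_mesh.nodes[epi]
        sel = np.abs(np.arctan2(pts[:, 1], pts[:, 0])) < np.pi / 6
        rho, _ = spearmanr(pts[sel, 2], res.t_act[epi][sel])
        assert rho > 0.95  # base (z=0) activates last


class TestConductionVelocity:
    def test_sqrt_sigma_scaling(self):
        p = MonodomainParams(sigma_f=1.15, sigma_s=0.3, sigma_n=0.3)
        cv1 = _bar_cv(p, "fibre", cv_guess=0.02)
        cv4 = _bar_cv(replace(p, sigma_f=4.6), "fibre", cv_guess=0.05)
        assert cv4 / cv1 == pytest.approx(2.0, rel=0.05)

    def test_symmetric_sigma_gives_unit_ratio(self):
        p = MonodomainParams(sigma_f=2.0, sigma_s=2.0, sigma_n=2.0)
        cvf = _bar_cv(p, "fibre", cv_guess=0.03)
        cvs = _bar_cv(p, "sheet", cv_guess=0.03)
        assert cvf / cvs == pytest.approx(1.0, abs=0.02)

    def test_calibration_closure(self):
        cal = calibrate_conductivities(0.06, 2.0)
        cvf = _bar_cv(cal, "fibre", cv_guess=0.06)
        cvs = _bar_cv(cal, "sheet", cv_guess=0.03)
        assert cvf == pytest.approx(0.06, rel=0.03)
        assert cvf / cvs == pytest.approx(2.0, rel=0.05)
        assert cal.sigma_s == pytest.approx(cal.sigma_f / 4)

    def test_unit_ratio_target(self):
        cal = calibrate_conductivities(0.05, 1.0)
        assert cal.sigma_s == pytest.approx(cal.sigma_f)
        assert cal.sigma_n == pytest.approx(cal.sigma_f)

    def test_doubling_target_quadruples_sigma(self):
        c1 = calibrate_conductivities(0.05, 2.0)
        c2 = calibrate_conductivities(0.10, 2.0)
        assert c2.sigma_f / c1.sigma_f == pytest.approx(4.0, rel=0.10)

    def test_non_monotone_activation_rejected(self):
        from lvemech.ep import ActivationResult
        rng = np.random.default_rng(0)
        nodes = np.zeros((100, 3))
        nodes[:, 0] = np.linspace(0, 1, 100)
        res = ActivationResult(
            t_act=rng.uniform(0, 10, 100), activated=np.ones(100, dtype=bool),
            sample_times=np.array([0.0]), voltage_samples=np.zeros((1, 100)),
            nodes=nodes)
        with pytest.raises(ValueError):
            measure_conduction_velocity(res, axis=(1, 0, 0))
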