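"""Solver: permeability calibration, stability bound, FTCS correctness."""

import numpy as np
import pytest

from rosnerve import geometry as geo, oracles, solver as sv
from rosnerve._kernels import run_chunk, run_chunk_numpy
from rosnerve.dynamics import BiochemParams, build_units


class TestPermeability:
    @pytest.mark.parametrize("p_m,res,expected", [
        (2.1e-2, 10.0, 2.1e-3),      # superoxide membrane permeability
        (0.0, 10.0, 0.0),
        (20.0, 7.0, 20.0 / 7.0),
    ])
    def test_membrane_diffusion(self, p_m, res, expected):
        assert sv.membrane_diffusion(p_m, res) == pytest.approx(expected)

    def test_myelin_folds_and_attenuation(self):
        """0.2 µm myelin over 10 nm membranes: 10 folds, 20x reduction."""
        assert sv.myelin_folds(0.2, 0.01) == pytest.approx(10.0)
        assert 20.0 / sv.myelin_permeability(20.0, 0.2, 0.01) \
            == pytest.approx(20.0)

    def test_single_fold_attenuates_twofold(self):
        assert sv.myelin_permeability(8.0, 0.02, 0.01) == pytest.approx(4.0)


class TestStabilityDt:
    def test_hand_evaluated_bound(self, uniform_coeffs):
        # 0.9 / (2*2000*(2*10^2) + 2*2000*10^2) = 7.5e-7 s, by hand
        c = uniform_coeffs((4, 4, 4), d=2000.0, res_xy=10.0, res_z=10.0)
        assert sv.stability_dt(c) == pytest.approx(7.5e-7)

    def test_quarter_on_doubling_resolution(self, uniform_coeffs):
        c1 = uniform_coeffs((4, 4, 4), res_xy=5.0, res_z=5.0)
        c2 = uniform_coeffs((4, 4, 4), res_xy=10.0, res_z=10.0)
        assert sv.stability_dt(c1) / sv.stability_dt(c2) == pytest.approx(4.0)

    def test_reaction_only_bound(self, uniform_coeffs):
        c = uniform_coeffs((4, 4, 1), d=0.0, dz=0.0, rs=1.0)
        assert sv.stability_dt(c) == pytest.approx(0.9)

    def test_all_zero_returns_cap(self, uniform_coeffs):
        c = uniform_coeffs((4, 4, 1), d=0.0, dz=0.0)
        assert sv.stability_dt(c, dt_cap=0.25) == 0.25


class TestStep:
    def test_uniform_field_unchanged(self, uniform_coeffs):
        c = uniform_coeffs((8, 8, 3))
        f = sv.ConcentrationField.uniform((8, 8, 3), 5.0)
        out = sv.run_steps(f, c, sv.stability_dt(c), 50)
        np.testing.assert_allclose(out.values, 5.0, rtol=1e-14)

    def test_mass_conserved_closed_domain(self, uniform_coeffs):
        rng = np.random.default_rng(0)
        c = uniform_coeffs((16, 16, 4))
        f = sv.ConcentrationField(rng.random((16, 16, 4)))
        out = sv.run_steps(f, c, sv.stability_dt(c), 1000)
        rel = abs(out.total_amount() - f.total_amount()) / f.total_amount()
        assert rel < 1e-10

    def test_jit_and_numpy_kernels_agree(self, uniform_coeffs):
        rng = np.random.default_rng(1)
        shape = (9, 7, 5)
        c = uniform_coeffs(shape, d=1000.0, rs=2.0, rp=3.0)
        c.dxx *= rng.random(shape)           # heterogeneous coefficients
        vals = rng.random(shape)
        fx, fy, fz = c.faces
        dt = sv.stability_dt(c)
        a = run_chunk(vals, fx, fy, fz, c.rp, c.rs, dt, 200)
        b = run_chunk_numpy(vals, fx, fy, fz, c.rp, c.rs, dt, 200)
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-14)

    def test_gaussian_point_source(self, uniform_coeffs):
        """Free 2D diffusion of a point source matches the heat kernel to
        2 % (L2) after 100 steps."""
        n, res, d = 129, 1.0, 2000.0
        c = uniform_coeffs((n, n, 1), d=d, res_xy=res)
        vals = np.zeros((n, n, 1))
        vals[n // 2, n // 2, 0] = 1.0
        dt = sv.stability_dt(c)
        out = sv.run_steps(sv.ConcentrationField(vals), c, dt, 100)
        t = 100 * dt
        xs = (np.arange(n) - n // 2) / res
        r = np.hypot(xs[:, None], xs[None, :])
        ref = oracles.gaussian_spread_oracle(d, t, 1.0 / res**2, r, ndim=2) \
            / res**2   # mass per voxel
        err = np.linalg.norm(out.values[:, :, 0] - ref) / np.linalg.norm(ref)
        assert err < 0.02

    def test_blocking_membrane_exact_confinement(self):
        """With D_m = 0, species born inside an axon never leaks out."""
        axon = geo.AxonSpec(0, 0.0, 0.0, 1.5, "T")
        model = geo.rasterize_model([axon], res_xy=7.0, nz=1,
                                    nerve_radius_um=4.0)
        params = BiochemParams(p_m_um_s=0.0, rs_intra=0.0, rs_extra=0.0)
        dxx, dzz = sv.diffusion_maps(model, params)
        memb = model.is_membrane_like()
        assert np.all(dxx[memb] == 0.0) and np.all(dzz[memb] == 0.0)
        inside = model.labels == geo.AXON_INTERIOR
        vals = np.where(inside, 10.0, 0.0)
        cm = sv.CoefficientMaps(dxx=dxx, dzz=dzz, rp=np.zeros_like(dxx),
                                rs=np.zeros_like(dxx), res_xy=7.0, res_z=1.0)
        out = sv.run_steps(sv.ConcentrationField(vals.astype(float)), cm,
                           sv.stability_dt(cm), 2000)
        outside = ~(inside | (model.axon_id == 0))
        assert np.all(out.values[outside] == 0.0)
        assert out.values[inside].sum() == pytest.approx(vals.sum())

    def test_instability_aborts_with_diagnostic(self, uniform_coeffs):
        c = uniform_coeffs((16, 16, 1))
        f = sv.ConcentrationField(np.random.default_rng(2).random((16, 16, 1)))
        with pytest.raises(sv.StabilityError, match="stability"):
            sv.run_steps(f, c, 50 * sv.stability_dt(c), 200)


class TestAssembleCoefficients:
    @pytest.fixture(scope="class")
    def longitudinal(self):
        axons = geo.place_axons(4.0, geo.DiameterDistribution.default(), 6)
        layout = [geo.Slab("unmyelinated", 5.0), geo.Slab("myelinated", 8.0),
                  geo.Slab("node", 1.0), geo.Slab("myelinated", 6.0)]
        model = geo.build_longitudinal_model(layout, axons, res_xy=7.0,
                                             res_z=1.0, nerve_radius_um=4.0)
        return geo.place_mitochondria(model, 8.0, 0.0, 7)

    def test_internodal_scavenging_scaled(self, longitudinal):
        params = BiochemParams(zone_rs={"internodal": 0.7},
                               rs_mito_factor=1.0)
        cm = sv.assemble_coefficients(longitudinal, params)
        interior = longitudinal.labels == geo.AXON_INTERIOR
        internodal = (longitudinal.zone_z == geo.ZONE_INTERNODAL)[None, None, :]
        unmyel = (longitudinal.zone_z == geo.ZONE_UNMYELINATED)[None, None, :]
        assert np.allclose(cm.rs[interior & internodal],
                           0.7 * params.rs_intra)
        assert np.allclose(cm.rs[interior & unmyel], params.rs_intra)
        assert np.all(cm.rs[longitudinal.is_membrane_like()] == 0.0)

    def test_superoxide_membranes_fully_blocking(self, longitudinal):
        params = BiochemParams(p_m_um_s=0.0)
        cm = sv.assemble_coefficients(longitudinal, params)
        memb = longitudinal.is_membrane_like()
        assert np.all(cm.dxx[memb] == 0.0)
        assert np.all(cm.dzz[memb] == 0.0)

    def test_dead_states_zero_production(self, longitudinal):
        from rosnerve.dynamics import DEAD, UnitStates, build_units
        params = BiochemParams()
        units = build_units(longitudinal, params)
        dead = UnitStates(np.full(units.n_units, DEAD, dtype=np.uint8),
                          np.zeros(units.n_units))
        cm = sv.assemble_coefficients(longitudinal, params, states=dead)
        assert np.all(cm.rp == 0.0)
        healthy = sv.assemble_coefficients(longitudinal, params)
        assert healthy.rp.max() > 0
        assert np.all(healthy.rp[~longitudinal.mito] == 0.0)


class TestSteadyState:
    def test_uniform_reaction_fixed_point(self, uniform_coeffs):
        """Closed uniform model converges to c* = RP/RS (10 nM here)."""
        c = uniform_coeffs((12, 12, 1), rp=10.0, rs=1.0)  # 0.01 µM/s, 1/s
        res = sv.run_to_steady_state(sv.ConcentrationField.uniform((12, 12, 1)),
                                     c, tol=1e-6, t_max=60.0)
        expect = oracles.uniform_steady_oracle(0.01, 1.0)
        assert res.converged
        np.testing.assert_allclose(res.field.values, expect, rtol=1e-3)

    def test_zero_production_immediate_convergence(self, uniform_coeffs):
        c = uniform_coeffs((6, 6, 1), rp=0.0, rs=1.0)
        res = sv.run_to_steady_state(sv.ConcentrationField.uniform((6, 6, 1)),
                                     c, tol=1e-5, t_max=10.0)
        assert res.converged and res.t_bio == 0.0

    def test_nonconvergence_flagged(self, uniform_coeffs):
        c = uniform_coeffs((6, 6, 1), rp=10.0, rs=0.01)
        res = sv.run_to_steady_state(sv.ConcentrationField.uniform((6, 6, 1)),
                                     c, tol=1e-9, t_max=1e-3)
        assert not res.converged

    def test_two_compartment_membrane_flux(self):
        """Trans-membrane equilibration rate matches the two-box ODE to 5 %.

        1-D column of high-D cells split by one membrane voxel.  The
        discrete scheme's effective permeability carries the series
        face-flux correction P_eff = P_m / (1 + P_m·dx/D_free) (documented
        in the methods note); box volumes exclude the membrane voxel, whose
        storage is quasi-steady.
        """
        res_xy, p_m, d_free = 5.0, 50.0, 5e4
        dx = 1.0 / res_xy
        n = 21
        m = n // 2                      # membrane cell index
        dxx = np.full((n, 1, 1), d_free)
        dxx[m] = sv.membrane_diffusion(p_m, res_xy)
        cm = sv.CoefficientMaps(dxx=dxx, dzz=np.zeros((n, 1, 1)),
                                rp=np.zeros((n, 1, 1)), rs=np.zeros((n, 1, 1)),
                                res_xy=res_xy, res_z=1.0)
        vals = np.zeros((n, 1, 1))
        vals[:m] = 100.0
        dt = sv.stability_dt(cm)
        v_in = v_out = m * dx
        p_eff = p_m / (1.0 + p_m * dx / d_free)
        ana = oracles.two_box_permeability_oracle(v_in, v_out, 1.0, p_eff,
                                                  100.0, 0.0)
        n1 = int(round(0.3 * ana.half_life / dt))
        n2 = int(round(0.9 * ana.half_life / dt))
        f1 = sv.run_steps(sv.ConcentrationField(vals.copy()), cm, dt, n1)
        f2 = sv.run_steps(f1, cm, dt, n2 - n1)

        def gap(g):
            return g.values[:m].mean() - g.values[m + 1:].mean()

        rate_meas = np.log(gap(f1) / gap(f2)) / ((n2 - n1) * dt)
        assert rate_meas == pytest.approx(ana.rate, rel=0.05)
        # closed-form and independently integrated ODE agree too
        t_eval = np.array([0.0, 0.3 * ana.half_life])
        y = oracles.two_box_numeric(v_in, v_out, 1.0, p_eff, 100.0, 0.0,
                                    t_eval)
        ref_in, ref_out = ana.concentrations(t_eval[1])
        assert y[0, -1] == pytest.approx(ref_in, rel=1e-6)
        assert y[1, -1] == pytest.approx(ref_out, rel=1e-6)

    @staticmethod
    def _steady_field_at(res):
        """Single membrane-wrapped axon with a fixed 1 µm² production patch."""
        axon = geo.AxonSpec(0, 0.0, 0.0, 1.5, "T")
        model = geo.rasterize_model([axon], res_xy=res, nz=1,
                                    nerve_radius_um=3.0)
        params = BiochemParams(p_m_um_s=20.0, rs_intra=10.0, rs_extra=10.0,
                               rs_mito_factor=1.0)
        dxx, dzz = sv.diffusion_maps(model, params)
        rs = sv.scavenging_map(model, params)
        n = model.grid_shape[0]
        xs = (np.arange(n) + 0.5) / res - 3.0
        box = (xs >= -0.5) & (xs < 0.5)     # half-open: area exactly 1 µm²
        rp = np.where((box[:, None] & box[None, :])[:, :, None], 100.0, 0.0)
        cm = sv.CoefficientMaps(dxx=dxx, dzz=dzz, rp=rp, rs=rs,
                                res_xy=res, res_z=1.0)
        return sv.solve_steady_state(cm, tol=1e-12).values[:, :, 0]

    @classmethod
    def _refinement_error(cls, r1, r2):
        coarse = cls._steady_field_at(r1)
        fine = cls._steady_field_at(r2)
        f = fine[:fine.shape[0] // 2 * 2, :fine.shape[1] // 2 * 2]
        fa = f.reshape(f.shape[0] // 2, 2, f.shape[1] // 2, 2).mean((1, 3))
        ca = coarse[:fa.shape[0], :fa.shape[1]]
        return np.linalg.norm(fa - ca) / np.linalg.norm(ca)

    def test_grid_refinement_steady_field_stable(self):
        """Halving the voxel size changes the steady field by < 5 % (L2) at
        the working resolution, and the error shrinks as resolution grows
        (first-order convergence of the one-voxel membrane representation)."""
        err_low = self._refinement_error(7.0, 14.0)
        err_work = self._refinement_error(10.0, 20.0)
        assert err_work < 0.05
        assert err_work < err_low
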