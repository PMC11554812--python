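"""Assembly properties and time-stepping accuracy of the porous-wall solver."""

import numpy as np
import pytest

from conftest import reference_ode_solution, uniform_pde_run
from myoperf import geometry as geo
from myoperf.darcy_fem import DarcyStepper, PressureFields
from myoperf.driving import PimField, build_plv_waveform
from myoperf.params import MMHG_TO_PA, ParameterSet

PRM = ParameterSet()


@pytest.fixture(scope="module")
def tiny_mesh():
    return geo.generate_idealized_wall("slab", (10, 10, 10), 5.0)


def _uniform_state(mesh, p_mmhg=(90.0, 60.0, 30.0), pim=0.0):
    n = mesh.n_nodes
    p = np.tile(np.asarray(p_mmhg)[:, None] * MMHG_TO_PA, (1, n))
    return PressureFields(p=p, pim=np.full(n, pim), time=0.0)


class TestAssembly:
    def test_matrix_symmetric(self, tiny_mesh):
        stepper = DarcyStepper(tiny_mesh, PRM)
        rng = np.random.default_rng(7)
        state = _uniform_state(tiny_mesh)
        state.p += rng.normal(scale=500.0, size=state.p.shape)
        sys0 = stepper.assemble(state, np.zeros(tiny_mesh.n_nodes),
                                np.zeros(tiny_mesh.n_nodes), PRM.dt)
        M = sys0.matrix
        asym = abs(M - M.T).max()
        assert asym < 1e-12 * abs(M).max()

    def test_spd_via_cholesky_like_check(self, tiny_mesh):
        stepper = DarcyStepper(tiny_mesh, PRM)
        state = _uniform_state(tiny_mesh)
        sys0 = stepper.assemble(state, np.zeros(tiny_mesh.n_nodes),
                                np.zeros(tiny_mesh.n_nodes), PRM.dt)
        from scipy.sparse.linalg import eigsh
        lam_min = eigsh(sys0.matrix, k=1, which="SA",
                        return_eigenvectors=False)[0]
        assert lam_min > 0.0

    def test_exchange_rows_conserve_mass(self, tiny_mesh):
        """Summing the three compartment blocks of any column must leave only
        stiffness (zero-sum) plus the venous sink: exchange cancels pairwise."""
        stepper = DarcyStepper(tiny_mesh, PRM, rigid=True)
        state = _uniform_state(tiny_mesh)
        sys0 = stepper.assemble(state, np.zeros(tiny_mesh.n_nodes),
                                np.zeros(tiny_mesh.n_nodes), None)
        n = tiny_mesh.n_nodes
        ones = np.ones(3 * n)
        v = sys0.matrix.T @ ones  # column sums
        nv = tiny_mesh.node_volumes * 1e-9
        expected = np.concatenate([np.zeros(2 * n),
                                   PRM.venous_conductance * nv])
        np.testing.assert_allclose(v, expected, atol=1e-18)

    def test_neumann_null_space_without_sink(self, tiny_mesh):
        # no exchange, no sink, no compliance: pure Neumann blocks are singular
        free = PRM.replace(morphometry_factor=(0.0, 0.0, 0.0),
                           venous_conductance=1e-300)
        stepper = DarcyStepper(tiny_mesh, free, rigid=True)
        state = _uniform_state(tiny_mesh)
        sys0 = stepper.assemble(state, np.zeros(tiny_mesh.n_nodes),
                                np.zeros(tiny_mesh.n_nodes), None)
        const = np.ones(3 * tiny_mesh.n_nodes)
        resid = np.abs(sys0.matrix @ const).max()
        assert resid < 1e-20
        sys0.rhs[:] = 1.0  # incompatible data must be flagged
        with pytest.raises(RuntimeError):
            stepper.solve_system(sys0)

    def test_nan_coefficient_raises(self, tiny_mesh):
        stepper = DarcyStepper(tiny_mesh, PRM)
        state = _uniform_state(tiny_mesh)
        state.p[1, 3] = np.nan
        with pytest.raises(FloatingPointError):
            stepper.assemble(state, np.zeros(tiny_mesh.n_nodes),
                             np.zeros(tiny_mesh.n_nodes), PRM.dt)


class TestStepping:
    def test_equilibrium_preserved(self, tiny_mesh):
        """θ ≡ 0, P_im ≡ 0, p_i = p_ra is a fixed point of the step."""
        stepper = DarcyStepper(tiny_mesh, PRM)
        n = tiny_mesh.n_nodes
        pra = PRM.right_atrium_pressure
        state = PressureFields(p=np.full((3, n), pra), pim=np.zeros(n))
        stepper.prepare_step(state, np.zeros(n), PRM.dt)
        p = stepper.step_with_theta1(np.zeros(n))
        np.testing.assert_allclose(p, pra, rtol=1e-12)

    def test_uniform_run_stays_uniform(self, tiny_mesh):
        plv = build_plv_waveform(140 * MMHG_TO_PA, 0.714, 0.37)
        lam = tiny_mesh.require_transmural()
        field = PimField(plv, lam, endo_factor=0.3, epi_factor=0.3)
        stepper = DarcyStepper(tiny_mesh, PRM)
        state = uniform_pde_run(stepper, field, theta1=0.05, dt=2e-3,
                                t_end=0.1, p0=np.array([90, 65, 35]) * MMHG_TO_PA)
        for i in range(3):
            spread = state.p[i].max() - state.p[i].min()
            assert spread < 1e-6 * state.p[i].mean()

    def test_matches_ode_oracle_first_order(self, tiny_mesh):
        """The semi-implicit step converges at O(Δt) to the 0D reduction."""
        plv = build_plv_waveform(140 * MMHG_TO_PA, 0.714, 0.37)
        lam = tiny_mesh.require_transmural()
        field = PimField(plv, lam, endo_factor=0.3, epi_factor=0.3)
        theta1 = 0.05  # s⁻¹, uniform prescribed source
        p0 = np.array([90.0, 65.0, 35.0]) * MMHG_TO_PA
        t_end = 0.26  # one systole
        ref = reference_ode_solution(PRM, lambda t: 0.3 * plv(t), theta1,
                                     t_end, y0=[p0[1], p0[2]])
        errs = {}
        for dt in (2e-3, 1e-3):
            stepper = DarcyStepper(tiny_mesh, PRM)
            end = uniform_pde_run(stepper, field, theta1, dt, t_end, p0)
            errs[dt] = np.hypot(end.p[1, 0] - ref.y[0, -1],
                                end.p[2, 0] - ref.y[1, -1])
        # errors small on the pressure scale and halving with Δt
        assert errs[2e-3] < 0.02 * 140 * MMHG_TO_PA
        ratio = errs[2e-3] / errs[1e-3]
        assert 1.5 < ratio < 2.6

    def test_solution_residual_is_tight(self, tiny_mesh):
        stepper = DarcyStepper(tiny_mesh, PRM)
        state = _uniform_state(tiny_mesh)
        stepper.prepare_step(state, np.zeros(tiny_mesh.n_nodes), PRM.dt)
        theta = np.full(tiny_mesh.n_nodes, 0.03)
        p = stepper.step_with_theta1(theta)  # raises if residual > 1e-10
        assert np.all(np.isfinite(p))

    def test_cg_solver_agrees_with_direct(self, tiny_mesh):
        state = _uniform_state(tiny_mesh)
        theta = np.full(tiny_mesh.n_nodes, 0.03)
        ps = {}
        for solver in ("auto", "cg"):
            stepper = DarcyStepper(tiny_mesh, PRM, solver=solver)
            stepper.prepare_step(state, np.zeros(tiny_mesh.n_nodes), PRM.dt)
            ps[solver] = stepper.step_with_theta1(theta)
        np.testing.assert_allclose(ps["cg"], ps["auto"], rtol=1e-8)

    def test_mass_balance_residual_tiny(self, tiny_mesh):
        stepper = DarcyStepper(tiny_mesh, PRM)
        state = _uniform_state(tiny_mesh)
        n = tiny_mesh.n_nodes
        theta = np.full(n, 0.05)
        stepper.prepare_step(state, np.zeros(n), PRM.dt)
        p = stepper.step_with_theta1(theta)
        new = PressureFields(p=p, pim=state.pim, time=PRM.dt)
        inflow = float(np.dot(tiny_mesh.node_volumes * 1e-9, theta))
        resid = stepper.mass_balance_residual(state, new, theta, PRM.dt)
        assert resid < 1e-10 * inflow
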