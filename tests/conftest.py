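"""Shared fixtures: meshes and the (expensive) reference simulations.

The coupled heartbeat runs are session-scoped so the rigid-vs-compliant pair
and the sensitivity sweeps are computed once and shared by all tests that
inspect them.
"""

from __future__ import annotations

import numpy as np
import pytest

from myoperf import experiments as ex
from myoperf import geometry as geo
from myoperf.params import ParameterSet


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def small_slab() -> geo.WallMesh:
    """20×20×10 mm slab, h = 2.5 mm — cheap unit-test domain."""
    return geo.generate_idealized_wall("slab", (20.0, 20.0, 10.0), 2.5)


@pytest.fixture(scope="session")
def coarse_wall() -> geo.WallMesh:
    """60×60×10 mm wall at h = 5 mm used for the coupled reference runs.

    Large enough (36 ml ≈ a third of an LV free wall) that each of the four
    synthetic outlet territories has a physiological volume.
    """
    return geo.generate_idealized_wall("slab", (60.0, 60.0, 10.0), 5.0)


@pytest.fixture(scope="session")
def sweep_wall() -> geo.WallMesh:
    """48×48×10 mm wall at h = 6 mm — coarser substrate for the sweeps."""
    return geo.generate_idealized_wall("slab", (48.0, 48.0, 10.0), 6.0)


@pytest.fixture(scope="session")
def pair_runs(coarse_wall, default_params):
    """Compliant and rigid reference runs on identical inputs."""
    return ex.compare_rigid(coarse_wall, default_params, seed=0,
                            max_beats=10, cycle_tol=0.0015)


@pytest.fixture(scope="session")
def compliant_run(pair_runs):
    return pair_runs.compliant


@pytest.fixture(scope="session")
def rigid_run(pair_runs):
    return pair_runs.rigid


@pytest.fixture(scope="session")
def kappa_sweep(sweep_wall, default_params):
    spec = ex.SweepSpec(parameter="kappa", values=[5e-10, 5e-9, 5e-8],
                        base=default_params, seed=0)
    return ex.sensitivity_sweep(spec, sweep_wall, n_beats=3)


@pytest.fixture(scope="session")
def nl_sweep(sweep_wall, default_params):
    spec = ex.SweepSpec(parameter="nL_scale", values=[0.75, 1.0, 1.5, 2.0],
                        base=default_params, seed=0)
    return ex.sensitivity_sweep(spec, sweep_wall, n_beats=3)


def reference_ode_solution(params, pim_of_t, theta1, t_end, y0, t_eval=None):
    """High-accuracy reference for the spatially uniform (0D) reduction.

    With uniform fields the porous-medium system degenerates to a DAE: the
    rigid first compartment gives the algebraic relation
    β₁₂(p₁ − p₂) = θ₁, and (p₂, p₃) obey
        (nL)₂C₂ d(p₂ − P_im)/dt = θ₁ − β₂₃(p₂ − p₃)
        (nL)₃C₃ d(p₃ − P_im)/dt = β₂₃(p₂ − p₃) − γ(p₃ − p_ra).
    Integrated with an implicit stiff solver at tight tolerance; serves as
    the independent oracle for the FEM time stepper.
    """
    from scipy.integrate import solve_ivp

    from myoperf import constitutive as law

    h = 1e-7

    def pim_rate(t):
        return (pim_of_t(t + h) - pim_of_t(t - h)) / (2 * h)

    def rhs(t, y):
        p2, p3 = y
        pim = pim_of_t(t)
        dp2, dp3 = p2 - pim, p3 - pim
        b23 = law.exchange_conductance(2, 3, dp2, dp3, params)
        c2 = params.nL[1] * law.distensibility(2, dp2)
        c3 = params.nL[2] * law.distensibility(3, dp3)
        f23 = b23 * (p2 - p3)
        dp2dt = pim_rate(t) + (theta1 - f23) / c2
        dp3dt = pim_rate(t) + (f23 - params.venous_conductance
                               * (p3 - params.right_atrium_pressure)) / c3
        return [dp2dt, dp3dt]

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="Radau",
                    rtol=1e-10, atol=1e-6, t_eval=t_eval, max_step=1e-3)
    assert sol.success
    return sol


def uniform_pde_run(stepper, pim_field, theta1, dt, t_end, p0):
    """March the FEM stepper with uniform prescribed source and P_im."""
    from myoperf.darcy_fem import PressureFields
    from myoperf.driving import evaluate_pim, pim_time_derivative

    n = stepper.mesh.n_nodes
    state = PressureFields(p=np.tile(np.asarray(p0, float)[:, None], (1, n)),
                           pim=evaluate_pim(pim_field, 0.0), time=0.0)
    theta = np.full(n, theta1)
    t = 0.0
    while t < t_end - 1e-12:
        dpim = pim_time_derivative(pim_field, t, dt)
        stepper.prepare_step(state, dpim, dt)
        p = stepper.step_with_theta1(theta)
        t += dt
        state = PressureFields(p=p, pim=evaluate_pim(pim_field, t), time=t)
        stepper.invalidate()
    return state


def make_rod(n: int = 11, spacing: float = 1.0):
    """1D chain 'mesh' stand-in for graph-based territory operations."""

    class Rod:
        nodes = np.column_stack([np.arange(n) * spacing,
                                 np.zeros(n), np.zeros(n)])
        edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        node_volumes = np.ones(n)
        n_nodes = n

    return Rod()
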