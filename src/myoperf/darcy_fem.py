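"""Semi-implicit finite-element stepper for the compliant Darcy system.

Per compartment i = 1..3 the model on the wall domain Ω (homogeneous Neumann
boundary) is

    −∇·(K_i ∇p_i) + (nL)_i C_i ∂(p_i − P_im)/∂t + Σ_j β_{i,j}(p_i − p_j) = θ_i,

with all coefficients K_i, C_i, β_{i,j} nonlinear functions of the local
transluminal pressure Δp_i = p_i − P_im.  One time step freezes the
coefficients at the previous state (semi-implicit linearization) and solves
the resulting symmetric positive-definite 3N×3N block system with pressures
fully implicit:

    −∇·(K_i^n ∇p_i^{n+1}) + (nL)_i C_i^n (p_i^{n+1} − p_i^n)/Δt
        + Σ_j β_{i,j}^n (p_i^{n+1} − p_j^{n+1})
        = θ_i + (nL)_i C_i^n (P_im^{n+1} − P_im^n)/Δt.

Space discretization: P1 tetrahedral elements, element-mean permeability in
the stiffness term, and row-sum (lumped) quadrature for every reaction-type
term — compliance, exchange and venous sink — which keeps the system SPD
and makes the discrete mass-balance statements exact sums.  The venous sink
γ p₃ regularizes the pure-Neumann null space.

Conservative compliance accounting: the plain frozen-coefficient product
C_i^n·Δ(p_i − P_im) is not an exact increment of the porosity φ_i, so its
sum around a periodic cycle carries an O(Δt) bias.  The stepper therefore
tracks the linearized porosity it has actually accounted,
φ̂^{n+1} = φ(Δp^n) + C^n·(Δp^{n+1} − Δp^n), and feeds the committed defect
φ(Δp^n) − φ̂^n back into the next right-hand side (a deferred correction in
the spirit of mixed-form Richards-equation solvers).  The accounted storage
then telescopes exactly, so inflow and venous outflow balance over a
periodic cycle to the periodicity tolerance; the correction is O(Δt²) per
step and leaves the matrix and the first-order accuracy untouched.

Internally the mesh (mm) is converted to metres so all assembled quantities
are SI; pressures are in Pa throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as law
from .geometry import WallMesh, p1_gradients, tet_volumes
from .params import ParameterSet

MM_TO_M = 1e-3
MM3_TO_M3 = 1e-9


@dataclass
class PressureFields:
    """The three nodal compartment pressures plus P_im at one instant (Pa)."""

    p: np.ndarray  # (3, N)
    pim: np.ndarray  # (N,)
    time: float = 0.0

    def copy(self) -> "PressureFields":
        return PressureFields(self.p.copy(), self.pim.copy(), self.time)

    @property
    def dp(self) -> np.ndarray:
        """Transluminal pressures Δp_i = p_i − P_im, (3, N)."""
        return self.p - self.pim[None, :]


@dataclass
class StepSystem:
    """Assembled linear system of one semi-implicit step."""

    matrix: sp.csr_matrix  # 3N × 3N, SPD
    rhs: np.ndarray
    n_nodes: int


class DarcyStepper:
    """Reusable assembler/solver bound to one mesh and parameter set.

    Element geometry (P1 gradients, volumes) is precomputed once; each step
    re-evaluates the nonlinear coefficients at the current state, assembles
    and factorizes.  Within a fixed-point pass at a frozen state only the
    source term changes, so the factorization is cached and reused until the
    state moves on (:meth:`invalidate`).

    ``rigid=True`` freezes every coefficient at Δp = 0 and removes the
    compliance term, turning the model into the classic rigid multi-
    compartment Darcy system.
    """

    def __init__(self, mesh: WallMesh, params: ParameterSet, *, rigid: bool = False,
                 solver: str = "auto"):
        self.mesh = mesh
        self.params = params
        self.rigid = rigid
        self.solver = solver
        nodes_m = mesh.nodes * MM_TO_M
        self._vol = tet_volumes(nodes_m, mesh.tets)  # m³
        grads = p1_gradients(nodes_m, mesh.tets)  # 1/m
        # geometric element stiffness ∫ ∇φ_a·∇φ_b, scaled later by K_e
        self._ke_geo = np.einsum("eik,ejk->eij", grads, grads) * self._vol[:, None, None]
        self._rows = np.repeat(mesh.tets, 4, axis=1).ravel()
        self._cols = np.tile(mesh.tets, (1, 4)).ravel()
        self._nv = mesh.node_volumes * MM3_TO_M3  # lumped nodal volumes, m³
        self._n = mesh.n_nodes
        self._cached = None  # (matrix, factor, frozen-coefficient dict)
        self._phi_lin = None  # accounted linearized porosities (3, N)

    # -- conservative compliance bookkeeping ------------------------------
    def porosities(self, state: PressureFields) -> np.ndarray:
        """Nodal porosities φ_i at the state's transluminal pressures, (3, N)."""
        p = self.params
        dp = np.zeros_like(state.p) if self.rigid else state.dp
        return np.stack([np.asarray(law.porosity(i, dp[i - 1], p))
                         for i in (1, 2, 3)])

    def reset_storage_tracking(self, state: PressureFields) -> None:
        """Anchor the accounted porosity at ``state`` (start of a transient)."""
        self._phi_lin = self.porosities(state)

    def commit_step(self, old: PressureFields, new: PressureFields) -> None:
        """Advance the accounted porosity φ̂ after a step is accepted.

        φ̂^{n+1} = φ(Δp^n) + (nL)C^n·(Δp^{n+1} − Δp^n), exactly the storage
        increment the linearized step charged against the mass balance.
        """
        if self.rigid:
            return
        c = self.coefficients(old)
        self._phi_lin = self.porosities(old) + c["nLC"] * (new.dp - old.dp)

    # -- coefficient evaluation -------------------------------------------
    def coefficients(self, state: PressureFields) -> dict:
        """Frozen nodal coefficients K_i, (nL)C_i, β_{i,j} at ``state``."""
        p = self.params
        dp = np.zeros_like(state.p) if self.rigid else state.dp
        K = np.stack([np.asarray(law.permeability(i, dp[i - 1], p)) for i in (1, 2, 3)])
        if self.rigid:
            nLC = np.zeros_like(K)
        else:
            nLC = np.stack([p.nL[i - 1] * np.asarray(law.distensibility(i, dp[i - 1]))
                            for i in (1, 2, 3)])
        b12 = np.asarray(law.exchange_conductance(1, 2, dp[0], dp[1], p))
        b23 = np.asarray(law.exchange_conductance(2, 3, dp[1], dp[2], p))
        if not np.all(np.isfinite(K)) or not np.all(np.isfinite(nLC)):
            bad = np.argwhere(~np.isfinite(K))
            raise FloatingPointError(
                f"non-finite coefficient at compartment/node {bad[:1]}")
        return {"K": K, "nLC": nLC, "b12": b12, "b23": b23}

    # -- assembly ----------------------------------------------------------
    def assemble(self, state: PressureFields, theta1: np.ndarray,
                 dpim_dt: np.ndarray, dt: float | None) -> StepSystem:
        """Assemble the 3N system for one step (``dt=None`` → steady problem).

        ``theta1``: nodal source (s⁻¹); ``dpim_dt``: nodal discrete rate of
        P_im (Pa/s), ignored in steady/rigid assembly.
        """
        c = self.coefficients(state)
        n, prm = self._n, self.params
        tets = self.mesh.tets

        blocks = []
        diags = np.zeros((3, n))
        for i in range(3):
            K_e = np.asarray(c["K"][i])[tets].mean(axis=1)
            vals = (self._ke_geo * K_e[:, None, None]).ravel()
            S = sp.coo_matrix((vals, (self._rows, self._cols)), shape=(n, n))
            blocks.append(S)
            if dt is not None:
                diags[i] += self._nv * c["nLC"][i] / dt
        # exchange (lumped): + on diagonal blocks, − on off-diagonal
        ex12 = self._nv * c["b12"]
        ex23 = self._nv * c["b23"]
        diags[0] += ex12
        diags[1] += ex12 + ex23
        diags[2] += ex23 + self._nv * prm.venous_conductance

        M = sp.bmat([
            [blocks[0] + sp.diags(diags[0]), sp.diags(-ex12), None],
            [sp.diags(-ex12), blocks[1] + sp.diags(diags[1]), sp.diags(-ex23)],
            [None, sp.diags(-ex23), blocks[2] + sp.diags(diags[2])],
        ], format="csr")

        rhs = np.zeros(3 * n)
        rhs[:n] = self._nv * theta1
        rhs[2 * n:] += self._nv * prm.venous_conductance * prm.right_atrium_pressure
        if dt is not None:
            defect = self._storage_defect(state)  # (3, N), dimensionless
            for i in range(3):
                hist = self._nv * (c["nLC"][i] * (state.p[i] / dt + dpim_dt)
                                   - defect[i] / dt)
                rhs[i * n:(i + 1) * n] += hist
        return StepSystem(matrix=M, rhs=rhs, n_nodes=n)

    def _storage_defect(self, state: PressureFields) -> np.ndarray:
        """φ(Δp^n) − φ̂^n: compliance volume charged short by earlier steps."""
        if self.rigid or self._phi_lin is None:
            return np.zeros((3, self._n))
        return self.porosities(state) - self._phi_lin

    # -- linear solve ------------------------------------------------------
    def _factorize(self, M: sp.csr_matrix):
        if self.solver == "cg":
            return None
        return spla.factorized(M.tocsc())

    def solve_system(self, system: StepSystem, factor=None) -> np.ndarray:
        M, b = system.matrix, system.rhs
        if self.solver == "cg":
            precond = sp.diags(1.0 / M.diagonal())
            x, info = spla.cg(M, b, rtol=1e-12, atol=0.0, M=precond, maxiter=20000)
            if info != 0:
                raise RuntimeError(f"CG failed to converge (info={info}); the "
                                   "system may be singular (pure-Neumann null "
                                   "space without sink or compliance)")
        else:
            solve = factor if factor is not None else self._factorize(M)
            x = solve(b)
        bnorm = np.linalg.norm(b)
        res = np.linalg.norm(M @ x - b) / (bnorm if bnorm > 0 else 1.0)
        if not np.isfinite(res) or res > 1e-10:
            raise RuntimeError(f"linear solve residual {res:.2e} exceeds 1e-10; "
                               "system may be singular (pure-Neumann null space)")
        return x

    # -- stepping ----------------------------------------------------------
    def prepare_step(self, state: PressureFields, dpim_dt: np.ndarray,
                     dt: float) -> None:
        """Freeze coefficients at ``state`` and factorize the step matrix.

        The source θ₁ enters only the right-hand side, so fixed-point
        iterations at this step can reuse the factorization.
        """
        sys0 = self.assemble(state, np.zeros(self._n), dpim_dt, dt)
        factor = self._factorize(sys0.matrix)
        self._cached = (sys0, factor)

    def step_with_theta1(self, theta1: np.ndarray) -> np.ndarray:
        """Solve the prepared step for a given source; returns p as (3, N)."""
        if self._cached is None:
            raise RuntimeError("call prepare_step first")
        sys0, factor = self._cached
        rhs = sys0.rhs.copy()
        rhs[:self._n] += self._nv * theta1
        x = self.solve_system(StepSystem(sys0.matrix, rhs, self._n), factor)
        return x.reshape(3, self._n)

    def invalidate(self) -> None:
        self._cached = None

    # -- diagnostics -------------------------------------------------------
    def storage_rate(self, old: PressureFields, new: PressureFields,
                     dt: float) -> float:
        """Discrete d/dt ∫ Σ_i φ_i dV over the step, m³/s (lumped).

        Uses exactly the solver's accounting — the linearized increment plus
        the deferred defect — so the per-step balance
        Σ_k q_k + ∫θ₃ − storage = 0 holds to solver precision and the sum
        telescopes over a cycle.
        """
        c = self.coefficients(old)
        defect = self._storage_defect(old)
        dpim = new.pim - old.pim
        total = 0.0
        for i in range(3):
            inc = c["nLC"][i] * (new.p[i] - old.p[i] - dpim) + defect[i]
            total += float(np.dot(self._nv, inc / dt))
        return total

    def mass_balance_residual(self, old: PressureFields, new: PressureFields,
                              theta1: np.ndarray, dt: float) -> float:
        """| ∫θ₁ + ∫θ₃ − storage | for one accepted step, m³/s."""
        from .coronary0d import theta3_sink
        inflow = float(np.dot(self._nv, theta1))
        sink = float(np.dot(self._nv, theta3_sink(new.p[2], self.params)))
        return abs(inflow + sink - self.storage_rate(old, new, dt))
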