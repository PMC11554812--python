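"""Computational domains: idealized left-ventricular-wall meshes.

The perfusion model is posed on a tetrahedral mesh of a ventricular-wall-like
domain Ω whose boundary is split into three tagged surfaces: *endocardium*
(inner), *epicardium* (outer) and *base* (the truncation surface).  Two
idealized generators are provided — a rectangular slab and a half-ellipsoid
shell — plus readers for externally supplied meshes (see
:mod:`myoperf.meshfile`).

The normalized transmural coordinate λ ∈ [0, 1] (0 on the endocardium, 1 on
the epicardium) is obtained by harmonic interpolation: λ solves Δλ = 0 with
Dirichlet data 0/1 on the tagged surfaces and zero flux on the base.  On a
flat slab this reproduces the linear depth profile exactly; on curved walls
it gives a smooth monotone depth that the maximum principle keeps in [0, 1].

All coordinates and volumes are in mm / mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

ENDO, EPI, BASE = "endocardium", "epicardium", "base"
SURFACE_TAGS = (ENDO, EPI, BASE)


@dataclass
class WallMesh:
    """Tetrahedral wall mesh with tagged surfaces and transmural field.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    tets : (E, 4) int array, positively oriented
    surface_tags : dict mapping tag name -> (F, 3) int array of boundary facets
    transmural : (N,) float array, λ in [0, 1] (filled lazily)
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface_tags: dict
    transmural: np.ndarray | None = None
    _node_volumes: np.ndarray | None = field(default=None, repr=False)
    _edges: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        vol = tet_volumes(self.nodes, self.tets)
        neg = vol <= 0
        if np.any(neg):
            # fix orientation by swapping two vertices of inverted tets
            t = self.tets.copy()
            t[neg, 1], t[neg, 2] = self.tets[neg, 2], self.tets[neg, 1]
            self.tets = t
            vol = tet_volumes(self.nodes, self.tets)
        if np.any(vol <= 0):
            raise ValueError("mesh contains degenerate (zero-volume) tetrahedra")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def node_volumes(self) -> np.ndarray:
        """Lumped nodal volumes (¼ of each incident tet), mm³."""
        if self._node_volumes is None:
            vol = tet_volumes(self.nodes, self.tets)
            nv = np.zeros(self.n_nodes)
            np.add.at(nv, self.tets.ravel(), np.repeat(vol / 4.0, 4))
            self._node_volumes = nv
        return self._node_volumes

    @property
    def total_volume(self) -> float:
        return float(tet_volumes(self.nodes, self.tets).sum())

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected mesh edges, (M, 2) int array."""
        if self._edges is None:
            t = self.tets
            pairs = np.vstack([t[:, [a, b]] for a, b in
                               ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))])
            pairs.sort(axis=1)
            self._edges = np.unique(pairs, axis=0)
        return self._edges

    def surface_nodes(self, tag: str) -> np.ndarray:
        """Sorted unique node indices of a tagged surface."""
        if tag not in self.surface_tags:
            raise KeyError(f"surface tag {tag!r} not present "
                           f"(found: {sorted(self.surface_tags)})")
        return np.unique(np.asarray(self.surface_tags[tag], dtype=np.int64))

    def require_transmural(self) -> np.ndarray:
        if self.transmural is None:
            self.transmural = compute_transmural_coordinate(self)
        return self.transmural


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes (positive for correct orientation), mm³."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def _hex_to_tets(corners):
    """Split a hexahedron (VTK corner order) into 6 tets around diagonal 0–6.

    Every quad face is split along the diagonal through the cell's corner 0
    or 6, which is the *same* spatial diagonal for the two cells sharing the
    face on a uniformly labeled structured grid — the decomposition is
    face-consistent and the union of tets tiles the grid without internal
    facet mismatches.
    """
    c = corners
    return [
        (c[0], c[1], c[2], c[6]), (c[0], c[2], c[3], c[6]),
        (c[0], c[3], c[7], c[6]), (c[0], c[7], c[4], c[6]),
        (c[0], c[4], c[5], c[6]), (c[0], c[5], c[1], c[6]),
    ]


def _boundary_facets(tets: np.ndarray) -> np.ndarray:
    """Facets appearing in exactly one tet, as (F, 3) node triples."""
    faces = np.vstack([tets[:, idx] for idx in
                       ((0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3))])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def generate_idealized_wall(shape: str = "slab", dimensions=None, h: float = 1.5,
                            seed: int = 0) -> WallMesh:
    """Generate an idealized ventricular-wall mesh.

    Parameters
    ----------
    shape : ``"slab"`` or ``"half_ellipsoid_shell"``.
    dimensions :
        slab — ``(Lx, Ly, thickness)`` in mm; the endocardium is the z = 0
        face, the epicardium the z = thickness face, the four lateral faces
        form the base.
        shell — ``(a, b, c, thickness)``: inner semi-axes in mm plus wall
        thickness; the z ≤ 0 half-shell is meshed, the z = 0 annulus is the
        base.
    h : target edge length, mm.
    seed : kept for interface stability; the generators are deterministic.
    """
    if h <= 0:
        raise ValueError(f"mesh size h must be positive, got {h}")
    if shape == "slab":
        if dimensions is None:
            dimensions = (20.0, 20.0, 10.0)
        return _generate_slab(dimensions, h)
    if shape == "half_ellipsoid_shell":
        if dimensions is None:
            dimensions = (20.0, 20.0, 40.0, 10.0)
        return _generate_half_shell(dimensions, h)
    raise ValueError(f"unknown shape {shape!r}; use 'slab' or 'half_ellipsoid_shell'")


def _generate_slab(dimensions, h: float) -> WallMesh:
    lx, ly, lz = (float(d) for d in dimensions)
    if min(lx, ly, lz) <= 0:
        raise ValueError(f"slab dimensions must be positive, got {dimensions}")
    nx, ny, nz = (max(1, round(d / h)) for d in (lx, ly, lz))
    xs, ys, zs = (np.linspace(0, d, n + 1) for d, n in ((lx, nx), (ly, ny), (lz, nz)))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corners = (nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                           nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                           nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1))
                tets.extend(_hex_to_tets(corners))
    tets = np.asarray(tets, dtype=np.int64)

    facets = _boundary_facets(tets)
    cz = nodes[facets].mean(axis=1)[:, 2]
    endo = facets[np.abs(cz) < 1e-12]
    epi = facets[np.abs(cz - lz) < 1e-12]
    base = facets[(np.abs(cz) >= 1e-12) & (np.abs(cz - lz) >= 1e-12)]
    mesh = WallMesh(nodes, tets, {ENDO: endo, EPI: epi, BASE: base})
    mesh.transmural = nodes[:, 2] / lz
    return mesh


def _generate_half_shell(dimensions, h: float) -> WallMesh:
    a, b, c, th = (float(d) for d in dimensions)
    if min(a, b, c, th) <= 0:
        raise ValueError(f"shell dimensions must be positive, got {dimensions}")
    # structured (phi, theta, r) grid on the z <= 0 half-shell, apex at -z
    mean_r = (a + b) / 2.0 + th / 2.0
    n_phi = max(8, round(2 * np.pi * mean_r / h))
    n_theta = max(4, round((np.pi / 2) * (c + th / 2.0) / h))
    n_r = max(2, round(th / h))
    phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    thetas = np.linspace(0.0, np.pi / 2, n_theta + 1)  # 0 = base plane, π/2 = apex
    rs = np.linspace(0.0, 1.0, n_r + 1)  # 0 = endo, 1 = epi

    # node numbering with apex collapse: for theta < π/2 a full ring of n_phi
    # nodes per (theta, r); at theta = π/2 a single node per r
    idx = {}
    coords = []
    for it, th_ang in enumerate(thetas):
        apex = it == n_theta
        for ir, r in enumerate(rs):
            ai, bi, ci = a + r * th, b + r * th, c + r * th
            if apex:
                idx[(it, 0, ir)] = len(coords)
                coords.append((0.0, 0.0, -ci))
            else:
                ct, st = np.cos(th_ang), np.sin(th_ang)
                for ip, ph in enumerate(phis):
                    idx[(it, ip, ir)] = len(coords)
                    coords.append((ai * ct * np.cos(ph), bi * ct * np.sin(ph),
                                   -ci * st))
    nodes = np.asarray(coords)

    def node(it, ip, ir):
        if it == n_theta:
            return idx[(it, 0, ir)]
        return idx[(it, ip % n_phi, ir)]

    tets = []
    for it in range(n_theta):
        for ip in range(n_phi):
            for ir in range(n_r):
                corners = (node(it, ip, ir), node(it, ip + 1, ir),
                           node(it + 1, ip + 1, ir), node(it + 1, ip, ir),
                           node(it, ip, ir + 1), node(it, ip + 1, ir + 1),
                           node(it + 1, ip + 1, ir + 1), node(it + 1, ip, ir + 1))
                for t in _hex_to_tets(corners):
                    if len(set(t)) == 4:
                        tets.append(t)
    tets = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    tets = tets[np.abs(vols) > 1e-12]

    facets = _boundary_facets(tets)
    centers = nodes[facets].mean(axis=1)
    # classify: base facets lie on z = 0; endo/epi by ellipsoidal level of the
    # facet center relative to the mid-surface
    on_base = np.abs(centers[:, 2]) < 1e-9
    r_mid = 0.5
    lev = np.zeros(len(facets))
    for k, fc in enumerate(centers):
        # invert r from |x/a(r)|² + ... = 1 approximately via mid-surface test
        lev[k] = (fc[0] / (a + r_mid * th)) ** 2 + (fc[1] / (b + r_mid * th)) ** 2 \
            + (fc[2] / (c + r_mid * th)) ** 2
    endo = facets[(~on_base) & (lev < 1.0)]
    epi = facets[(~on_base) & (lev >= 1.0)]
    base = facets[on_base]
    return WallMesh(nodes, tets, {ENDO: endo, EPI: epi, BASE: base})


def half_shell_volume(a: float, b: float, c: float, th: float) -> float:
    """Analytic volume of the half-ellipsoid shell (oracle for meshing), mm³."""
    return (2.0 * np.pi / 3.0) * ((a + th) * (b + th) * (c + th) - a * b * c)


def p1_laplacian(mesh: WallMesh, coeff=None) -> sp.csr_matrix:
    """P1 finite-element stiffness matrix ∫ c ∇u·∇v on the mesh (mm units).

    ``coeff`` is an optional per-element scalar field (defaults to 1).
    """
    nodes, tets = mesh.nodes, mesh.tets
    vol = tet_volumes(nodes, tets)
    grads = p1_gradients(nodes, tets)  # (E, 4, 3)
    ke = np.einsum("eik,ejk->eij", grads, grads) * vol[:, None, None]
    if coeff is not None:
        ke = ke * np.asarray(coeff)[:, None, None]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)),
                         shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()


def p1_gradients(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Gradients of the 4 P1 basis functions per tet, (E, 4, 3), units 1/mm."""
    x = nodes[tets]  # (E, 4, 3)
    mat = x[:, 1:, :] - x[:, :1, :]  # (E, 3, 3) rows = edge vectors
    inv = np.linalg.inv(mat)  # columns give ∇λ_1..3
    g123 = np.transpose(inv, (0, 2, 1))  # (E, 3, 3): grad of basis 1..3
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1)


def compute_transmural_coordinate(mesh: WallMesh) -> np.ndarray:
    """Harmonic transmural coordinate λ: 0 on endocardium, 1 on epicardium.

    Solves the Laplace problem with zero-flux conditions on the base.
    """
    endo = mesh.surface_nodes(ENDO)
    epi = mesh.surface_nodes(EPI)
    if endo.size == 0 and epi.size == 0:
        raise ValueError("endocardial and epicardial surfaces must be nonempty")
    n = mesh.n_nodes
    lam = np.zeros(n)
    lam[epi] = 1.0
    overlap = np.intersect1d(endo, epi)
    lam[overlap] = 0.0  # doubly tagged nodes count as endocardial
    fixed = np.union1d(endo, epi)
    free = np.setdiff1d(np.arange(n), fixed)
    if free.size:
        A = p1_laplacian(mesh)
        rhs = -A[free][:, fixed] @ lam[fixed]
        Aff = A[free][:, free].tocsc()
        sol = spla.spsolve(Aff, rhs)
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("transmural Laplace solve failed "
                               "(disconnected surface sets?)")
        lam[free] = sol
    return np.clip(lam, 0.0, 1.0)


def min_dihedral_angle(mesh: WallMesh) -> float:
    """Minimum dihedral angle over all tets, degrees (mesh-quality report)."""
    nodes, tets = mesh.nodes, mesh.tets
    # face normals per tet
    faces = ((0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3))
    normals = []
    for f in faces:
        a = nodes[tets[:, f[1]]] - nodes[tets[:, f[0]]]
        b = nodes[tets[:, f[2]]] - nodes[tets[:, f[0]]]
        nrm = np.cross(a, b)
        normals.append(nrm / np.linalg.norm(nrm, axis=1, keepdims=True))
    worst = 180.0
    for i in range(4):
        for j in range(i + 1, 4):
            cosang = np.clip(-np.einsum("ij,ij->i", normals[i], normals[j]), -1, 1)
            worst = min(worst, float(np.degrees(np.arccos(cosang)).min()))
    return worst
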