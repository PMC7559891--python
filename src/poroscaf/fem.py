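"""Quasi-static Biot poroelastic finite elements on labeled voxel grids.

Discretization: trilinear hexahedral elements with equal-order displacement
and pore-pressure interpolation (3 displacement + 1 pressure unknown per
node).  All elements of a grid are identical cubes, so per-material element
matrices are computed once and scattered.

Unit system: mm - N - s - MPa.  Permeabilities given in m^4/(N s) are
converted to mm^4/(N s) (factor 1e12) when material properties are created.

Coupled system, backward-Euler step of size dt (symmetric indefinite form)::

    [ K    -Q  ] [u_n]   [ f_n                      ]
    [-Q^T -(S+dt H)] [p_n] = [-Q^T u_{n-1} - S p_{n-1}]

with K the elastic stiffness, Q the Biot coupling (coefficient alpha),
S the storage matrix (1/M) and H the permeability (Darcy) matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import LabeledGrid, Phase

__all__ = [
    "MaterialProperties",
    "LoadCase",
    "FEModel",
    "FEMResult",
    "default_materials",
    "build_fe_model",
    "build_column_model",
    "apply_load_case",
    "solve_consolidation",
    "element_strains",
    "darcy_velocities",
    "apparent_modulus",
    "base_reaction",
]

log = logging.getLogger(__name__)

M4_PER_NS_TO_MM4 = 1e12  # 1 m^4/(N s) = 1e12 mm^4/(N s)
MM_PER_S_TO_UM_PER_S = 1e3

#: stiffness ratio of the soft pore filler used in bare-scaffold (solid_only)
#: models; keeps coarse voxelizations with floating solid clusters solvable
#: while adding < 0.1% to the apparent stiffness of connected structures
VOID_CONTRAST = 1e-3


@dataclass(frozen=True)
class MaterialProperties:
    """Poroelastic material constants (mm-N-s-MPa units).

    ``k`` is the hydraulic permeability divided by fluid viscosity, stored in
    mm^4/(N s); use :meth:`from_si_permeability` when quoting m^4/(N s).
    """

    E: float  # Young's modulus, MPa
    nu: float  # Poisson ratio
    k: float  # permeability, mm^4/(N s)
    porosity: float
    K_grain: float  # solid-grain bulk modulus, MPa
    K_fluid: float  # fluid bulk modulus, MPa

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError(f"nu must be in [0, 0.5), got {self.nu}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"porosity must be in (0,1), got {self.porosity}")
        if self.K_grain <= 0 or self.K_fluid <= 0:
            raise ValueError("bulk moduli must be positive")

    @classmethod
    def from_si_permeability(cls, E, nu, k_si, porosity, K_grain, K_fluid):
        return cls(E, nu, k_si * M4_PER_NS_TO_MM4, porosity, K_grain, K_fluid)

    @property
    def K_drained(self) -> float:
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def biot_alpha(self) -> float:
        """Biot effective-stress coefficient, alpha = 1 - K_drained/K_grain."""
        return 1.0 - self.K_drained / self.K_grain

    @property
    def storage(self) -> float:
        """Inverse Biot modulus 1/M = n/K_fluid + (alpha - n)/K_grain, 1/MPa."""
        a = self.biot_alpha
        return self.porosity / self.K_fluid + (a - self.porosity) / self.K_grain

    @property
    def M_confined(self) -> float:
        """Drained constrained (oedometer) modulus, MPa."""
        return self.E * (1.0 - self.nu) / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))

    @property
    def consolidation_coefficient(self) -> float:
        """1-D consolidation coefficient c_v = k M_c / (S M_c + alpha^2), mm^2/s."""
        a = self.biot_alpha
        Mc = self.M_confined
        return self.k * Mc / (self.storage * Mc + a * a)


def default_materials() -> dict:
    """Published material constants for granulation tissue and scaffold."""
    return {
        "granulation": MaterialProperties.from_si_permeability(
            E=0.2, nu=0.167, k_si=1e-14, porosity=0.8, K_grain=2300.0, K_fluid=2300.0
        ),
        "scaffold": MaterialProperties.from_si_permeability(
            E=1000.0, nu=0.3, k_si=1e-14, porosity=0.5, K_grain=13920.0, K_fluid=2300.0
        ),
    }


@dataclass(frozen=True)
class LoadCase:
    """Plate load: mode, magnitude per unit area, and ramp schedule.

    The total plate force magnitude is ``F_UA * L^2``.  The load ramps
    linearly from 0 to full over ``ramp_time`` in ``n_increments`` steps; an
    optional constant-load hold phase of ``hold_time`` in ``n_hold`` steps can
    follow (used to reach the drained state in stiffness benchmarks).
    """

    mode: str = "compression"
    F_UA: float = 0.1  # MPa
    ramp_time: float = 1.0  # s
    n_increments: int = 10
    hold_time: float = 0.0
    n_hold: int = 0

    def __post_init__(self):
        if self.mode not in ("compression", "shear"):
            raise ValueError(f"unknown load mode {self.mode!r}")
        if self.F_UA < 0:
            raise ValueError(f"F_UA must be >= 0, got {self.F_UA}")
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")

    def total_force(self, L: float) -> float:
        return self.F_UA * L * L

    def force_direction(self) -> int:
        """Loaded global axis: z (2) for compression, x (0) for shear."""
        return 2 if self.mode == "compression" else 0

    def schedule(self):
        """(time, load_factor) pairs for each increment."""
        out = []
        dt = self.ramp_time / self.n_increments
        for i in range(1, self.n_increments + 1):
            out.append((i * dt, i / self.n_increments))
        if self.n_hold > 0 and self.hold_time > 0:
            dth = self.hold_time / self.n_hold
            for i in range(1, self.n_hold + 1):
                out.append((self.ramp_time + i * dth, 1.0))
        return out


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

# local node offsets within one voxel; global node id = ravel(ix+dx, iy+dy, iz+dz)
_NODE_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [1, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 1],
    ]
)


def _gauss_points():
    g = 1.0 / math.sqrt(3.0)
    pts = []
    for a in (-g, g):
        for b in (-g, g):
            for c in (-g, g):
                pts.append((a, b, c))
    return pts


def _shape(xi):
    """Trilinear shape values N (8,) and natural gradients dN/dxi (8,3)."""
    s = 2.0 * _NODE_OFFSETS - 1.0  # signs in {-1, +1}
    xi = np.asarray(xi)
    terms = (1.0 + s * xi) / 2.0  # (8,3)
    N = terms.prod(axis=1)
    dN = np.empty((8, 3))
    for d in range(3):
        others = [i for i in range(3) if i != d]
        dN[:, d] = (s[:, d] / 2.0) * terms[:, others[0]] * terms[:, others[1]]
    return N, dN


def _elastic_D(E, nu):
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2.0 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def element_matrices(mat: MaterialProperties, h: float):
    """Element K (24x24), Q (24x8), H (8x8), S (8x8) for a cube of edge h."""
    D = _elastic_D(mat.E, mat.nu)
    alpha = mat.biot_alpha
    Ke = np.zeros((24, 24))
    Qe = np.zeros((24, 8))
    He = np.zeros((8, 8))
    Se = np.zeros((8, 8))
    detJ = (h / 2.0) ** 3  # dx = h/2 dxi
    for xi in _gauss_points():
        N, dNdxi = _shape(xi)
        dNdx = dNdxi * (2.0 / h)  # (8,3)
        B = np.zeros((6, 24))
        for a in range(8):
            bx, by, bz = dNdx[a]
            col = 3 * a
            B[0, col] = bx
            B[1, col + 1] = by
            B[2, col + 2] = bz
            B[3, col] = by
            B[3, col + 1] = bx
            B[4, col + 1] = bz
            B[4, col + 2] = by
            B[5, col] = bz
            B[5, col + 2] = bx
        Ke += B.T @ D @ B * detJ
        # volumetric-strain row: d(u_a,c)/dx_c
        bvol = np.zeros(24)
        for a in range(8):
            bvol[3 * a : 3 * a + 3] = dNdx[a]
        Qe += alpha * np.outer(bvol, N) * detJ
        He += mat.k * (dNdx @ dNdx.T) * detJ
        Se += mat.storage * np.outer(N, N) * detJ
    return Ke, Qe, He, Se


def _centroid_grads(h):
    """Shape gradients dN/dx at the element centroid, (8,3)."""
    _, dNdxi = _shape((0.0, 0.0, 0.0))
    return dNdxi * (2.0 / h)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class ConfigurationError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


@dataclass
class FEModel:
    """Assembled poroelastic voxel model with boundary-condition sets.

    Displacement dofs are numbered ``3*node + comp`` over active nodes, the
    pressure block follows at offset ``3*n_nodes``.  Interface nodes between
    the two materials are shared, which enforces the tie (no relative
    displacement) by construction.
    """

    h: float  # voxel edge, mm
    L: float  # model height, mm
    node_shape: tuple  # (nx+1, ny+1, nz+1) of the full node lattice
    active_nodes: np.ndarray  # lattice ids of active nodes
    node_coords: np.ndarray  # (N,3) coordinates of active nodes, mm
    elem_nodes: np.ndarray  # (ne,8) active-node indices
    elem_mat: np.ndarray  # (ne,) material index into `materials`
    materials: list  # list of MaterialProperties
    material_names: list  # parallel names
    K: sp.csr_matrix
    Q: sp.csr_matrix
    H: sp.csr_matrix
    S: sp.csr_matrix
    fixed_u_dofs: np.ndarray  # displacement dofs with u = 0
    drained_nodes: np.ndarray  # active-node indices with p = 0
    plate_nodes: np.ndarray  # active-node indices tied to the rigid plate
    tie_components: tuple = (0, 1, 2)  # plate-tied displacement components
    load: Optional[LoadCase] = None
    plate_force: Optional[np.ndarray] = None  # (3,) force on the plate reference
    area: float = 0.0  # loaded area, mm^2

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elem_nodes.shape[0]

    @property
    def n_dofs(self) -> int:
        return 4 * self.n_nodes


@dataclass
class FEMResult:
    """Time history of the coupled solution plus mesh metadata for scoring."""

    model: FEModel
    times: np.ndarray  # (nt,)
    displacements: np.ndarray  # (nt, N, 3) mm
    pressures: np.ndarray  # (nt, N) MPa
    plate_displacement: np.ndarray  # (nt, 3) mm, rigid-plate reference

    def __post_init__(self):
        nt = len(self.times)
        if self.displacements.shape[0] != nt or self.pressures.shape[0] != nt:
            raise ValueError("inconsistent time-history lengths")
        if not (np.isfinite(self.displacements).all() and np.isfinite(self.pressures).all()):
            raise NumericalError("non-finite values in solution fields")


def _assemble(grid_labels_flat, elem_nodes_lattice, mat_ids, materials, h, n_lattice):
    """Assemble the K, Q, H, S blocks over the active node set."""
    active = np.unique(elem_nodes_lattice)
    remap = -np.ones(n_lattice, dtype=np.int64)
    remap[active] = np.arange(active.size)
    en = remap[elem_nodes_lattice]  # (ne,8) active-node ids
    N = active.size

    Kb = sp.csr_matrix((3 * N, 3 * N))
    Qb = sp.csr_matrix((3 * N, N))
    Hb = sp.csr_matrix((N, N))
    Sb = sp.csr_matrix((N, N))
    for mid, mat in enumerate(materials):
        sel = np.nonzero(mat_ids == mid)[0]
        if sel.size == 0:
            continue
        Ke, Qe, He, Se = element_matrices(mat, h)
        en_m = en[sel]  # (m,8)
        udofs = (3 * en_m[:, :, None] + np.arange(3)[None, None, :]).reshape(sel.size, 24)
        pdofs = en_m
        Kb = Kb + _scatter(Ke, udofs, udofs, (3 * N, 3 * N))
        Qb = Qb + _scatter(Qe, udofs, pdofs, (3 * N, N))
        Hb = Hb + _scatter(He, pdofs, pdofs, (N, N))
        Sb = Sb + _scatter(Se, pdofs, pdofs, (N, N))
    return active, en, Kb.tocsr(), Qb.tocsr(), Hb.tocsr(), Sb.tocsr()


def _scatter(elem_mat, rows, cols, shape):
    m = rows.shape[0]
    nr, nc = elem_mat.shape
    r = np.broadcast_to(rows[:, :, None], (m, nr, nc)).ravel()
    c = np.broadcast_to(cols[:, None, :], (m, nr, nc)).ravel()
    v = np.broadcast_to(elem_mat[None, :, :], (m, nr, nc)).ravel()
    return sp.coo_matrix((v, (r, c)), shape=shape).tocsr()


def build_fe_model(
    grid: LabeledGrid,
    materials: Optional[dict] = None,
    load: Optional[LoadCase] = None,
    *,
    solid_only: bool = False,
    plate_tie: str = "all",
    base: str = "encastre",
) -> FEModel:
    """Build the poroelastic model from a labeled voxel grid.

    Boundary conditions follow the published setup: encastre (all displacement
    components fixed) on the base ``z = 0``; all top-face nodes tied to a rigid
    loading plate; pore pressure fixed to zero on exterior granulation faces of
    the four lateral sides and the bottom (the top face under the plate is
    sealed).

    ``solid_only`` drops the granulation elements (used for apparent-modulus
    runs of the bare scaffold); in that mode every exterior face except the top
    is drained.  ``plate_tie`` is ``"all"`` (rigid plate, all components) or
    ``"normal"`` (load-direction component only; uniaxial benchmarks).
    ``base`` is ``"encastre"`` or ``"roller"`` (z only).
    """
    if materials is None:
        materials = default_materials()
    labels = grid.labels
    present = np.unique(labels)
    if not solid_only and present.size < 2:
        raise ConfigurationError(
            "grid contains a single material; a scaffold/granulation bi-material "
            "grid is required (use solid_only=True for bare-scaffold runs)"
        )

    nx, ny, nz = labels.shape
    node_shape = (nx + 1, ny + 1, nz + 1)
    n_lattice = node_shape[0] * node_shape[1] * node_shape[2]

    if solid_only:
        # Pores carry a very soft "void" filler (stiffness contrast
        # VOID_CONTRAST) instead of being removed: voxelization can lose
        # sub-voxel solid slivers and leave floating clusters, which would
        # make the pure-solid system singular.  The filler's stiffness is
        # negligible against both scaffold and granulation tissue.
        ex, ey, ez = np.nonzero(np.ones_like(labels, dtype=bool))
        scaf = materials["scaffold"]
        void = MaterialProperties(
            E=scaf.E * VOID_CONTRAST,
            nu=scaf.nu,
            k=materials.get("granulation", scaf).k if isinstance(materials, dict) else scaf.k,
            porosity=0.8,
            K_grain=scaf.K_grain,
            K_fluid=scaf.K_fluid,
        )
        mat_names = ["void", "scaffold"]
        mats = [void, scaf]
        mat_ids = (labels[ex, ey, ez] == Phase.SCAFFOLD).astype(np.int64)
    else:
        ex, ey, ez = np.nonzero(np.ones_like(labels, dtype=bool))
        mat_names = ["granulation", "scaffold"]
        mats = [materials["granulation"], materials["scaffold"]]
        mat_ids = (labels[ex, ey, ez] == Phase.SCAFFOLD).astype(np.int64)
    if ex.size == 0:
        raise ConfigurationError("no active elements in grid")

    elem_nodes_lattice = _element_node_ids(ex, ey, ez, node_shape)
    h = grid.voxel_size
    active, en, K, Q, H, S = _assemble(None, elem_nodes_lattice, mat_ids, mats, h, n_lattice)

    iz = active % node_shape[2]
    rem = active // node_shape[2]
    iy = rem % node_shape[1]
    ix = rem // node_shape[1]
    coords = np.stack([ix, iy, iz], axis=1).astype(float) * h

    bottom = np.nonzero(iz == 0)[0]
    top = np.nonzero(iz == nz)[0]

    if base == "encastre":
        fixed_u = (3 * bottom[:, None] + np.arange(3)[None, :]).ravel()
    elif base == "roller":
        fixed_u = 3 * bottom + 2
    else:
        raise ValueError(f"unknown base condition {base!r}")

    drained = _drained_nodes(
        labels, ex, ey, ez, elem_nodes_lattice, active, node_shape, solid_only, mat_ids
    )

    if plate_tie == "all":
        tie_components = (0, 1, 2)
    elif plate_tie == "normal":
        d = load.force_direction() if load is not None else 2
        tie_components = (d,)
    else:
        raise ValueError(f"unknown plate_tie {plate_tie!r}")

    model = FEModel(
        h=h,
        L=nz * h,
        node_shape=node_shape,
        active_nodes=active,
        node_coords=coords,
        elem_nodes=en,
        elem_mat=mat_ids,
        materials=mats,
        material_names=mat_names,
        K=K,
        Q=Q,
        H=H,
        S=S,
        fixed_u_dofs=np.asarray(fixed_u, dtype=np.int64),
        drained_nodes=drained,
        plate_nodes=top,
        tie_components=tie_components,
        area=(nx * h) * (ny * h),
    )
    if load is not None:
        apply_load_case(model, load)
    return model


def _element_node_ids(ex, ey, ez, node_shape):
    """(ne,8) lattice node ids for voxel elements at indices (ex, ey, ez)."""
    sy, sz = node_shape[1] * node_shape[2], node_shape[2]

    def nid(ax, ay, az):
        return ax * sy + ay * sz + az

    cols = [
        nid(ex + dx, ey + dy, ez + dz) for dx, dy, dz in _NODE_OFFSETS
    ]
    return np.stack(cols, axis=1).astype(np.int64)


def _drained_nodes(labels, ex, ey, ez, elem_lat, active, node_shape, solid_only, mat_ids):
    """Active-node indices carrying p = 0 (free fluid exudation).

    Exterior faces of granulation elements on the four lateral sides and the
    bottom are drained; the top face (under the impermeable plate) is sealed.
    Scaffold-labeled exterior faces carry no drainage condition.
    """
    nx, ny, nz = labels.shape
    remap = -np.ones(node_shape[0] * node_shape[1] * node_shape[2], dtype=np.int64)
    remap[active] = np.arange(active.size)

    if solid_only:
        drain_elem = np.ones(ex.size, dtype=bool)
    else:
        drain_elem = mat_ids == 0  # granulation elements

    # (face-selector, local node ids of that face) for the 5 drained sides
    # local node order per _NODE_OFFSETS
    faces = [
        (ex == 0, [0, 2, 4, 6]),  # x = 0
        (ex == nx - 1, [1, 3, 5, 7]),  # x = L
        (ey == 0, [0, 1, 4, 5]),  # y = 0
        (ey == ny - 1, [2, 3, 6, 7]),  # y = L
        (ez == 0, [0, 1, 2, 3]),  # z = 0 (bottom)
    ]
    ids = []
    for on_face, local in faces:
        sel = np.nonzero(on_face & drain_elem)[0]
        if sel.size:
            ids.append(elem_lat[np.ix_(sel, local)].ravel())
    if not ids:
        return np.empty(0, dtype=np.int64)
    lat = np.unique(np.concatenate(ids))
    return np.unique(remap[lat])


def apply_load_case(model: FEModel, load: LoadCase) -> FEModel:
    """Attach the load case: total plate force ``F_UA * L^2`` along the loaded axis.

    Compression pushes the plate down (-z); shear drags it along +x.
    """
    F = load.F_UA * model.area
    f = np.zeros(3)
    if load.mode == "compression":
        f[2] = -F
    else:
        f[0] = +F
    model.load = load
    model.plate_force = f
    if model.tie_components != (0, 1, 2):
        d = load.force_direction()
        if d not in model.tie_components:
            raise ConfigurationError(
                f"plate ties components {model.tie_components} but the load acts along axis {d}"
            )
    return model


#: free-dof count above which the Schur-complement CG path replaces splu
#: (SuperLU fill-in grows pathologically on these 27-point voxel stencils)
DIRECT_SOLVER_MAX_DOFS = 6_000


def _tie_transform_u(model: FEModel):
    """Master-slave transform on the displacement block only.

    Returns ``(Pu, n_red_u, master_cols)``: ``u_full = Pu @ u_red`` with the
    plate-tied dofs of each tied component collapsed onto one master column
    (appended at the end).
    """
    N = model.n_nodes
    nu = 3 * N
    tied = model.tie_components
    slave_dofs = {c: (3 * model.plate_nodes + c) for c in tied}
    slave = np.zeros(nu, dtype=bool)
    for c in tied:
        slave[slave_dofs[c]] = True
    keep = np.nonzero(~slave)[0]
    col_of = -np.ones(nu, dtype=np.int64)
    col_of[keep] = np.arange(keep.size)
    master_cols = {c: keep.size + j for j, c in enumerate(tied)}
    n_red = keep.size + len(tied)

    rows = [keep]
    cols = [col_of[keep]]
    for c in tied:
        rows.append(slave_dofs[c])
        cols.append(np.full(slave_dofs[c].size, master_cols[c], dtype=np.int64))
    Pu = sp.coo_matrix(
        (np.ones(sum(r.size for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nu, n_red),
    ).tocsr()
    # reduced indices of Dirichlet-fixed u dofs (identity-mapped; never slaves)
    fixed_red = col_of[model.fixed_u_dofs]
    if np.any(fixed_red < 0):
        raise ConfigurationError("a fixed displacement dof is plate-tied; BC sets overlap")
    return Pu, n_red, master_cols, fixed_red


class _DirectStep:
    """One backward-Euler step operator: monolithic symmetric-indefinite splu."""

    def __init__(self, K, Q, C):
        A = sp.bmat([[K, -Q], [-Q.T, -C]], format="csc")
        try:
            self.lu = spla.splu(A, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:  # pragma: no cover
            raise NumericalError(f"sparse factorization failed: {exc}") from exc
        self.A = A
        self.nu = K.shape[0]

    def solve(self, b1, b2, x0=None, rtol=1e-10):
        b = np.concatenate([b1, b2])
        x = self.lu.solve(b)
        resid = np.linalg.norm(self.A @ x - b)
        scale = np.linalg.norm(b)
        if scale > 0 and resid > max(1e4 * rtol * scale, 1e-8):
            raise NumericalError(f"direct solve residual {resid:.3e} (rhs {scale:.3e})")
        return x[: self.nu], x[self.nu :]


class _SchurCGStep:
    """One backward-Euler step via pressure elimination.

    The pressure block ``C = S + dt H`` is factorized directly (it is small
    and Laplacian-like); the SPD displacement Schur complement
    ``K + Q C^-1 Q^T`` is solved with Jacobi-preconditioned CG.
    """

    def __init__(self, K, Q, C):
        self.K = K.tocsr()
        self.Q = Q.tocsr()
        self.QT = Q.T.tocsr()
        self.C_lu = spla.splu(C.tocsc(), permc_spec="MMD_AT_PLUS_A")
        nu = K.shape[0]
        dC = C.diagonal()
        diag = K.diagonal() + (self.Q.multiply(self.Q) @ (1.0 / dC))
        diag[diag <= 0] = 1.0
        self.Minv = 1.0 / diag
        self.op = spla.LinearOperator((nu, nu), matvec=self._matvec)
        self.prec = spla.LinearOperator((nu, nu), matvec=lambda r: self.Minv * r)

    def _matvec(self, u):
        return self.K @ u + self.Q @ self.C_lu.solve(self.QT @ u)

    def solve(self, b1, b2, x0=None, rtol=1e-10):
        # second block row: -Q^T u - C p = b2  ->  p = -C^-1 (b2 + Q^T u)
        rhs = b1 - self.Q @ self.C_lu.solve(b2)
        scale = np.linalg.norm(rhs)
        if scale == 0.0:
            nu = self.K.shape[0]
            return np.zeros(nu), -self.C_lu.solve(b2)
        u, info = spla.cg(
            self.op, rhs, x0=x0, rtol=rtol, atol=0.0, maxiter=20000, M=self.prec
        )
        if info != 0:
            raise NumericalError(f"Schur CG failed to converge (info={info})")
        p = -self.C_lu.solve(b2 + self.QT @ u)
        return u, p


def solve_consolidation(model: FEModel, rtol: float = 1e-10) -> FEMResult:
    """Backward-Euler time stepping of the coupled Biot system.

    The step operator (constant while dt is constant) is factorized once and
    reused.  Systems up to ``DIRECT_SOLVER_MAX_DOFS`` free dofs use a sparse
    direct factorization; larger ones use the Schur-complement CG path with
    relative tolerance ``rtol``.  The final increment is the scoring state.
    """
    if model.load is None:
        raise ConfigurationError("no load case applied; call apply_load_case first")
    N = model.n_nodes

    Pu, n_red_u, master_cols, fixed_red = _tie_transform_u(model)
    free_u_mask = np.ones(n_red_u, dtype=bool)
    free_u_mask[fixed_red] = False
    free_u = np.nonzero(free_u_mask)[0]
    free_p_mask = np.ones(N, dtype=bool)
    if model.drained_nodes.size:
        free_p_mask[model.drained_nodes] = False
    free_p = np.nonzero(free_p_mask)[0]

    K_red = (Pu.T @ model.K @ Pu).tocsr()
    Q_red = (Pu.T @ model.Q).tocsr()
    K_ff = K_red[free_u][:, free_u]
    Q_ff = Q_red[free_u][:, free_p]
    S_ff = model.S[free_p][:, free_p]
    H_ff = model.H[free_p][:, free_p]
    QT_red = Q_red.T.tocsr()

    # reduced force vector: plate master entries carry the total plate force
    f_red = np.zeros(n_red_u)
    for c, col in master_cols.items():
        f_red[col] = model.plate_force[c]
    f_ff = f_red[free_u]
    master_free_pos = {}
    pos_of = -np.ones(n_red_u, dtype=np.int64)
    pos_of[free_u] = np.arange(free_u.size)
    for c, col in master_cols.items():
        master_free_pos[c] = int(pos_of[col])

    n_free = free_u.size + free_p.size
    step_cache = {}

    schedule = model.load.schedule()
    nt = len(schedule)
    u_red = np.zeros(n_red_u)
    p_full = np.zeros(N)
    disp_hist = np.zeros((nt + 1, N, 3))
    pres_hist = np.zeros((nt + 1, N))
    plate_hist = np.zeros((nt + 1, 3))

    u_warm = None
    t_prev = 0.0
    for step, (t, lam) in enumerate(schedule, start=1):
        dt = t - t_prev
        t_prev = t
        key = round(dt, 12)
        if key not in step_cache:
            C_ff = (S_ff + dt * H_ff).tocsc()
            if n_free <= DIRECT_SOLVER_MAX_DOFS:
                step_cache[key] = _DirectStep(K_ff, Q_ff, C_ff)
            else:
                log.debug("using Schur-CG step operator for %d free dofs", n_free)
                step_cache[key] = _SchurCGStep(K_ff, Q_ff, C_ff)
        op = step_cache[key]

        b1 = lam * f_ff
        b2_full = -(QT_red @ u_red)[free_p] - (S_ff @ p_full[free_p])
        uf, pf = op.solve(b1, b2_full, x0=u_warm, rtol=rtol)
        u_warm = uf

        u_red = np.zeros(n_red_u)
        u_red[free_u] = uf
        p_full = np.zeros(N)
        p_full[free_p] = pf

        disp_hist[step] = (Pu @ u_red).reshape(N, 3)
        pres_hist[step] = p_full
        for c, col in master_cols.items():
            plate_hist[step, c] = u_red[col]

    times = np.array([t for t, _ in schedule])
    return FEMResult(
        model=model,
        times=np.concatenate([[0.0], times]),
        displacements=disp_hist,
        pressures=pres_hist,
        plate_displacement=plate_hist,
    )


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def element_strains(result: FEMResult, increment: int = -1) -> np.ndarray:
    """Small-strain tensors at element centroids, Voigt order
    ``[exx, eyy, ezz, gxy, gyz, gxz]`` (engineering shears), shape (ne, 6)."""
    model = result.model
    u = result.displacements[increment]  # (N,3)
    dNdx = _centroid_grads(model.h)  # (8,3)
    ue = u[model.elem_nodes]  # (ne,8,3)
    grad = np.einsum("eai,aj->eij", ue, dNdx)  # (ne,3,3) du_i/dx_j
    eps = np.empty((model.n_elements, 6))
    eps[:, 0] = grad[:, 0, 0]
    eps[:, 1] = grad[:, 1, 1]
    eps[:, 2] = grad[:, 2, 2]
    eps[:, 3] = grad[:, 0, 1] + grad[:, 1, 0]
    eps[:, 4] = grad[:, 1, 2] + grad[:, 2, 1]
    eps[:, 5] = grad[:, 0, 2] + grad[:, 2, 0]
    return eps


def darcy_velocities(result: FEMResult, increment: int = -1) -> np.ndarray:
    """Darcy flux vectors v = -k grad(p) at element centroids, in um/s, (ne, 3)."""
    model = result.model
    p = result.pressures[increment]
    dNdx = _centroid_grads(model.h)
    pe = p[model.elem_nodes]  # (ne,8)
    gradp = pe @ dNdx  # (ne,3) MPa/mm = N/mm^3
    k = np.array([m.k for m in model.materials])[model.elem_mat]  # mm^4/(N s)
    v_mm_s = -k[:, None] * gradp
    return v_mm_s * MM_PER_S_TO_UM_PER_S


def apparent_modulus(result: FEMResult, F_UA: float, L: float) -> float:
    """Apparent stiffness ``E_app = F_UA * L / |u2|`` from the final plate
    displacement along the loading axis (MPa)."""
    d = result.model.load.force_direction()
    u2 = abs(result.plate_displacement[-1, d])
    if u2 == 0.0:
        raise NumericalError("zero plate displacement; apparent modulus undefined")
    return F_UA * L / u2


def base_reaction(result: FEMResult, increment: int = -1) -> np.ndarray:
    """Total reaction force (3,) transmitted through the fixed base dofs, N.

    Computed as the residual of the equilibrium block at the constrained dofs:
    r = K u - Q p restricted to the base."""
    model = result.model
    u = result.displacements[increment].ravel()
    p = result.pressures[increment]
    r = model.K @ u - model.Q @ p
    out = np.zeros(3)
    for dof in model.fixed_u_dofs:
        out[dof % 3] += r[dof]
    return out


# ---------------------------------------------------------------------------
# 1-D consolidation column (validation fixture)
# ---------------------------------------------------------------------------


def build_column_model(
    material: MaterialProperties,
    n_elements: int,
    height: float,
    F_UA: float,
    n_increments: int = 40,
    t_end: Optional[float] = None,
) -> FEModel:
    """Laterally confined single-material column, loaded in step compression
    through a permeable platen and drained at the top only.

    Boundary conditions reproduce the classical 1-D consolidation problem:
    all lateral displacements fixed, base z fixed, top nodes tied (normal
    component) to the loaded platen, p = 0 at the top surface.
    """
    h = height / n_elements
    labels = np.zeros((1, 1, n_elements), dtype=np.uint8)  # single material
    node_shape = (2, 2, n_elements + 1)
    n_lattice = 4 * (n_elements + 1)
    ez = np.arange(n_elements)
    ex = np.zeros(n_elements, dtype=np.int64)
    ey = np.zeros(n_elements, dtype=np.int64)
    elem_lat = _element_node_ids(ex, ey, ez, node_shape)
    mat_ids = np.zeros(n_elements, dtype=np.int64)
    active, en, K, Q, H, S = _assemble(None, elem_lat, mat_ids, [material], h, n_lattice)

    iz = active % node_shape[2]
    rem = active // node_shape[2]
    iy = rem % node_shape[1]
    ix = rem // node_shape[1]
    coords = np.stack([ix, iy, iz], axis=1).astype(float) * h

    N = active.size
    # confined: u_x = u_y = 0 everywhere; u_z = 0 at base
    fixed = [3 * np.arange(N), 3 * np.arange(N) + 1]
    bottom = np.nonzero(iz == 0)[0]
    fixed.append(3 * bottom + 2)
    fixed_u = np.unique(np.concatenate(fixed))
    top = np.nonzero(iz == n_elements)[0]

    if t_end is None:
        cv = material.consolidation_coefficient
        t_end = 0.6 * height * height / cv
    dt = t_end / n_increments
    load = LoadCase(
        mode="compression",
        F_UA=F_UA,
        ramp_time=dt,  # full load on after the first increment (step load)
        n_increments=1,
        hold_time=t_end - dt,
        n_hold=n_increments - 1,
    )

    model = FEModel(
        h=h,
        L=height,
        node_shape=node_shape,
        active_nodes=active,
        node_coords=coords,
        elem_nodes=en,
        elem_mat=mat_ids,
        materials=[material],
        material_names=["column"],
        K=K,
        Q=Q,
        H=H,
        S=S,
        fixed_u_dofs=fixed_u,
        drained_nodes=top,
        plate_nodes=top,
        tie_components=(2,),
        area=h * h,
    )
    apply_load_case(model, load)
    return model


def terzaghi_pressure(
    material: MaterialProperties,
    z: np.ndarray,
    t: float,
    height: float,
    sigma0: float,
    n_terms: int = 200,
) -> np.ndarray:
    """Closed-form 1-D consolidation pressure profile (drainage at z = height).

    Initial (undrained) pressure ``p0 = alpha sigma0 / (S M_c + alpha^2)``
    decays by the classical Fourier series in ``Tv = c_v t / H^2``; depth is
    measured from the drained surface.
    """
    a = material.biot_alpha
    Mc = material.M_confined
    Ssto = material.storage
    p0 = a * sigma0 / (Ssto * Mc + a * a)
    cv = material.consolidation_coefficient
    H = height
    Tv = cv * t / (H * H)
    zdrain = H - np.asarray(z, dtype=float)  # distance below the drained face
    series = np.zeros_like(zdrain)
    for m in range(n_terms):
        Mm = math.pi * (2 * m + 1) / 2.0
        series += (2.0 / Mm) * np.sin(Mm * zdrain / H) * math.exp(-(Mm**2) * Tv)
    return p0 * series
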