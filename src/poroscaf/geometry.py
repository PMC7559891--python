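"""Parametric spherical-pore unit-cell geometry and voxelization.

The unit cell is a cube of edge ``Luc`` from which a centered sphere of
diameter ``Ds`` and three axis-aligned centered cylinders of diameter ``Dc``
are subtracted.  Pores are assumed to be filled with granulation tissue, so a
voxelized model carries exactly two labels: scaffold solid and granulation.

Two constraint dialects are supported for the cylinder-diameter upper bound:

``as_printed``
    ``Dc <= Ds/2`` for both topologies (the published constraint table).
``derived``
    ``Dc <= Ds/sqrt(2)`` (the bound implied by the inscribed-square
    construction; several published example geometries satisfy only this one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "Phase",
    "Topology",
    "UnitCellSpec",
    "ScaffoldSpec",
    "LabeledGrid",
    "ValidationReport",
    "classify_topology",
    "chord_length",
    "validate_cell",
    "phase_at_point",
    "build_unit_cell",
    "assemble_scaffold",
    "volume_fraction",
]

log = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)

#: default memory cap for assembled grids (voxel count)
MAX_VOXELS = 2**27


class Phase(IntEnum):
    """Voxel label: granulation tissue (pore filling) or scaffold solid."""

    GRANULATION = 0
    SCAFFOLD = 1


class Topology(Enum):
    S = "S"
    L = "L"
    INVALID = "invalid"


class ConstraintError(ValueError):
    """Raised when a geometry spec violates its coherence constraints."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid unit-cell spec: " + "; ".join(self.violations))


class ResourceError(RuntimeError):
    """Raised when a requested grid would exceed the configured memory cap."""


def classify_topology(Ds: float, Luc: float) -> Topology:
    """Classify the unit-cell topology from the sphere diameter.

    ``S`` ("small"): ``0 < Ds <= Luc``; ``L`` ("large"): ``Luc < Ds <= 2*Luc``.
    Anything above ``2*Luc`` yields ``Topology.INVALID``.
    """
    if Ds <= 0 or Luc <= 0:
        raise ValueError(f"Ds and Luc must be positive, got Ds={Ds}, Luc={Luc}")
    if Ds <= Luc:
        return Topology.S
    if Ds <= 2.0 * Luc:
        return Topology.L
    return Topology.INVALID


def chord_length(Ds: float, Luc: float) -> float:
    """Chord of the sphere cut by the cube face: ``C = sqrt(Ds^2 - Luc^2)``.

    Defined only for topology L (``Ds > Luc``); for smaller spheres the
    spherical surface does not reach the face and the chord does not exist.
    """
    if Ds <= 0 or Luc <= 0:
        raise ValueError(f"Ds and Luc must be positive, got Ds={Ds}, Luc={Luc}")
    if Ds < Luc:
        raise ValueError(
            f"chord undefined for Ds={Ds} <= Luc={Luc} (topology S: sphere does not reach the face)"
        )
    return math.sqrt(max(Ds * Ds - Luc * Luc, 0.0))


@dataclass(frozen=True)
class UnitCellSpec:
    """Parametric unit cell: cube edge ``Luc``, sphere ``Ds``, cylinders ``Dc`` (mm)."""

    Luc: float
    Ds: float
    Dc: float
    constraint_dialect: str = "as_printed"

    def __post_init__(self):
        if self.Luc <= 0 or self.Ds <= 0 or self.Dc <= 0:
            raise ValueError(
                f"all dimensions must be positive: Luc={self.Luc}, Ds={self.Ds}, Dc={self.Dc}"
            )
        if self.Ds > 2.0 * self.Luc * (1.0 + 1e-12):
            raise ValueError(
                f"Ds={self.Ds} exceeds 2*Luc={2 * self.Luc}: sphere diameters above "
                "twice the cell edge are not allowed"
            )
        if self.constraint_dialect not in ("as_printed", "derived"):
            raise ValueError(f"unknown constraint dialect {self.constraint_dialect!r}")

    @property
    def topology(self) -> Topology:
        return classify_topology(self.Ds, self.Luc)

    def dc_upper_bound(self) -> float:
        """Upper bound on Dc under the active dialect."""
        if self.constraint_dialect == "as_printed":
            return self.Ds / 2.0
        return self.Ds / _SQRT2


@dataclass(frozen=True)
class ScaffoldSpec:
    """Full scaffold: cube of edge ``L`` tiled by ``cells_per_side**3`` unit cells."""

    cell: UnitCellSpec
    L: float = 2.548
    cells_per_side: int = 4

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError(f"L must be positive, got {self.L}")
        if self.cells_per_side < 1:
            raise ValueError(f"cells_per_side must be >= 1, got {self.cells_per_side}")
        if not math.isclose(self.L, self.cells_per_side * self.cell.Luc, rel_tol=1e-9):
            raise ValueError(
                f"L={self.L} != cells_per_side*Luc={self.cells_per_side * self.cell.Luc}"
            )

    @classmethod
    def create(
        cls,
        Ds: float,
        Dc: float,
        L: float = 2.548,
        cells_per_side: int = 4,
        constraint_dialect: str = "as_printed",
    ) -> "ScaffoldSpec":
        cell = UnitCellSpec(
            Luc=L / cells_per_side, Ds=Ds, Dc=Dc, constraint_dialect=constraint_dialect
        )
        return cls(cell=cell, L=L, cells_per_side=cells_per_side)

    @property
    def Vtot(self) -> float:
        return self.L**3

    @property
    def n_cells(self) -> int:
        return self.cells_per_side**3


@dataclass
class ValidationReport:
    valid: bool
    violations: list = field(default_factory=list)

    def __bool__(self):
        return self.valid


def validate_cell(spec: UnitCellSpec) -> ValidationReport:
    """Check the coherence constraints on (Ds, Dc) for the cell's topology.

    Topology S requires ``0 < Dc <= bound``; topology L additionally requires
    ``Dc`` to exceed the face chord ``sqrt(Ds^2 - Luc^2)`` so that the
    cylindrical openings swallow the spherical caps protruding through the
    faces.  ``bound`` is ``Ds/2`` (as_printed) or ``Ds/sqrt(2)`` (derived).
    """
    violations = []
    topo = spec.topology
    if topo is Topology.INVALID:
        violations.append(f"Ds={spec.Ds} > 2*Luc={2 * spec.Luc}")
        return ValidationReport(False, violations)

    bound = spec.dc_upper_bound()
    bound_name = "Ds/2" if spec.constraint_dialect == "as_printed" else "Ds/sqrt(2)"
    if spec.Dc > bound * (1.0 + 1e-12):
        violations.append(f"Dc={spec.Dc} > {bound_name}={bound:.6g}")
    if topo is Topology.L:
        C = chord_length(spec.Ds, spec.Luc)
        if spec.Dc <= C * (1.0 - 1e-12):
            violations.append(
                f"Dc={spec.Dc} <= chord sqrt(Ds^2-Luc^2)={C:.6g} (topology L lower bound)"
            )
    return ValidationReport(not violations, violations)


def _pore_membership(points: np.ndarray, spec: UnitCellSpec) -> np.ndarray:
    """Vectorized pore membership for points in cell-centered coordinates.

    ``points``: (..., 3) array with coordinates in [-Luc/2, Luc/2].
    Returns a boolean array: True where the point lies in the pore (sphere or
    any of the three axis-aligned cylinders).
    """
    p = np.asarray(points, dtype=float)
    r_s = spec.Ds / 2.0
    r_c = spec.Dc / 2.0
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    in_sphere = x * x + y * y + z * z <= r_s * r_s
    rc2 = r_c * r_c
    in_cyl_x = y * y + z * z <= rc2
    in_cyl_y = x * x + z * z <= rc2
    in_cyl_z = x * x + y * y <= rc2
    return in_sphere | in_cyl_x | in_cyl_y | in_cyl_z


def phase_at_point(p, spec: UnitCellSpec) -> Phase:
    """Phase of a single point given in cell-centered coordinates (mm).

    Returns ``Phase.GRANULATION`` for pore points (inside the sphere or a
    cylinder) and ``Phase.SCAFFOLD`` otherwise.  The point must lie inside the
    cell cube ``[-Luc/2, Luc/2]^3``.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {p.shape}")
    half = spec.Luc / 2.0 * (1.0 + 1e-12)
    if np.any(np.abs(p) > half):
        raise ValueError(f"point {p.tolist()} lies outside the cell cube of edge {spec.Luc}")
    return Phase.GRANULATION if bool(_pore_membership(p, spec)) else Phase.SCAFFOLD


@dataclass
class LabeledGrid:
    """Voxelized scaffold model over the cube ``[0, L]^3``.

    ``labels`` holds one :class:`Phase` value per voxel, indexed ``[ix, iy, iz]``
    with the origin at the cube's lower corner and z the loading axis.
    """

    labels: np.ndarray
    voxel_size: float
    resolution: int  # voxels per unit-cell edge
    cells_per_side: int = 1

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def L(self) -> float:
        return self.labels.shape[0] * self.voxel_size

    @property
    def n_voxels(self) -> int:
        return int(self.labels.size)

    @classmethod
    def full_solid(cls, resolution: int, L: float) -> "LabeledGrid":
        """All-scaffold cube (no pores), used for homogeneous benchmarks."""
        labels = np.full((resolution,) * 3, Phase.SCAFFOLD, dtype=np.uint8)
        return cls(labels=labels, voxel_size=L / resolution, resolution=resolution)


def build_unit_cell(spec: UnitCellSpec, resolution: int) -> LabeledGrid:
    """Voxelize one unit cell by point membership at voxel centers."""
    if resolution < 4:
        raise ValueError(f"resolution must be >= 4, got {resolution}")
    report = validate_cell(spec)
    if not report.valid:
        raise ConstraintError(report.violations)
    return _voxelize_cell(spec, resolution)


def _voxelize_cell(spec: UnitCellSpec, resolution: int) -> LabeledGrid:
    """Voxelization without constraint checking (for constraint-exempt models)."""
    h = spec.Luc / resolution
    # voxel-center coordinates, cell-centered
    c = (np.arange(resolution) + 0.5) * h - spec.Luc / 2.0
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    pore = _pore_membership(pts, spec)
    labels = np.where(pore, np.uint8(Phase.GRANULATION), np.uint8(Phase.SCAFFOLD))
    return LabeledGrid(labels=labels, voxel_size=h, resolution=resolution)


def assemble_scaffold(
    spec: ScaffoldSpec,
    resolution: int,
    max_voxels: int = MAX_VOXELS,
    check_constraints: bool = True,
) -> LabeledGrid:
    """Tile the unit cell ``cells_per_side^3`` times into the full model.

    The unit cell is mirror-symmetric about its three mid-planes, so the
    published mirror-and-replicate assembly is equivalent to plain
    translation-replication; tiling is used here.
    """
    m = spec.cells_per_side
    total = (resolution * m) ** 3
    if total > max_voxels:
        raise ResourceError(
            f"grid of {total} voxels exceeds the cap of {max_voxels}; "
            "lower resolution or raise max_voxels"
        )
    if check_constraints:
        cell_grid = build_unit_cell(spec.cell, resolution)
    else:
        cell_grid = _voxelize_cell(spec.cell, resolution)
    log.debug(
        "assembling %d unit-cell instances by translation-replication "
        "(equivalent to mirroring: the cell is mirror-symmetric about its mid-planes)",
        m**3,
    )
    labels = np.tile(cell_grid.labels, (m, m, m))
    return LabeledGrid(
        labels=labels,
        voxel_size=cell_grid.voxel_size,
        resolution=resolution,
        cells_per_side=m,
    )


def volume_fraction(grid: LabeledGrid) -> float:
    """Solid volume fraction ``Vf = Vs / Vtot`` of a labeled grid."""
    if grid.n_voxels == 0:
        raise ValueError("empty grid")
    return float(np.count_nonzero(grid.labels == Phase.SCAFFOLD) / grid.n_voxels)


def analytic_pore_volume_mc(
    spec: UnitCellSpec, n_samples: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the pore volume fraction of one cell.

    Independent oracle for the voxel volume fraction: uniform random points in
    the cell cube classified by exact point membership.
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-spec.Luc / 2.0, spec.Luc / 2.0, size=(n_samples, 3))
    return float(np.mean(_pore_membership(pts, spec)))
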