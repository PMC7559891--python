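"""CLI, configuration, file output, and deterministic test fixtures.

Subcommands: ``validate``, ``build``, ``solve``, ``optimize``, ``sweep``.
All physical config keys carry units in their names (``L_mm``, ``F_UA_MPa``)
and every run writes a JSON manifest (config hash, seed, package versions) so
a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__, fem, geometry, mechanoreg, optimizer
from .fem import LoadCase, MaterialProperties, default_materials
from .geometry import LabeledGrid, ScaffoldSpec, UnitCellSpec

log = logging.getLogger(__name__)

PHENOTYPE_LEGEND = {
    0: "resorption",
    1: "mature_bone",
    2: "immature_bone",
    3: "cartilage",
    4: "fibrous",
    255: "scaffold (not scored)",
}


@dataclass
class RunConfig:
    """Validated run configuration; defaults reproduce the published setup."""

    L_mm: float = 2.548
    cells_per_side: int = 4
    Ds_mm: float = 0.5
    Dc_mm: float = 0.25
    resolution: int = 8
    constraint_dialect: str = "as_printed"
    mode: str = "compression"
    F_UA_MPa: float = 0.1
    ramp_time_s: float = 1.0
    n_increments: int = 10
    hold_time_s: float = 0.0
    n_hold: int = 0
    stimulus_a: float = 0.0375
    stimulus_b_um_s: float = 3.0
    flow_measure: str = "darcy"
    optimizer_method: str = "derivative_free"
    max_evaluations: int = 120
    xtol_mm: float = 1e-3
    grid_presearch: int = 4
    seed: int = 0
    out_dir: str = "poroscaf_out"
    log_level: str = "INFO"
    materials: dict = field(default_factory=dict)  # per-label overrides

    def __post_init__(self):
        checks = [
            (self.L_mm > 0, "L_mm must be positive"),
            (self.cells_per_side >= 1, "cells_per_side must be >= 1"),
            (self.Ds_mm > 0, "Ds_mm must be positive"),
            (self.Dc_mm > 0, "Dc_mm must be positive"),
            (self.resolution >= 4, "resolution must be >= 4"),
            (self.constraint_dialect in ("as_printed", "derived"), "unknown constraint_dialect"),
            (self.mode in ("compression", "shear"), "mode must be compression or shear"),
            (self.F_UA_MPa >= 0, "F_UA_MPa must be >= 0"),
            (self.n_increments >= 1, "n_increments must be >= 1"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if errors:
            raise ValueError("; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def scaffold_spec(self) -> ScaffoldSpec:
        return ScaffoldSpec.create(
            Ds=self.Ds_mm,
            Dc=self.Dc_mm,
            L=self.L_mm,
            cells_per_side=self.cells_per_side,
            constraint_dialect=self.constraint_dialect,
        )

    def load_case(self) -> LoadCase:
        return LoadCase(
            mode=self.mode,
            F_UA=self.F_UA_MPa,
            ramp_time=self.ramp_time_s,
            n_increments=self.n_increments,
            hold_time=self.hold_time_s,
            n_hold=self.n_hold,
        )

    def material_map(self) -> dict:
        mats = default_materials()
        for label, over in (self.materials or {}).items():
            base = asdict(mats[label]) if label in mats else {}
            base.update(over)
            mats[label] = MaterialProperties(**base)
        return mats

    def stimulus_model(self) -> mechanoreg.StimulusModel:
        return mechanoreg.StimulusModel(
            a=self.stimulus_a, b=self.stimulus_b_um_s, flow_measure=self.flow_measure
        )

    def optimizer_config(self) -> optimizer.OptimizerConfig:
        return optimizer.OptimizerConfig(
            method=self.optimizer_method,
            max_evaluations=self.max_evaluations,
            xtol=self.xtol_mm,
            seed=self.seed,
            resolution=self.resolution,
            constraint_dialect=self.constraint_dialect,
            grid_presearch=self.grid_presearch,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(cfg: RunConfig, out_dir: Path, extra: dict | None = None) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "poroscaf": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# VTK / STL writers
# ---------------------------------------------------------------------------


def _vtk_data_array(name, data, n_components=1):
    arr = np.asarray(data, dtype=np.float32).ravel()
    el = ET.Element(
        "DataArray",
        type="Float32",
        Name=name,
        NumberOfComponents=str(n_components),
        format="ascii",
    )
    el.text = " ".join(f"{v:.9g}" for v in arr)
    return el


def write_image_vtk(path, shape, spacing, cell_fields=None, point_fields=None):
    """Write a VTK XML ImageData (.vti) file with named cell/point arrays.

    ``shape`` is the voxel (cell) count per axis; arrays are flattened in
    x-fastest (VTK) order by the caller or passed as 3-D arrays here.
    """
    nx, ny, nz = shape
    root = ET.Element("VTKFile", type="ImageData", version="1.0", byte_order="LittleEndian")
    img = ET.SubElement(
        root,
        "ImageData",
        WholeExtent=f"0 {nx} 0 {ny} 0 {nz}",
        Origin="0 0 0",
        Spacing=f"{spacing} {spacing} {spacing}",
    )
    piece = ET.SubElement(img, "Piece", Extent=f"0 {nx} 0 {ny} 0 {nz}")

    def _flatten(a, ncomp):
        a = np.asarray(a)
        if ncomp == 1 and a.ndim == 3:
            return np.transpose(a, (2, 1, 0)).ravel()  # VTK is x-fastest
        if ncomp > 1 and a.ndim == 4:
            return np.transpose(a, (2, 1, 0, 3)).reshape(-1, ncomp)
        return a

    if point_fields:
        pd = ET.SubElement(piece, "PointData")
        for name, (data, ncomp) in point_fields.items():
            pd.append(_vtk_data_array(name, _flatten(data, ncomp), ncomp))
    if cell_fields:
        cd = ET.SubElement(piece, "CellData")
        for name, (data, ncomp) in cell_fields.items():
            cd.append(_vtk_data_array(name, _flatten(data, ncomp), ncomp))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="ascii")
    return Path(path)


def read_image_vtk(path):
    """Read back arrays written by :func:`write_image_vtk` (name -> float32 array)."""
    tree = ET.parse(path)
    out = {}
    for da in tree.iter("DataArray"):
        vals = np.fromstring(da.text, sep=" ", dtype=np.float32)
        ncomp = int(da.get("NumberOfComponents", "1"))
        if ncomp > 1:
            vals = vals.reshape(-1, ncomp)
        out[da.get("Name")] = vals
    return out


def write_fields_vtk(result: fem.FEMResult, path, stimulus_field=None, grid=None):
    """Write displacement/pressure (points) and stimulus fields (cells) to .vti.

    Cell arrays defined only on granulation elements carry NaN (S, S_over_Smax)
    or code 255 (phenotype) on scaffold elements; see ``PHENOTYPE_LEGEND``.
    """
    model = result.model
    nxn, nyn, nzn = model.node_shape
    shape = (nxn - 1, nyn - 1, nzn - 1)
    n_lattice = nxn * nyn * nzn

    # scatter active-node fields onto the full lattice
    disp = np.zeros((n_lattice, 3), dtype=np.float32)
    pres = np.zeros(n_lattice, dtype=np.float32)
    disp[model.active_nodes] = result.displacements[-1]
    pres[model.active_nodes] = result.pressures[-1]
    disp = disp.reshape(nxn, nyn, nzn, 3)
    pres = pres.reshape(nxn, nyn, nzn)

    point_fields = {"displacement": (disp, 3), "pressure": (pres, 1)}

    cell_fields = {}
    if grid is not None:
        cell_fields["label"] = (grid.labels.astype(np.float32), 1)
    if stimulus_field is not None:
        ne_total = int(np.prod(shape))
        S = np.full(ne_total, np.nan, dtype=np.float32)
        Sn = np.full(ne_total, np.nan, dtype=np.float32)
        ph = np.full(ne_total, 255.0, dtype=np.float32)
        # element order in the model is C order over voxel indices
        S[stimulus_field.element_ids] = stimulus_field.S
        Sn[stimulus_field.element_ids] = stimulus_field.normalized
        ph[stimulus_field.element_ids] = stimulus_field.phenotype
        for name, arr in [("S", S), ("S_over_Smax", Sn), ("phenotype", ph)]:
            cell_fields[name] = (arr.reshape(shape), 1)

    return write_image_vtk(path, shape, model.h, cell_fields=cell_fields, point_fields=point_fields)


def write_stl(grid: LabeledGrid, path):
    """ASCII STL of the scaffold surface via marching cubes on the solid mask."""
    from skimage import measure

    solid = (grid.labels == geometry.Phase.SCAFFOLD).astype(np.float32)
    padded = np.pad(solid, 1)  # close the surface at the boundary
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(grid.voxel_size,) * 3)
    verts = verts - grid.voxel_size  # undo padding offset
    with open(path, "w") as f:
        f.write("solid scaffold\n")
        for tri in faces:
            p0, p1, p2 = verts[tri]
            n = np.cross(p1 - p0, p2 - p0)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            f.write(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
            f.write("    outer loop\n")
            for p in (p0, p1, p2):
                f.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
            f.write("    endloop\n")
            f.write("  endfacet\n")
        f.write("endsolid scaffold\n")
    return Path(path)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "tiny_cell",
    "terzaghi_column",
    "homogeneous_cube",
    "fig9_geometry",
    "section3_triplet",
)


def generate_fixture(name: str):
    """Deterministic small configurations used across the test suite.

    Returns ``(RunConfig or list, expected: dict)``.
    """
    if name == "tiny_cell":
        cfg = RunConfig(
            L_mm=0.637, cells_per_side=1, Ds_mm=0.5, Dc_mm=0.2, resolution=8,
            F_UA_MPa=0.1, max_evaluations=40,
        )
        return cfg, {"n_cells": 1, "topology": "S"}
    if name == "terzaghi_column":
        cfg = {
            "material": default_materials()["granulation"],
            "n_elements": 16,
            "height_mm": 1.0,
            "F_UA_MPa": 0.1,
        }
        return cfg, {"drained_face": "top"}
    if name == "homogeneous_cube":
        cfg = RunConfig(
            L_mm=1.0, cells_per_side=1, Ds_mm=0.5, Dc_mm=0.2, resolution=8, F_UA_MPa=0.1,
            hold_time_s=20.0, n_hold=5,
        )
        return cfg, {"Vf": 1.0, "E_app_MPa": 1000.0}
    if name == "fig9_geometry":
        cfg = RunConfig(
            Ds_mm=0.425, Dc_mm=0.275, constraint_dialect="derived",
            mode="compression", F_UA_MPa=0.5, resolution=8,
        )
        return cfg, {"as_printed_valid": False, "derived_valid": True}
    if name == "section3_triplet":
        cfgs = [
            RunConfig(Ds_mm=Ds, Dc_mm=Dc, constraint_dialect="derived",
                      mode="compression", F_UA_MPa=0.1, resolution=8)
            for Ds, Dc in ((0.85, 0.55), (0.75, 0.5), (0.65, 0.45))
        ]
        return cfgs, {"ordering": "Vf and E_app decrease from (0.65,0.45) to (0.85,0.55)"}
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _setup_logging(level):
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")


def _load_config(config_path, **overrides):
    if config_path:
        cfg = RunConfig.from_yaml(config_path)
        data = asdict(cfg)
    else:
        data = asdict(RunConfig())
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


@click.group()
@click.version_option(version=__version__)
def cli():
    """Spherical-pore scaffold micro-geometry design tool."""


_common = [
    click.option("--config", "config_path", type=click.Path(exists=True), default=None),
    click.option("--ds", "Ds_mm", type=float, default=None, help="sphere diameter, mm"),
    click.option("--dc", "Dc_mm", type=float, default=None, help="cylinder diameter, mm"),
    click.option("--L", "L_mm", type=float, default=None, help="scaffold edge, mm"),
    click.option("--cells-per-side", type=int, default=None),
    click.option("--resolution", type=int, default=None),
    click.option("--dialect", "constraint_dialect",
                 type=click.Choice(["as_printed", "derived"]), default=None),
    click.option("--mode", type=click.Choice(["compression", "shear"]), default=None),
    click.option("--f-ua", "F_UA_MPa", type=float, default=None, help="load per unit area, MPa"),
    click.option("--seed", type=int, default=None),
    click.option("--out", "out_dir", type=click.Path(), default=None),
    click.option("--log-level", default=None),
]


def _with_common(f):
    for opt in reversed(_common):
        f = opt(f)
    return f


def _build_cfg_or_exit(config_path, kwargs):
    try:
        return _load_config(config_path, **kwargs)
    except (ValueError, TypeError) as exc:
        click.echo(f"config error: {exc}", err=True)
        sys.exit(2)


@cli.command()
@_with_common
def validate(config_path, **kwargs):
    """Check (Ds, Dc) against the coherence constraints and print the topology."""
    cfg = _build_cfg_or_exit(config_path, kwargs)
    _setup_logging(cfg.log_level)
    Luc = cfg.L_mm / cfg.cells_per_side
    try:
        cell = UnitCellSpec(Luc=Luc, Ds=cfg.Ds_mm, Dc=cfg.Dc_mm,
                            constraint_dialect=cfg.constraint_dialect)
    except ValueError as exc:
        click.echo(f"invalid geometry: {exc}", err=True)
        sys.exit(2)
    report = geometry.validate_cell(cell)
    click.echo(f"topology: {cell.topology.value}")
    if report.valid:
        click.echo("constraints: satisfied")
    else:
        for v in report.violations:
            click.echo(f"violated: {v}")
        sys.exit(2)


@cli.command()
@_with_common
def build(config_path, **kwargs):
    """Voxelize the scaffold, write label grid (.vti) and surface (.stl)."""
    cfg = _build_cfg_or_exit(config_path, kwargs)
    _setup_logging(cfg.log_level)
    out = Path(cfg.out_dir)
    try:
        spec = cfg.scaffold_spec()
        grid = geometry.assemble_scaffold(spec, cfg.resolution)
    except (ValueError, geometry.ConstraintError) as exc:
        click.echo(f"geometry error: {exc}", err=True)
        sys.exit(2)
    out.mkdir(parents=True, exist_ok=True)
    write_image_vtk(out / "labels.vti", grid.shape, grid.voxel_size,
                    cell_fields={"label": (grid.labels.astype(np.float32), 1)})
    write_stl(grid, out / "scaffold.stl")
    write_manifest(cfg, out, {"Vf": geometry.volume_fraction(grid),
                              "n_cells": spec.n_cells})
    click.echo(f"Vf = {geometry.volume_fraction(grid):.4f}; wrote {out}/labels.vti, scaffold.stl")


@cli.command()
@_with_common
def solve(config_path, **kwargs):
    """Run one poroelastic solve and write stimulus fields + summary CSV."""
    cfg = _build_cfg_or_exit(config_path, kwargs)
    _setup_logging(cfg.log_level)
    out = Path(cfg.out_dir)
    try:
        spec = cfg.scaffold_spec()
        grid = geometry.assemble_scaffold(spec, cfg.resolution)
    except (ValueError, geometry.ConstraintError) as exc:
        click.echo(f"geometry error: {exc}", err=True)
        sys.exit(2)
    try:
        model = fem.build_fe_model(grid, cfg.material_map(), cfg.load_case())
        result = fem.solve_consolidation(model)
        sfield = mechanoreg.compute_stimulus_field(result, cfg.stimulus_model())
        bo = mechanoreg.bone_fraction(sfield, spec.L)
    except (fem.ConfigurationError, fem.NumericalError) as exc:
        click.echo(f"solve error: {exc}", err=True)
        sys.exit(1)
    out.mkdir(parents=True, exist_ok=True)
    write_fields_vtk(result, out / "fields.vti", stimulus_field=sfield, grid=grid)
    import pandas as pd

    shares = {
        ph.name.lower(): float(np.mean(sfield.phenotype == ph)) if sfield.S.size else 0.0
        for ph in mechanoreg.Phenotype
    }
    pd.DataFrame([{"BO_percent": bo.BO_percent, "S_max": sfield.S_max, **shares}]).to_csv(
        out / "summary.csv", index=False
    )
    write_manifest(cfg, out, {"BO_percent": bo.BO_percent})
    click.echo(f"BO% = {bo.BO_percent:.3f}; wrote {out}/fields.vti, summary.csv")


@cli.command()
@_with_common
@click.option("--max-evaluations", type=int, default=None)
def optimize(config_path, max_evaluations, **kwargs):
    """Optimize (Ds, Dc) for one load case; write trace JSON."""
    cfg = _build_cfg_or_exit(config_path,
                             {**kwargs, "max_evaluations": max_evaluations})
    _setup_logging(cfg.log_level)
    out = Path(cfg.out_dir)
    spec = cfg.scaffold_spec()
    try:
        res = optimizer.optimize_geometry(
            spec, cfg.load_case(), cfg.optimizer_config(),
            materials=cfg.material_map(), stimulus_model=cfg.stimulus_model(),
        )
    except (fem.ConfigurationError, fem.NumericalError) as exc:
        click.echo(f"optimization error: {exc}", err=True)
        sys.exit(1)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trace.json").write_text(res.trace.to_json(orient="records", indent=2))
    write_manifest(cfg, out, {"Ds_opt": res.Ds_opt, "Dc_opt": res.Dc_opt,
                              "BO_opt": res.BO_opt})
    click.echo(f"Ds_opt={res.Ds_opt:.4f} mm, Dc_opt={res.Dc_opt:.4f} mm, "
               f"BO%={res.BO_opt:.3f}")


@cli.command()
@_with_common
@click.option("--loads", "loads_csv", default=None,
              help="comma-separated F_UA values in MPa (default: published list)")
@click.option("--max-evaluations", type=int, default=None)
def sweep(config_path, loads_csv, max_evaluations, **kwargs):
    """Optimize across the load list; write the (mode, F_UA, Ds, Dc, BO%) table."""
    cfg = _build_cfg_or_exit(config_path,
                             {**kwargs, "max_evaluations": max_evaluations})
    _setup_logging(cfg.log_level)
    out = Path(cfg.out_dir)
    if loads_csv:
        values = [float(v) for v in loads_csv.split(",")]
    else:
        values = list(optimizer.COMPRESSION_LOADS_MPA if cfg.mode == "compression"
                      else optimizer.SHEAR_LOADS_MPA)
    loads = [LoadCase(mode=cfg.mode, F_UA=v, ramp_time=cfg.ramp_time_s,
                      n_increments=cfg.n_increments) for v in values]
    spec = cfg.scaffold_spec()
    table = optimizer.load_sweep(spec, loads, cfg.optimizer_config(),
                                 materials=cfg.material_map(),
                                 stimulus_model=cfg.stimulus_model())
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "sweep.csv", index=False)
    write_manifest(cfg, out, {"n_rows": len(table)})
    click.echo(table.to_string(index=False))
    if table["failed"].any():
        sys.exit(1)


def run_cli(argv=None) -> int:
    """Programmatic CLI entry point returning the exit code."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except SystemExit as exc:
        return int(exc.code or 0)
    except click.ClickException as exc:
        exc.show()
        return 2


def main():
    cli()


if __name__ == "__main__":
    main()
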