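# poroscaf

Mechanobiology-driven design of bone-scaffold micro-geometry with spherical
pores and cylindrical interconnections.

A parametric unit cell (cube of edge `Luc` minus a centered sphere of diameter
`Ds` and three orthogonal cylinders of diameter `Dc`) is tiled into a cubic
scaffold, the pores are filled with granulation tissue, and the assembly is
solved as a biphasic (Biot) poroelastic continuum under a ramped compression
or shear plate load. Each soft-tissue element is scored by the
tissue-differentiation stimulus `S = gamma/a + v/b` (octahedral shear strain
and interstitial fluid speed); the share of the model volume predicted to
become mature bone (`BO%`, elements with `0.01 < S < 0.53`) is the objective
that a constrained optimizer maximizes over `(Ds, Dc)`.

## Modules

| module | contents |
| --- | --- |
| `poroscaf.geometry` | unit-cell CSG membership, topology S/L classification, coherence constraints (two dialects), voxelization, volume fraction |
| `poroscaf.fem` | voxel hexahedral Biot poroelastic solver (u–p, backward Euler), rigid-plate loading, encastre base, drained granulation surfaces, apparent modulus, Terzaghi reference solution |
| `poroscaf.mechanoreg` | stimulus, phenotype classification, `BO%` |
| `poroscaf.optimizer` | penalized derivative-free (or finite-difference SLSQP) maximization of `BO%` with grid presearch and multistart, load sweeps |
| `poroscaf.interface` | YAML config, CLI, VTK/STL export, manifests, test fixtures |

## CLI

```sh
poroscaf validate --ds 0.5 --dc 0.25 --L 2.548        # constraint check + topology
poroscaf build    --ds 0.5 --dc 0.2  --resolution 8 --out out/   # .vti + .stl
poroscaf solve    --ds 0.5 --dc 0.2 --f-ua 0.1 --out out/        # fields + BO%
poroscaf optimize --L 0.637 --cells-per-side 1 --out out/        # optimal (Ds, Dc)
poroscaf sweep    --mode compression --out out/                  # table across loads
```

All options can also be given in a YAML config (`--config cfg.yaml`); keys
carry units (`L_mm`, `F_UA_MPa`, ...). Every run writes `manifest.json` with
the config hash, seed and package versions.

Defaults reproduce the reference setup: `L = 2.548` mm, 4x4x4 unit cells,
granulation tissue `E = 0.2` MPa / scaffold `E = 1000` MPa (full constants in
`poroscaf.fem.default_materials`), compression loads
{0.05, 0.1, 0.5, 1.0, 1.5} MPa and shear loads {0.01, 0.05, 0.1, 0.2, 0.5} MPa.

## Notes

- Constraint dialects: `as_printed` enforces `Dc <= Ds/2`; `derived` enforces
  `Dc <= Ds/sqrt(2)` (the bound implied by the inscribed-square construction,
  needed to accept some published example geometries).
- The solver uses a sparse direct factorization for small systems and a
  Schur-complement CG (pressure block eliminated) above ~6k free dofs.
- Bare-scaffold (`solid_only`) stiffness runs fill the pores with a
  `1e-3`-contrast soft material so that coarse voxelizations with
  disconnected solid clusters remain solvable.
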