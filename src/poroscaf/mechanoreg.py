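"""Mechano-regulation scoring: biophysical stimulus, phenotype, bone fraction.

The stimulus on the soft tissue in the pores is

    S = gamma / a + v / b

with ``gamma`` the octahedral shear strain, ``v`` the interstitial fluid
speed (um/s), and scale constants ``a = 0.0375``, ``b = 3 um/s`` adopted from
the mechano-regulation literature this model builds on.  Stimulus ranges map
to predicted tissue phenotypes; the optimization objective BO% is the share
of the total model volume occupied by elements in the mature-bone range.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .fem import FEMResult, darcy_velocities, element_strains

__all__ = [
    "StimulusModel",
    "PhenotypeThresholds",
    "Phenotype",
    "StimulusField",
    "BoneFractionResult",
    "octahedral_shear_strain",
    "stimulus",
    "classify_phenotype",
    "compute_stimulus_field",
    "bone_fraction",
]


@dataclass(frozen=True)
class StimulusModel:
    """Stimulus scale constants: strain scale ``a`` and fluid-speed scale ``b`` (um/s)."""

    a: float = 0.0375
    b: float = 3.0
    flow_measure: str = "darcy"  # or "seepage" (flux / porosity)

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("stimulus constants a and b must be positive")
        if self.flow_measure not in ("darcy", "seepage"):
            raise ValueError(f"unknown flow measure {self.flow_measure!r}")


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Stimulus interval bounds separating the five predicted phenotypes."""

    resorption_hi: float = 0.01
    mature_hi: float = 0.53
    immature_hi: float = 1.0
    cartilage_hi: float = 3.0

    def __post_init__(self):
        seq = (0.0, self.resorption_hi, self.mature_hi, self.immature_hi, self.cartilage_hi)
        if any(b >= c for b, c in zip(seq, seq[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {seq[1:]}")


class Phenotype(IntEnum):
    RESORPTION = 0
    MATURE_BONE = 1
    IMMATURE_BONE = 2
    CARTILAGE = 3
    FIBROUS = 4


@dataclass
class StimulusField:
    """Per-granulation-element stimulus and phenotype labels."""

    element_ids: np.ndarray  # indices into the model's element list
    S: np.ndarray
    phenotype: np.ndarray  # Phenotype codes
    element_volume: float  # mm^3, identical voxels
    S_max: float

    def __post_init__(self):
        if self.S.size and self.S_max < self.S.max():
            raise ValueError("S_max below the field maximum")

    @property
    def normalized(self) -> np.ndarray:
        """S / S_max (zeros if the field is identically zero)."""
        if self.S_max == 0.0:
            return np.zeros_like(self.S)
        return self.S / self.S_max


@dataclass
class BoneFractionResult:
    BO_percent: float
    qualifying_volume: float  # mm^3
    Vtot: float  # mm^3


def octahedral_shear_strain(eps) -> np.ndarray:
    """Octahedral shear strain from a small-strain tensor.

    gamma = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2) over principal
    strains.  Accepts a (..., 3, 3) tensor or a (..., 6) Voigt vector with
    engineering shears [exx, eyy, ezz, gxy, gyz, gxz].
    """
    eps = np.asarray(eps, dtype=float)
    if eps.shape[-1] == 6 and (eps.ndim == 1 or eps.shape[-2:] != (3, 3)):
        t = np.zeros(eps.shape[:-1] + (3, 3))
        t[..., 0, 0] = eps[..., 0]
        t[..., 1, 1] = eps[..., 1]
        t[..., 2, 2] = eps[..., 2]
        t[..., 0, 1] = t[..., 1, 0] = eps[..., 3] / 2.0
        t[..., 1, 2] = t[..., 2, 1] = eps[..., 4] / 2.0
        t[..., 0, 2] = t[..., 2, 0] = eps[..., 5] / 2.0
        eps = t
    elif eps.shape[-2:] != (3, 3):
        raise ValueError(f"expected (...,3,3) tensor or (...,6) Voigt vector, got {eps.shape}")
    if not np.allclose(eps, np.swapaxes(eps, -1, -2), atol=1e-12):
        raise ValueError("strain tensor must be symmetric")
    e = np.linalg.eigvalsh(eps)
    e1, e2, e3 = e[..., 0], e[..., 1], e[..., 2]
    out = (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)
    return out if out.ndim else float(out)


def stimulus(gamma, v, model: StimulusModel = StimulusModel()):
    """Biophysical stimulus S = gamma/a + v/b (scalar or elementwise)."""
    gamma = np.asarray(gamma, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(gamma < 0) or np.any(v < 0):
        raise ValueError("gamma and v must be non-negative")
    out = gamma / model.a + v / model.b
    return out if out.ndim else float(out)


def classify_phenotype(S, thresholds: PhenotypeThresholds = PhenotypeThresholds()):
    """Map stimulus values to phenotypes.

    Bins (lower-inclusive at the printed interval bounds):
    [0, 0.01) resorption, [0.01, 0.53) mature bone, [0.53, 1) immature bone,
    [1, 3] cartilage, (3, inf) fibrous tissue.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("stimulus must be non-negative")
    t = thresholds
    out = np.full(S.shape, Phenotype.FIBROUS, dtype=np.int64)
    out[S <= t.cartilage_hi] = Phenotype.CARTILAGE
    out[S < t.immature_hi] = Phenotype.IMMATURE_BONE
    out[S < t.mature_hi] = Phenotype.MATURE_BONE
    out[S < t.resorption_hi] = Phenotype.RESORPTION
    return out if out.ndim else Phenotype(int(out))


def compute_stimulus_field(
    result: FEMResult,
    model: StimulusModel = StimulusModel(),
    thresholds: PhenotypeThresholds = PhenotypeThresholds(),
    increment: int = -1,
) -> StimulusField:
    """Evaluate S and the phenotype on every granulation element.

    Strain and Darcy flux are taken at element centroids at the requested
    increment (default: final, i.e. peak load).
    """
    femodel = result.model
    try:
        gran_mat = femodel.material_names.index("granulation")
    except ValueError:
        raise ValueError("model has no granulation elements to score") from None
    gran = np.nonzero(femodel.elem_mat == gran_mat)[0]

    eps = element_strains(result, increment)[gran]
    gamma = octahedral_shear_strain(eps)
    vvec = darcy_velocities(result, increment)[gran]
    v = np.linalg.norm(vvec, axis=1)
    if model.flow_measure == "seepage":
        v = v / femodel.materials[gran_mat].porosity
    S = stimulus(gamma, v, model)
    pheno = classify_phenotype(S, thresholds)
    return StimulusField(
        element_ids=gran,
        S=S,
        phenotype=pheno,
        element_volume=femodel.h**3,
        S_max=float(S.max()) if S.size else 0.0,
    )


def bone_fraction(field: StimulusField, L: float) -> BoneFractionResult:
    """BO% = 100 x (volume of mature-bone elements) / L^3."""
    n_mature = int(np.count_nonzero(field.phenotype == Phenotype.MATURE_BONE))
    vol = n_mature * field.element_volume
    Vtot = L**3
    return BoneFractionResult(
        BO_percent=100.0 * vol / Vtot, qualifying_volume=vol, Vtot=Vtot
    )
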