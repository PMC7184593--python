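"""Dose-averaged LET bookkeeping and LET-dependent proton RBE models.

The dose-averaged LET of a voxel is the energy-deposition-weighted mean of
the per-step LET values: each step's LET (energy deposited / step length)
is multiplied by the energy deposited in that step, and the sum of these
weighted values is divided by the total energy deposited in the voxel.

Two phenomenological linear-quadratic RBE models are implemented.  With
dose per fraction D (Gy), dose-averaged LET (keV/um) and tissue alpha/beta
ratio a = alpha/beta (Gy):

Wedenberg::

    RBE = (1 / 2D) * ( sqrt(a^2 + 4D(a + 0.434 LET) + 4D^2) - a )

McNamara::

    RBE = (1 / 2D) * ( sqrt(a^2
            + 4D a (0.999064 + (0.35605 / a) LET)
            + 4D^2 (1.1012 + 0.0038703 sqrt(a) LET)^2) - a )

Both reduce to familiar limits: Wedenberg gives exactly 1 at LET = 0 for
any D and a; McNamara tends to ``1.1012 + 0.0038703 sqrt(a) LET`` at high
dose.  Conventional parameter choices are alpha/beta = 10 Gy in the target
and 3 Gy in normal tissue, at 2 Gy per fraction.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .grids import GridError, Quantity, StructureMask, VoxelGrid, require_congruent


class RBEModel(str, enum.Enum):
    WEDENBERG = "wedenberg"
    MCNAMARA = "mcnamara"


@dataclasses.dataclass
class RBEParams:
    """RBE evaluation settings (alpha/beta in Gy, dose per fraction in Gy)."""

    model: RBEModel = RBEModel.WEDENBERG
    dose_per_fraction: float = 2.0
    alpha_beta_target: float = 10.0
    alpha_beta_normal: float = 3.0

    def __post_init__(self) -> None:
        self.model = RBEModel(self.model)
        if self.dose_per_fraction <= 0:
            raise GridError("dose_per_fraction must be positive")
        if self.alpha_beta_target <= 0 or self.alpha_beta_normal <= 0:
            raise GridError("alpha/beta ratios must be positive")


# ---------------------------------------------------------------------------
# dose-averaged LET accumulation
# ---------------------------------------------------------------------------

class LETAccumulator:
    """Running per-voxel sums for dose-averaged LET scoring.

    ``weighted_sum`` holds sum(energy_i * LET_i), ``energy_sum`` holds
    sum(energy_i); accumulation is order-independent.
    """

    def __init__(self, shape: tuple[int, int, int]):
        self.weighted_sum = np.zeros(shape, dtype=float)
        self.energy_sum = np.zeros(shape, dtype=float)

    def add(self, voxels, energy, let) -> "LETAccumulator":
        voxels = np.atleast_2d(np.asarray(voxels, dtype=np.intp))
        energy = np.atleast_1d(np.asarray(energy, dtype=float))
        let = np.atleast_1d(np.asarray(let, dtype=float))
        if voxels.shape != (energy.size, 3):
            raise GridError("voxels must be an (N, 3) index array")
        if np.any(energy < 0):
            raise GridError("deposited energy must be non-negative")
        if np.any(let < 0):
            raise GridError("LET must be non-negative")
        idx = tuple(voxels.T)
        np.add.at(self.weighted_sum, idx, energy * let)
        np.add.at(self.energy_sum, idx, energy)
        return self


def accumulate_let(acc: LETAccumulator, voxels, energy, let) -> LETAccumulator:
    """Add deposition events ``(voxel, energy, LET)`` to the accumulator."""
    return acc.add(voxels, energy, let)


def finalize_let(acc: LETAccumulator,
                 spacing: tuple[float, float, float],
                 origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
                 ) -> tuple[VoxelGrid, np.ndarray]:
    """Per-voxel dose-averaged LET and a mask of defined voxels.

    Voxels with zero deposited energy are undefined (LET set to 0 in the
    grid, False in the mask) and must be excluded from RBE statistics.
    """
    defined = acc.energy_sum > 0
    values = np.zeros_like(acc.weighted_sum)
    values[defined] = acc.weighted_sum[defined] / acc.energy_sum[defined]
    return VoxelGrid(values, spacing, origin, Quantity.LET), defined


# ---------------------------------------------------------------------------
# RBE models
# ---------------------------------------------------------------------------

def _check_dose(dose: np.ndarray) -> None:
    if np.any(dose <= 0):
        raise GridError("RBE models require strictly positive dose (Gy)")


def rbe_wedenberg(dose, let, alpha_beta: float):
    """Wedenberg LET-dependent RBE (element-wise; dose in Gy, LET in keV/um)."""
    dose = np.asarray(dose, dtype=float)
    let = np.asarray(let, dtype=float)
    _check_dose(dose)
    ab = float(alpha_beta)
    root = np.sqrt(ab**2 + 4.0 * dose * (ab + 0.434 * let) + 4.0 * dose**2)
    return (root - ab) / (2.0 * dose)


def rbe_mcnamara(dose, let, alpha_beta: float):
    """McNamara LET-dependent RBE (element-wise; dose in Gy, LET in keV/um)."""
    dose = np.asarray(dose, dtype=float)
    let = np.asarray(let, dtype=float)
    _check_dose(dose)
    ab = float(alpha_beta)
    lin = ab * (0.999064 + (0.35605 / ab) * let)
    quad = (1.1012 + 0.0038703 * np.sqrt(ab) * let) ** 2
    root = np.sqrt(ab**2 + 4.0 * dose * lin + 4.0 * dose**2 * quad)
    return (root - ab) / (2.0 * dose)


_MODEL_FN = {RBEModel.WEDENBERG: rbe_wedenberg, RBEModel.MCNAMARA: rbe_mcnamara}


@dataclasses.dataclass
class RBEWeightedResult:
    """RBE-weighted dose and RBE grids, plus undefined-LET voxel count."""

    weighted: VoxelGrid
    rbe: VoxelGrid
    n_undefined: int


def rbe_weighted_dose(dose: VoxelGrid, let: VoxelGrid, params: RBEParams,
                      target: StructureMask, normal: StructureMask,
                      defined: np.ndarray | None = None) -> RBEWeightedResult:
    """Per-voxel RBE-weighted dose with mask-dependent alpha/beta.

    The relative dose grid (% of prescription) is anchored to physical
    dose by mapping 100% to ``dose_per_fraction`` Gy before evaluating the
    model.  Target voxels use ``alpha_beta_target``, normal-tissue voxels
    ``alpha_beta_normal``; the masks must not overlap.  Voxels with
    undefined LET, zero dose, or outside both masks keep their physical
    dose (RBE 1) and undefined voxels are counted.
    """
    require_congruent(dose, let)
    require_congruent(dose, target)
    require_congruent(dose, normal)
    if np.any(target.mask & normal.mask):
        raise GridError("target and normal masks overlap")
    if defined is None:
        defined = np.ones(dose.values.shape, dtype=bool)

    dose_gy = dose.values / 100.0 * params.dose_per_fraction
    rbe = np.ones_like(dose.values, dtype=float)
    fn = _MODEL_FN[params.model]
    n_undefined = 0
    for mask, ab in ((target.mask, params.alpha_beta_target),
                     (normal.mask, params.alpha_beta_normal)):
        n_undefined += int(np.count_nonzero(mask & ~defined))
        sel = mask & defined & (dose_gy > 0)
        if np.any(sel):
            rbe[sel] = fn(dose_gy[sel], let.values[sel], ab)
    weighted = dose.values * rbe
    return RBEWeightedResult(
        weighted=VoxelGrid(weighted, dose.spacing, dose.origin,
                           Quantity.RBE_WEIGHTED_DOSE),
        rbe=VoxelGrid(rbe, dose.spacing, dose.origin, Quantity.RBE),
        n_undefined=n_undefined,
    )
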