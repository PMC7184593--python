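"""Gamma-index comparison of two dose grids (3%/3 mm local by default).

For each reference voxel r above the low-dose cutoff::

    gamma(r) = min over evaluated positions e within the search radius of
        sqrt( (|d_e - d_r| / (dose_tol * norm))^2 + (||e - r|| / dta)^2 )

with trilinear interpolation of the evaluated grid on a sub-voxel search
lattice.  ``local`` mode normalises the dose difference by the reference
voxel dose, ``global`` by the reference maximum.  A voxel passes when
gamma < 1 (strict); the passing rate is reported in percent of evaluated
voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import GridError, Quantity, StructureMask, VoxelGrid, require_congruent


@dataclasses.dataclass
class GammaCriteria:
    """Acceptance criteria and search settings for the gamma comparison."""

    dose_tol: float = 0.03         # fractional dose tolerance (3%)
    dta: float = 3.0               # distance-to-agreement, mm
    mode: str = "local"            # 'local' or 'global' normalisation
    low_dose_cutoff: float = 0.10  # fraction of reference maximum
    search_radius: float | None = None  # mm; default 3 * dta
    search_step: float | None = None    # mm; default dta / 10

    def __post_init__(self) -> None:
        if self.dose_tol <= 0:
            raise GridError("dose_tol must be positive")
        if self.dta <= 0:
            raise GridError("dta must be positive")
        if self.mode not in ("local", "global"):
            raise GridError("mode must be 'local' or 'global'")
        if self.search_radius is None:
            self.search_radius = 3.0 * self.dta
        if self.search_step is None:
            self.search_step = self.dta / 10.0
        if self.search_radius < self.dta:
            raise GridError("search_radius must be >= dta")
        if self.search_step <= 0:
            raise GridError("search_step must be positive")


def _search_offsets(criteria: GammaCriteria) -> np.ndarray:
    """Sub-voxel search lattice offsets (mm), sorted by distance."""
    s = criteria.search_step
    r = criteria.search_radius
    k = int(np.floor(r / s + 1e-9))
    axis = np.arange(-k, k + 1) * s
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    norms = np.sqrt((offsets**2).sum(axis=1))
    keep = norms <= r + 1e-9
    offsets, norms = offsets[keep], norms[keep]
    order = np.argsort(norms, kind="stable")
    return offsets[order]


def gamma_index(reference: VoxelGrid, evaluated: VoxelGrid,
                criteria: GammaCriteria | None = None) -> VoxelGrid:
    """Per-voxel gamma index; NaN for reference voxels below the cutoff.

    The minimisation explores offsets in order of increasing distance and
    stops once the distance term alone exceeds every remaining voxel's
    running minimum (the distance contribution only grows, so no later
    offset can improve the result).  Evaluated positions falling outside
    the grid are skipped.
    """
    criteria = criteria or GammaCriteria()
    require_congruent(reference, evaluated)
    ref = reference.values.astype(float)
    cutoff = criteria.low_dose_cutoff * float(ref.max())
    sel = ref > cutoff
    if not np.any(sel):
        raise GridError("no reference voxels above the low-dose cutoff")

    norm = ref[sel] if criteria.mode == "local" else float(ref.max())
    denom = criteria.dose_tol * norm

    base = np.array(np.nonzero(sel), dtype=float)          # (3, N) voxel coords
    ref_sel = ref[sel]
    spacing = np.asarray(reference.spacing)

    gamma2 = np.full(ref_sel.shape, np.inf)
    active = np.arange(ref_sel.size)
    ev = evaluated.values.astype(float)

    for offset in _search_offsets(criteria):
        dist2 = float((offset**2).sum()) / criteria.dta**2
        keep = gamma2[active] > dist2
        active = active[keep]
        if active.size == 0:
            break
        coords = base[:, active] + (offset / spacing)[:, None]
        vals = map_coordinates(ev, coords, order=1, mode="constant",
                               cval=np.nan, prefilter=False)
        d = denom[active] if criteria.mode == "local" else denom
        cand = dist2 + ((vals - ref_sel[active]) / d) ** 2
        gamma2[active] = np.fmin(gamma2[active], cand)

    out = np.full(ref.shape, np.nan)
    out[sel] = np.sqrt(gamma2)
    return VoxelGrid(out, reference.spacing, reference.origin, Quantity.GAMMA)


def passing_rate(gamma: VoxelGrid, mask: StructureMask | None = None) -> float:
    """Percent of evaluated voxels with gamma strictly below 1."""
    values = gamma.values
    sel = np.isfinite(values)
    if mask is not None:
        require_congruent(gamma, mask)
        sel &= mask.mask
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise GridError("no evaluated voxels")
    return 100.0 * float(np.count_nonzero(values[sel] < 1.0)) / n
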