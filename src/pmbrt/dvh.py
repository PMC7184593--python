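"""Dose-volume histograms and homogeneity/coverage metrics.

Doses are in percent of the prescribed dose ``D_50`` (= 100%).  Metrics:

* ``s_index`` — sigma-index: standard deviation of the normalised
  differential DVH, in % of prescription (dose-homogeneity measure);
* ``d95`` — maximum dose level received by at least 95% of the volume;
* ``v93`` / ``v110`` — % of the volume receiving strictly less than 93% /
  strictly more than 110% of prescription;
* ``mc_uncertainty`` — MC-style relative statistical uncertainty:
  sqrt(mean variance) over voxels above 90% of the maximum dose, divided
  by the mean dose of those voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grids import (
    GridError,
    StructureMask,
    VoxelGrid,
    require_congruent,
    require_nonempty,
)

#: default DVH bin width, % of prescription (below Table-style metric precision)
DEFAULT_BIN_WIDTH = 0.1


@dataclasses.dataclass
class DVHCurve:
    """Differential and cumulative dose-volume curves for one structure.

    ``differential[i]`` is the fractional volume in
    ``[bin_edges[i], bin_edges[i+1])`` (sums to 1); ``cumulative[i]`` the
    fractional volume receiving at least ``bin_edges[i]``.
    """

    bin_edges: np.ndarray
    differential: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.differential = np.asarray(self.differential, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.bin_edges.size != self.differential.size + 1:
            raise GridError("bin_edges must have one more entry than differential")
        if self.cumulative.size != self.bin_edges.size:
            raise GridError("cumulative must be evaluated at the bin edges")
        if np.any(self.differential < 0):
            raise GridError("differential DVH must be non-negative")
        if abs(self.differential.sum() - 1.0) > 1e-9:
            raise GridError("differential DVH must sum to 1")
        if np.any(np.diff(self.cumulative) > 1e-12):
            raise GridError("cumulative DVH must be non-increasing")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def cumulative_at(self, dose) -> np.ndarray:
        """Fractional volume receiving >= dose (linear between edges)."""
        return np.interp(dose, self.bin_edges, self.cumulative)


@dataclasses.dataclass
class HomogeneityReport:
    """Coverage/homogeneity summary for one structure (all % of prescription)."""

    mean_dose: float
    d95: float
    v93: float
    v110: float
    s_index: float
    n_voxels: int
    pvdr: float | None = None
    pvdr_sd: float | None = None

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: v for k, v in out.items() if v is not None}


def _masked_doses(dose: VoxelGrid, mask: StructureMask) -> np.ndarray:
    require_congruent(dose, mask)
    require_nonempty(mask)
    return dose.values[mask.mask]


def compute_dvh(dose: VoxelGrid, mask: StructureMask,
                bin_width: float = DEFAULT_BIN_WIDTH) -> DVHCurve:
    """Equal-volume-weighted DVH of the masked voxels.

    The cumulative curve is the suffix sum of the differential one, so it
    is exactly 1 at dose 0 and exactly 0 above the maximum dose.
    """
    if bin_width <= 0:
        raise GridError("bin_width must be positive")
    doses = _masked_doses(dose, mask)
    n_bins = int(np.ceil((doses.max() + bin_width) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    diff = counts / doses.size
    # suffix sum on the integer counts: exactly 1 at dose 0, exactly 0 above
    # the maximum dose
    suffix = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])
    cum = suffix / doses.size
    return DVHCurve(edges, diff, cum)


def s_index(dvh: DVHCurve) -> float:
    """Sigma-index: SD of the normalised differential DVH, % of prescription."""
    c = dvh.bin_centers
    v = dvh.differential
    mean = float(np.sum(v * c))
    return float(np.sqrt(np.sum(v * (c - mean) ** 2)))


def coverage_stats(dose: VoxelGrid, mask: StructureMask,
                   bin_width: float = DEFAULT_BIN_WIDTH) -> HomogeneityReport:
    """Mean dose, D95, V93, V110 and s-index for one structure.

    D95 is the exact inverted-CDF 5th percentile of the voxel doses (the
    largest dose level received by >= 95% of the volume); V93/V110 use
    strict inequalities.
    """
    doses = _masked_doses(dose, mask)
    d95 = float(np.quantile(doses, 0.05, method="inverted_cdf"))
    v93 = 100.0 * float(np.mean(doses < 93.0))
    v110 = 100.0 * float(np.mean(doses > 110.0))
    sig = s_index(compute_dvh(dose, mask, bin_width))
    return HomogeneityReport(
        mean_dose=float(doses.mean()), d95=d95, v93=v93, v110=v110,
        s_index=sig, n_voxels=doses.size)


def mc_uncertainty(dose: VoxelGrid, variance: VoxelGrid) -> float:
    """Relative statistical uncertainty of an MC-like dose grid.

    Selects voxels with dose above 90% of the maximum and returns
    sqrt(mean variance) / mean dose over that set (fractional form; 0.03
    means 3%).
    """
    require_congruent(dose, variance)
    if np.any(variance.values < 0):
        raise GridError("variance must be non-negative")
    vmax = float(dose.values.max())
    if vmax <= 0:
        raise GridError("no voxels above the 90%-of-maximum threshold")
    sel = dose.values > 0.9 * vmax
    return float(np.sqrt(variance.values[sel].mean()) / dose.values[sel].mean())
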