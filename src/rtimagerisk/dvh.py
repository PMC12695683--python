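"""Differential and cumulative dose-volume histograms.

The differential DVH (dDVH) is the carrier for the scalar radiobiological
models: per-bin volume fractions v_i at bin-midpoint doses D_i. Bins are
left-closed, right-open and centred on integer multiples of the bin width
(midpoints at 0, bw, 2*bw, ...), so an unirradiated organ contributes dose
exactly 0 and the maximum-dose voxel always lands in the last bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, ParameterError
from .grids import DoseGrid, ROIMask

#: default histogram bin width in Gy; fine enough that bin-midpoint
#: quadrature error on OED/gEUD stays below 0.005 Gy
DEFAULT_BIN_WIDTH = 0.01


@dataclass
class DifferentialDVH:
    """Binned dose-volume-fraction histogram for one ROI.

    ``bin_edges`` (Gy, ascending, length B+1) and ``volume_fraction``
    (length B, sums to 1). ``voxel_volume`` is in mm^3.
    """

    bin_edges: np.ndarray
    volume_fraction: np.ndarray
    roi_name: str = ""
    voxel_volume: float = 0.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.bin_edges.ndim != 1 or self.volume_fraction.ndim != 1:
            raise ParameterError("bin_edges and volume_fraction must be 1-D")
        if len(self.bin_edges) != len(self.volume_fraction) + 1:
            raise ParameterError("need B+1 edges for B volume fractions")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin_edges must be strictly increasing")
        if np.any(self.volume_fraction < 0):
            raise ParameterError("volume fractions must be non-negative")
        if abs(self.volume_fraction.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"volume fractions must sum to 1 (got {self.volume_fraction.sum()!r})"
            )

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        """Bin-midpoint approximation of the mean dose (error <= bin_width/2)."""
        return float(np.dot(self.volume_fraction, self.bin_midpoints))


def compute_ddvh(dose: DoseGrid, mask: ROIMask,
                 bin_width: float = DEFAULT_BIN_WIDTH) -> DifferentialDVH:
    """Histogram the masked voxel doses into a differential DVH.

    Each voxel contributes its volume to exactly one left-closed,
    right-open bin; fractions are normalized by the ROI volume.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if not mask.inside.shape == dose.values.shape:
        raise ParameterError("mask and dose grid shapes differ")
    doses = dose.values[mask.inside]
    if doses.size == 0:
        raise EmptyMaskError("cannot compute a DVH over an empty mask")
    # bins centred on k*bin_width; edges reach past the max so the hottest
    # voxel is interior to the last bin
    n_bins = int(np.floor(doses.max() / bin_width + 0.5)) + 1
    edges = bin_width * np.arange(n_bins + 1) - bin_width / 2.0
    counts, _ = np.histogram(doses, bins=edges)
    return DifferentialDVH(
        bin_edges=edges,
        volume_fraction=counts / doses.size,
        roi_name=mask.roi_name,
        voxel_volume=dose.voxel_volume_mm3,
    )


def mean_dose(dose: DoseGrid, mask: ROIMask) -> float:
    """Voxel-exact mean dose: the arithmetic average over masked voxels.

    This is the quantity reported per ROI; the DVH-based
    :meth:`DifferentialDVH.mean` is only a bin-midpoint approximation.
    """
    doses = dose.values[mask.inside]
    if doses.size == 0:
        raise EmptyMaskError("cannot compute mean dose over an empty mask")
    return float(doses.mean())


def cumulative_from_differential(dvh: DifferentialDVH):
    """Cumulative DVH: volume fraction receiving >= dose, at the bin edges.

    Returns ``(dose_edges, fraction_at_or_above)`` with the curve starting
    at 1.0 at 0 Gy and non-increasing; differentiating it recovers the
    differential DVH.
    """
    frac_above = np.concatenate([
        [1.0],
        1.0 - np.cumsum(dvh.volume_fraction),
    ])
    # guard tiny negative rounding at the tail
    frac_above = np.clip(frac_above, 0.0, 1.0)
    return dvh.bin_edges.copy(), frac_above


def export_dvh_csv(dvhs, path) -> None:
    """Write differential DVHs as CSV rows (roi, bin_lo_gy, bin_hi_gy, volume_fraction)."""
    import pandas as pd

    rows = []
    for dvh in dvhs:
        for lo, hi, vf in zip(dvh.bin_edges[:-1], dvh.bin_edges[1:], dvh.volume_fraction):
            rows.append({"roi": dvh.roi_name, "bin_lo_gy": lo, "bin_hi_gy": hi,
                         "volume_fraction": vf})
    pd.DataFrame(rows).to_csv(path, index=False)
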