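"""PET lesion metrics: SUVmax, metabolic tumor volume, total lesion glycolysis.

The volume of interest (VOI) is delineated by the fixed-fraction isocontour
convention standard in FDG-PET: voxels at or above a fraction of the lesion
SUVmax (40% by default), restricted to the 26-connected component that
contains the hottest voxel.  From the VOI,

    SUVmax  = max SUV over the mask            (g/cm^3)
    SUVmean = mean SUV over the mask           (g/cm^3)
    MTV     = voxel count x voxel volume       (cm^3)
    TLG     = SUVmean x MTV                    (g)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import PETVolume

__all__ = ["LesionVOI", "PETMetrics", "extract_voi", "compute_pet_metrics"]

# 26-neighborhood: thin isocontour shells stay connected on coarse grids
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LesionVOI:
    """A binary lesion mask on a PET volume, with the threshold that made it."""

    volume: PETVolume
    mask: np.ndarray
    threshold_fraction: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.volume.data.shape:
            raise ValueError("mask shape must match the volume")
        if not mask.any():
            raise ValueError("lesion mask is empty")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class PETMetrics:
    suvmax: float
    suvmean: float
    mtv_cm3: float
    tlg_g: float


def extract_voi(volume: PETVolume, threshold_fraction: float = 0.4) -> LesionVOI:
    """Isocontour VOI: voxels >= fraction x SUVmax, connected to the hottest voxel."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    data = volume.data
    suvmax = float(data.max())
    if suvmax <= 0:
        raise ValueError("volume has no voxel above zero uptake")
    supra = data >= threshold_fraction * suvmax
    if not supra.any():
        raise ValueError("no voxel reaches the threshold")
    labels, _ = ndimage.label(supra, structure=_STRUCTURE)
    hottest = np.unravel_index(int(np.argmax(data)), data.shape)
    mask = labels == labels[hottest]
    return LesionVOI(volume=volume, mask=mask, threshold_fraction=threshold_fraction)


def compute_pet_metrics(voi: LesionVOI) -> PETMetrics:
    """SUVmax / SUVmean / MTV / TLG of an extracted VOI."""
    vals = voi.volume.data[voi.mask]
    suvmax = float(vals.max())
    suvmean = float(vals.mean())
    mtv = float(vals.size) * voi.volume.voxel_volume_cm3
    return PETMetrics(suvmax=suvmax, suvmean=suvmean, mtv_cm3=mtv, tlg_g=suvmean * mtv)
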