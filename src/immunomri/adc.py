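"""ADC map estimation from multi-b-value diffusion-weighted MRI.

The apparent diffusion coefficient is obtained per voxel from the classic
monoexponential decay S(b) = S0 * exp(-b * ADC) by an ordinary least-squares
fit of ln S(b) against b; ADC is minus the slope. Default b-values are
0, 100 and 800 s/mm^2 and all of them enter the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["DwiSeries", "AdcMap", "fit_adc_map", "mean_adc", "delta_adc"]


@dataclass
class DwiSeries:
    """Signal volumes acquired at each b-value (s/mm^2), one common grid."""

    volumes: Sequence[np.ndarray]
    b_values: tuple[float, ...] = (0.0, 100.0, 800.0)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.b_values):
            raise ValueError(
                f"{len(self.volumes)} volumes but {len(self.b_values)} b-values"
            )
        if len(set(self.b_values)) < 2:
            raise ValueError("need at least two distinct b-values")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError(f"DWI volumes must share one shape, got {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")


@dataclass
class AdcMap:
    adc: np.ndarray  # mm^2/s, NaN where not fitted
    valid: np.ndarray  # voxels with a usable fit
    r2: np.ndarray | None = None  # per-voxel goodness of fit
    n_excluded_nonpositive: int = 0


def fit_adc_map(dwi: DwiSeries, mask: np.ndarray, with_r2: bool = False) -> AdcMap:
    """Voxelwise log-linear OLS fit of the monoexponential decay.

    Voxels with any nonpositive signal inside the mask are excluded (the log
    is undefined) rather than clipped; exclusion counts are logged.
    """
    mask = np.asarray(mask, bool)
    shape = dwi.volumes[0].shape
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match DWI shape {shape}")
    if not mask.any():
        raise ValueError("mask is empty")

    stack = np.stack([np.asarray(v, float) for v in dwi.volumes])  # (nb, z, y, x)
    valid = mask & np.all(stack > 0, axis=0)
    n_excl = int(mask.sum() - valid.sum())
    if n_excl:
        log.warning("fit_adc_map: excluded %d voxels with nonpositive signal", n_excl)
    if not valid.any():
        raise ValueError("no voxel with positive signal at every b-value; ADC not fittable")

    b = np.asarray(dwi.b_values, float)
    y = np.log(stack[:, valid])  # (nb, nvox)
    bc = b - b.mean()
    slope = (bc @ y) / (bc @ bc)
    adc = np.full(shape, np.nan)
    adc[valid] = -slope

    r2 = None
    if with_r2:
        yc = y - y.mean(axis=0)
        ss_tot = (yc**2).sum(axis=0)
        resid = yc - np.outer(bc, slope)
        ss_res = (resid**2).sum(axis=0)
        r2 = np.full(shape, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[valid] = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return AdcMap(adc=adc, valid=valid, r2=r2, n_excluded_nonpositive=n_excl)


def mean_adc(adc_map: AdcMap, roi: np.ndarray) -> float:
    """Arithmetic mean ADC (mm^2/s) over fitted ROI voxels."""
    roi = np.asarray(roi, bool)
    sel = adc_map.valid & roi
    if not sel.any():
        raise ValueError("no fitted voxels inside ROI")
    return float(adc_map.adc[sel].mean())


def delta_adc(pre: float, post: float) -> float:
    """Treatment change in mean ADC, post minus pre (mm^2/s)."""
    return post - pre
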