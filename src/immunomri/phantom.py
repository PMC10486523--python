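"""Digital DCE- and DW-MRI phantoms with known voxelwise ground truth.

The phantoms are ellipsoidal "tumors" embedded in a flat background. Inside
the tumor, true percent enhancement (PE, %), signal enhancement ratio (SER,
unitless) and apparent diffusion coefficient (ADC, mm^2/s) vary as linear
fields (a mean plus a spatial gradient). Signal volumes are constructed by
inverting the estimator definitions:

* DCE:  S1 = S0 * (1 + PE/100);  S2 = S0 + (S1 - S0) / SER
* DWI:  S(b) = S0 * exp(-b * ADC)

so that on a noiseless phantom every downstream estimator must reproduce the
generating field exactly. Gaussian or Rician noise can be added on top; Rician
is the physically appropriate model for MRI magnitude images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FieldParams",
    "PhantomSpec",
    "GroundTruth",
    "make_dce_phantom",
    "make_dwi_phantom",
]

#: minimum number of valid voxels a 3x3x3 hotspot window must contain
MIN_PEAK_WINDOW_VOXELS = 14


@dataclass(frozen=True)
class FieldParams:
    """A linear scalar field: ``mean + gradient . (voxel - tumor_center)``.

    ``gradient`` is per-voxel change along (z, y, x).
    """

    mean: float
    gradient: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def evaluate(self, coords: np.ndarray, center: Sequence[float]) -> np.ndarray:
        offs = coords - np.asarray(center, dtype=float)
        return self.mean + offs @ np.asarray(self.gradient, dtype=float)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, true parameter fields and noise model for one phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm, (z, y, x)
    tumor_center: tuple[float, float, float] | None = None  # voxel coords; default grid center
    tumor_radii: tuple[float, float, float] = (10.0, 12.0, 14.0)  # voxels
    pe_field: FieldParams = field(default_factory=lambda: FieldParams(200.0, (0.0, 2.0, 0.0)))
    ser_field: FieldParams = field(default_factory=lambda: FieldParams(1.5, (0.01, 0.0, 0.0)))
    adc_field: FieldParams = field(default_factory=lambda: FieldParams(1.0e-3, (0.0, 0.0, 5.0e-6)))
    s0_background: float = 100.0
    noise_model: Literal["none", "gaussian", "rician"] = "none"
    noise_sigma: float = 0.0  # signal units
    seed: int = 0

    @property
    def center(self) -> tuple[float, float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return tuple((n - 1) / 2.0 for n in self.grid_shape)

    def validate(self) -> None:
        if any(n < 3 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 3 per axis, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError(f"tumor_radii must be positive, got {self.tumor_radii}")
        c = self.center
        for ax, (ci, ri, ni) in enumerate(zip(c, self.tumor_radii, self.grid_shape)):
            if ci - ri < 0 or ci + ri > ni - 1:
                raise ValueError(
                    f"tumor ellipsoid exceeds grid along axis {ax}: "
                    f"center {ci}, radius {ri}, extent {ni}"
                )
        if self.s0_background <= 0:
            raise ValueError("s0_background must be positive")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class GroundTruth:
    """True parameter maps and the lesion-level summaries they imply.

    DCE phantoms populate the PE/SER family; DWI phantoms populate the ADC
    family. ``ftv_true`` uses the same PE >= 50% rule as the estimator;
    ``wf_true`` the PE >= 50% and SER >= 1.1 rule, over all tumor voxels.
    """

    pe_true: np.ndarray | None = None  # % per voxel (NaN outside tumor)
    ser_true: np.ndarray | None = None  # unitless (NaN outside tumor)
    adc_true: np.ndarray | None = None  # mm^2/s (NaN outside tumor)
    ftv_true: float | None = None  # cm^3
    wf_true: float | None = None  # fraction in [0, 1]
    peak_pe_true: float | None = None
    peak_ser_true: float | None = None
    mean_adc_true: float | None = None


def _tumor_mask(spec: PhantomSpec) -> np.ndarray:
    coords = np.indices(spec.grid_shape, dtype=float)
    c = np.asarray(spec.center)
    r = np.asarray(spec.tumor_radii)
    norm = sum(((coords[i] - c[i]) / r[i]) ** 2 for i in range(3))
    return norm <= 1.0


def _coords_of(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(mask).astype(float)


def _apply_noise(vol: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none" or spec.noise_sigma == 0.0:
        return vol
    if spec.noise_model == "gaussian":
        return vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    # Rician: magnitude of a complex signal with iid Gaussian noise per channel
    re = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    im = rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    return np.hypot(re, im)


def _brute_peak_mean(
    values: np.ndarray,
    valid: np.ndarray,
    roi: np.ndarray,
    min_valid: int = MIN_PEAK_WINDOW_VOXELS,
) -> float:
    """Exhaustive 3x3x3 hotspot search (loop-based; used only for ground truth).

    A window is admissible when its center lies in the ROI, it fits inside
    the grid, and it covers at least ``min_valid`` valid voxels. Returns the
    highest in-window mean of valid voxels.
    """
    nz, ny, nx = values.shape
    best = -np.inf
    vals = np.where(valid, values, 0.0)
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                if not roi[z, y, x]:
                    continue
                w = valid[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2]
                k = int(w.sum())
                if k < min_valid:
                    continue
                m = vals[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2].sum() / k
                if m > best:
                    best = m
    if not np.isfinite(best):
        raise ValueError("no admissible 3x3x3 hotspot window in phantom tumor")
    return float(best)


def make_dce_phantom(spec: PhantomSpec):
    """Build a three-timepoint DCE series with exact kinetic ground truth.

    Returns ``(series, roi, truth)`` where ``series`` is a
    :class:`~immunomri.dce.DceSeries`, ``roi`` the boolean tumor mask and
    ``truth`` a :class:`GroundTruth`.
    """
    from .dce import DceSeries  # local import to avoid a cycle

    spec.validate()
    roi = _tumor_mask(spec)
    coords = _coords_of(roi)

    pe_vals = spec.pe_field.evaluate(coords, spec.center)
    ser_vals = spec.ser_field.evaluate(coords, spec.center)
    if np.any(pe_vals <= 0):
        raise ValueError("pe_field must be strictly positive inside the tumor")
    if np.any(ser_vals <= 0):
        raise ValueError("ser_field must be strictly positive inside the tumor (zero is undefined)")

    pe_true = np.full(spec.grid_shape, np.nan)
    ser_true = np.full(spec.grid_shape, np.nan)
    idx = tuple(coords.astype(int).T)
    pe_true[idx] = pe_vals
    ser_true[idx] = ser_vals

    s0 = np.full(spec.grid_shape, spec.s0_background, dtype=float)
    s1 = s0.copy()
    s2 = s0.copy()
    s1[idx] = s0[idx] * (1.0 + pe_vals / 100.0)
    s2[idx] = s0[idx] + (s1[idx] - s0[idx]) / ser_vals

    rng = np.random.default_rng(spec.seed)
    s0n, s1n, s2n = (_apply_noise(v, spec, rng) for v in (s0, s1, s2))
    series = DceSeries(s0=s0n, s1=s1n, s2=s2n, voxel_size=spec.voxel_size)

    n_tumor = int(roi.sum())
    enhancing = pe_true[idx] >= 50.0
    washout = enhancing & (ser_true[idx] >= 1.1)
    voxel_mm3 = float(np.prod(spec.voxel_size))
    truth = GroundTruth(
        pe_true=pe_true,
        ser_true=ser_true,
        ftv_true=float(enhancing.sum()) * voxel_mm3 / 1000.0,
        wf_true=float(washout.sum()) / n_tumor,
        peak_pe_true=_brute_peak_mean(np.nan_to_num(pe_true), roi, roi),
        peak_ser_true=_brute_peak_mean(
            np.nan_to_num(ser_true), roi & (np.nan_to_num(pe_true) >= 50.0), roi
        ),
    )
    return series, roi, truth


def make_dwi_phantom(spec: PhantomSpec, b_values: Sequence[float] = (0.0, 100.0, 800.0)):
    """Build a multi-b-value DWI series with exact ADC ground truth.

    Background voxels decay with a fixed free-water-like ADC of
    2.0e-3 mm^2/s so that every voxel carries a positive, physically
    sensible signal. Returns ``(series, roi, truth)``.
    """
    from .adc import DwiSeries

    spec.validate()
    if len(set(b_values)) < 2:
        raise ValueError("need at least two distinct b-values")
    roi = _tumor_mask(spec)
    coords = _coords_of(roi)
    idx = tuple(coords.astype(int).T)

    adc_vals = spec.adc_field.evaluate(coords, spec.center)
    if np.any(adc_vals <= 0):
        raise ValueError("adc_field must be strictly positive inside the tumor")

    adc_true = np.full(spec.grid_shape, np.nan)
    adc_true[idx] = adc_vals
    adc_full = np.full(spec.grid_shape, 2.0e-3)
    adc_full[idx] = adc_vals

    rng = np.random.default_rng(spec.seed)
    volumes = []
    for b in b_values:
        vol = spec.s0_background * np.exp(-float(b) * adc_full)
        volumes.append(_apply_noise(vol, spec, rng))
    series = DwiSeries(volumes=volumes, b_values=tuple(float(b) for b in b_values),
                       voxel_size=spec.voxel_size)
    truth = GroundTruth(adc_true=adc_true, mean_adc_true=float(adc_vals.mean()))
    return series, roi, truth
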