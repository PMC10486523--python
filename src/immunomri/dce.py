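"""Voxelwise DCE-MRI kinetic mapping and lesion-level feature extraction.

Kinetics of contrast uptake and clearance are summarized per voxel by the
percent enhancement PE = (S1 - S0)/S0 x 100 and the signal enhancement ratio
SER = (S1 - S0)/(S2 - S0), where S0, S1, S2 are the pre-contrast, initial
(~120 s) and delayed (360-480 s) post-contrast signals. Lesion-level features
follow the standard breast-MRI definitions: functional tumor volume (FTV) is
the summed volume of voxels with PE >= 50%, the washout fraction (WF) the
fraction of all tumor voxels with PE >= 50% and SER >= 1.1, and the peak PE /
peak SER are the highest 3x3x3-window means of the respective maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "DceSeries",
    "KineticMaps",
    "KineticFeatureSet",
    "compute_pe_map",
    "compute_ser_map",
    "compute_ftv",
    "compute_washout_fraction",
    "find_peak_region",
    "summarize_dce",
    "delta_features",
    "PE_THRESHOLD",
    "SER_THRESHOLD",
]

PE_THRESHOLD = 50.0  # %, enhancing-voxel cut for FTV / SER validity
SER_THRESHOLD = 1.1  # washout cut
EPS_REL = 1e-6  # relative epsilon (vs ROI-median S0) for degenerate denominators
MIN_PEAK_WINDOW_VOXELS = 14  # >= 14/27 valid voxels per 3x3x3 hotspot window


def _check_mask(mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != shape:
        raise ValueError(f"ROI mask shape {mask.shape} does not match series shape {shape}")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return mask


@dataclass
class DceSeries:
    """Registered pre-contrast (s0), initial (s1) and delayed (s2) volumes."""

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    voxel_size: tuple[float, float, float]  # mm, (z, y, x)

    def __post_init__(self) -> None:
        if not (self.s0.shape == self.s1.shape == self.s2.shape):
            raise ValueError("DCE volumes must share one shape")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")


@dataclass
class KineticMaps:
    """PE (%) and SER maps with their validity masks.

    ``pe`` is NaN outside ``pe_valid``; ``ser`` is NaN outside ``ser_valid``.
    SER validity is a subset of the PE >= threshold region: voxels with a
    degenerate delayed-phase denominator keep their PE (and still count
    toward FTV) but carry no SER.
    """

    pe: np.ndarray
    ser: np.ndarray
    pe_valid: np.ndarray
    ser_valid: np.ndarray
    n_excluded_s0: int = 0
    n_excluded_ser_denom: int = 0


@dataclass
class KineticFeatureSet:
    """Lesion-level DCE (and optionally ADC) summary for one timepoint."""

    ftv: float  # cm^3
    wf: float  # fraction in [0, 1]
    peak_pe: float  # %
    peak_ser: float  # unitless
    peak_pe_location: tuple[int, int, int]
    peak_ser_location: tuple[int, int, int]
    mean_adc: float | None = None  # mm^2/s
    timepoint_label: str = ""

    def as_dict(self) -> dict[str, float]:
        d = {"ftv": self.ftv, "wf": self.wf, "peak_pe": self.peak_pe, "peak_ser": self.peak_ser}
        if self.mean_adc is not None:
            d["mean_adc"] = self.mean_adc
        return d


def compute_pe_map(series: DceSeries, roi: np.ndarray) -> KineticMaps:
    """Percent-enhancement map over the ROI.

    Voxels whose baseline signal is at or below ``EPS_REL`` x the ROI-median
    S0 are excluded from the valid mask (the ratio is undefined there).
    """
    roi = _check_mask(roi, series.s0.shape)
    eps = EPS_REL * float(np.median(series.s0[roi]))
    valid = roi & (series.s0 > eps)
    n_excl = int(roi.sum() - valid.sum())
    if n_excl:
        log.warning("compute_pe_map: excluded %d ROI voxels with S0 <= %.3g", n_excl, eps)
    if not valid.any():
        raise ValueError("all ROI voxels have degenerate baseline signal; no PE computable")
    pe = np.full(series.s0.shape, np.nan)
    pe[valid] = (series.s1[valid] - series.s0[valid]) / series.s0[valid] * 100.0
    ser = np.full(series.s0.shape, np.nan)
    return KineticMaps(pe=pe, ser=ser, pe_valid=valid,
                       ser_valid=np.zeros_like(valid), n_excluded_s0=n_excl)


def compute_ser_map(
    series: DceSeries,
    roi: np.ndarray,
    maps: KineticMaps,
    pe_threshold: float = PE_THRESHOLD,
) -> KineticMaps:
    """Fill the SER part of ``maps`` (in place) for voxels with PE >= threshold.

    Voxels whose delayed-phase denominator |S2 - S0| is degenerate are dropped
    from SER validity only; they keep their PE.
    """
    roi = _check_mask(roi, series.s0.shape)
    eps = EPS_REL * float(np.median(series.s0[roi]))
    candidates = maps.pe_valid & (np.nan_to_num(maps.pe, nan=-np.inf) >= pe_threshold)
    denom = series.s2 - series.s0
    ok = candidates & (np.abs(denom) > eps)
    n_excl = int(candidates.sum() - ok.sum())
    if n_excl:
        log.warning("compute_ser_map: excluded %d voxels with |S2 - S0| <= %.3g", n_excl, eps)
    ser = np.full(series.s0.shape, np.nan)
    ser[ok] = (series.s1[ok] - series.s0[ok]) / denom[ok]
    maps.ser = ser
    maps.ser_valid = ok
    maps.n_excluded_ser_denom = n_excl
    return maps


def compute_ftv(
    maps: KineticMaps,
    voxel_size: tuple[float, float, float],
    pe_threshold: float = PE_THRESHOLD,
) -> float:
    """Functional tumor volume (cm^3): voxel volume x count of PE >= threshold."""
    n = int((maps.pe_valid & (np.nan_to_num(maps.pe, nan=-np.inf) >= pe_threshold)).sum())
    return n * float(np.prod(voxel_size)) / 1000.0


def compute_washout_fraction(
    maps: KineticMaps,
    roi: np.ndarray,
    pe_threshold: float = PE_THRESHOLD,
    ser_threshold: float = SER_THRESHOLD,
) -> float:
    """Fraction of all ROI voxels with PE >= threshold and SER >= threshold."""
    roi = _check_mask(roi, maps.pe.shape)
    washout = (
        maps.ser_valid
        & (np.nan_to_num(maps.pe, nan=-np.inf) >= pe_threshold)
        & (np.nan_to_num(maps.ser, nan=-np.inf) >= ser_threshold)
    )
    return float(washout.sum()) / float(roi.sum())


def find_peak_region(
    values: np.ndarray,
    valid: np.ndarray,
    roi: np.ndarray,
    min_valid: int = MIN_PEAK_WINDOW_VOXELS,
) -> tuple[float, tuple[int, int, int]]:
    """Hotspot search: the 3x3x3 window with the highest mean of valid voxels.

    Admissible windows have their center voxel in the ROI, lie fully inside
    the image bounds, and contain at least ``min_valid`` valid voxels. Ties
    break to the lowest (z, y, x) center. Returns ``(peak mean, center)``.
    """
    roi = _check_mask(roi, values.shape)
    valid = np.asarray(valid, bool)
    vals = np.where(valid, values, 0.0)
    kernel = np.ones((3, 3, 3))
    sums = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(valid.astype(float), kernel, mode="constant", cval=0.0)
    counts = np.rint(counts)

    in_bounds = np.zeros_like(roi)
    in_bounds[1:-1, 1:-1, 1:-1] = True
    admissible = roi & in_bounds & (counts >= min_valid)
    if not admissible.any():
        raise ValueError("no admissible 3x3x3 hotspot window (ROI too small or too few valid voxels)")
    means = np.full(values.shape, -np.inf)
    means[admissible] = sums[admissible] / counts[admissible]
    flat = int(np.argmax(means))  # first max in C order == lowest (z, y, x)
    center = np.unravel_index(flat, values.shape)
    return float(means[center]), tuple(int(c) for c in center)


def summarize_dce(
    series: DceSeries,
    roi: np.ndarray,
    pe_threshold: float = PE_THRESHOLD,
    ser_threshold: float = SER_THRESHOLD,
    timepoint_label: str = "",
) -> KineticFeatureSet:
    """Full kinetic summary of one timepoint: FTV, WF, peak PE, peak SER."""
    maps = compute_pe_map(series, roi)
    maps = compute_ser_map(series, roi, maps, pe_threshold=pe_threshold)
    peak_pe, pe_loc = find_peak_region(np.nan_to_num(maps.pe), maps.pe_valid, roi)
    peak_ser, ser_loc = find_peak_region(np.nan_to_num(maps.ser), maps.ser_valid, roi)
    return KineticFeatureSet(
        ftv=compute_ftv(maps, series.voxel_size, pe_threshold=pe_threshold),
        wf=compute_washout_fraction(maps, roi, pe_threshold=pe_threshold,
                                    ser_threshold=ser_threshold),
        peak_pe=peak_pe,
        peak_ser=peak_ser,
        peak_pe_location=pe_loc,
        peak_ser_location=ser_loc,
        timepoint_label=timepoint_label,
    )


def delta_features(pre: KineticFeatureSet | Mapping[str, float],
                   post: KineticFeatureSet | Mapping[str, float]) -> dict[str, float]:
    """Treatment change per feature, post minus pre.

    Accepts feature sets or plain name->value mappings; the two must cover
    the same features.
    """
    pre_d = pre.as_dict() if isinstance(pre, KineticFeatureSet) else dict(pre)
    post_d = post.as_dict() if isinstance(post, KineticFeatureSet) else dict(post)
    if set(pre_d) != set(post_d):
        raise ValueError(
            f"mismatched feature sets: pre has {sorted(pre_d)}, post has {sorted(post_d)}"
        )
    return {name: post_d[name] - pre_d[name] for name in pre_d}
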