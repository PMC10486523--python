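"""NIfTI volume and tabular I/O helpers.

Volumes travel as NIfTI-1 with voxel spacing carried in the header zooms;
tables as UTF-8 comma-separated files with a header row. Masks must share
grid shape and spacing with their series — no implicit resampling happens
anywhere in this package.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_table",
    "write_table",
    "read_bvals",
    "check_same_grid",
]


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a 3-D NIfTI volume; returns (data, voxel spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def write_volume(data: np.ndarray, voxel_size, path) -> None:
    """Write a volume as NIfTI-1 with the spacing recorded in the header."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.diag([*voxel_size, 1.0]))
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))


def read_mask(path, expect_shape=None) -> np.ndarray:
    data, _ = read_volume(path)
    if expect_shape is not None and data.shape != tuple(expect_shape):
        raise ValueError(
            f"mask {path} has shape {data.shape}, series has shape {tuple(expect_shape)}"
        )
    return data > 0.5


def check_same_grid(name_a: str, shape_a, name_b: str, shape_b) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"{name_a} shape {tuple(shape_a)} != {name_b} shape {tuple(shape_b)}")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")


def read_bvals(path, n_expected: int | None = None) -> tuple[float, ...]:
    """Read a whitespace/comma-separated b-value sidecar text file."""
    text = Path(path).read_text().replace(",", " ")
    vals = tuple(float(tok) for tok in text.split())
    if n_expected is not None and len(vals) != n_expected:
        raise ValueError(f"{path}: expected {n_expected} b-values, found {len(vals)}")
    return vals
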