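"""3D volumes, label maps, and NIfTI-1 I/O.

A :class:`Volume` is a real (H, W, S) intensity array; a :class:`LabelMap` is
a congruent integer array with tissue classes 0 background, 1 CSF, 2 GM,
3 WM.  Coordinates are 0-based and row-major; the slice axis is the third
array axis, and "axial" means slicing along it.  Files are NIfTI-1
(``.nii`` / ``.nii.gz``) via nibabel; the viewing plane is carried in the
header description field so a write/read round trip is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PLANES", "CLASS_NAMES", "Volume", "LabelMap",
    "read_volume", "read_labelmap", "write_volume", "write_labelmap",
]

PLANES = ("axial", "coronal", "sagittal")

#: Fixed project-wide class channel order.
CLASS_NAMES = ("background", "CSF", "GM", "WM")


def _check_plane(plane: str) -> str:
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    return plane


@dataclass
class Volume:
    """A 3D grayscale image with plane metadata."""

    data: np.ndarray
    plane: str = "axial"
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("Volume intensities must be finite")
        _check_plane(self.plane)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


@dataclass
class LabelMap:
    """An integer tissue class map congruent with a Volume."""

    data: np.ndarray
    plane: str = "axial"
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap values must be integers")
        lo, hi = self.data.min(), self.data.max()
        if lo < 0 or hi >= len(CLASS_NAMES):
            raise ValueError(
                f"LabelMap values must lie in [0, {len(CLASS_NAMES) - 1}], "
                f"found range [{lo}, {hi}]")
        _check_plane(self.plane)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# NIfTI-1 I/O

def _affine(spacing) -> np.ndarray:
    return np.diag([*(spacing or (1.0, 1.0, 1.0)), 1.0])


def _write(data: np.ndarray, plane: str, spacing, path) -> None:
    img = nib.Nifti1Image(data, _affine(spacing))
    img.header["descrip"] = f"plane={plane}".encode()
    nib.save(img, str(path))


def _read(path) -> tuple[np.ndarray, str, tuple[float, float, float] | None]:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(
            f"{path}: expected a 3D volume, got {data.ndim}D {data.shape}")
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    plane = "axial"
    if descrip.startswith("plane="):
        candidate = descrip.split("=", 1)[1]
        if candidate in PLANES:
            plane = candidate
    zooms = img.header.get_zooms()[:3]
    return data, plane, tuple(float(z) for z in zooms)


def write_volume(vol: Volume, path) -> None:
    _write(vol.data.astype(np.float32), vol.plane, vol.spacing, path)


def read_volume(path) -> Volume:
    data, plane, spacing = _read(path)
    return Volume(data=np.asarray(data, dtype=np.float32), plane=plane,
                  spacing=spacing)


def write_labelmap(lab: LabelMap, path) -> None:
    _write(lab.data.astype(np.int16), lab.plane, lab.spacing, path)


def read_labelmap(path) -> LabelMap:
    data, plane, spacing = _read(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise IOError(f"{path}: label maps must be integer-typed NIfTI")
    return LabelMap(data=data.astype(np.int16), plane=plane, spacing=spacing)
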