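"""Volume -> model-ready patches and back.

The training pipeline standardizes every slice to a fixed square canvas by
zero padding (never resampling), extracts a subset of informative slices at a
constant interval, and divides each padded slice into uniform patches —
either the four non-overlapping quadrants or a dense overlapping sliding
window.  Every step records enough placement metadata for exact inversion:
``reassemble`` places per-patch predictions back, fuses overlaps by averaging
softmax probabilities before the argmax, and crops the padding away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .volume import Volume, PLANES

__all__ = [
    "PadRecord", "PatchGrid",
    "normalize_intensity", "pad_to_square", "crop_pad",
    "extract_slices", "reslice", "divide_patches", "reassemble",
]


class PadRecord(NamedTuple):
    """Zero padding applied to one slice: rows/cols added per edge."""
    top: int
    bottom: int
    left: int
    right: int


def normalize_intensity(data: np.ndarray) -> np.ndarray:
    """Per-volume min-max normalization to [0, 1] (constant input -> zeros)."""
    data = np.asarray(data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def pad_to_square(slice2d: np.ndarray, target: int = 256):
    """Zero-pad a 2D slice to ``target x target``.

    The padding is split evenly per axis; an odd difference puts the extra
    pixel on the bottom/right.  Returns ``(padded, PadRecord)``; the record
    allows exact cropping back.  Dimensions exceeding ``target`` are an
    error — this pipeline never resamples.
    """
    slice2d = np.asarray(slice2d)
    h, w = slice2d.shape
    if h > target or w > target:
        raise ValueError(
            f"slice {h}x{w} exceeds the {target}x{target} canvas; "
            "resampling is not performed")
    top = (target - h) // 2
    left = (target - w) // 2
    pad = PadRecord(top, target - h - top, left, target - w - left)
    out = np.pad(slice2d, ((pad.top, pad.bottom), (pad.left, pad.right)))
    return out, pad


def crop_pad(slice2d: np.ndarray, pad: PadRecord) -> np.ndarray:
    """Exact inverse of :func:`pad_to_square`."""
    h, w = slice2d.shape[-2:]
    return slice2d[..., pad.top:h - pad.bottom, pad.left:w - pad.right]


def extract_slices(vol: "Volume | int", spacing: int = 3,
                   count: int = 48, start: int | None = None) -> np.ndarray:
    """Indices of ``count`` slices at a constant interval, window centred.

    Slices near the start and end of a brain volume carry little anatomy and
    neighbouring slices are nearly identical, so a centred arithmetic
    subsequence with step ``spacing`` is retained.  ``start`` overrides the
    centred placement.
    """
    n_slices = vol if isinstance(vol, int) else vol.n_slices
    if spacing < 1 or count < 1:
        raise ValueError("spacing and count must be >= 1")
    span = spacing * (count - 1) + 1
    if span > n_slices:
        raise ValueError(
            f"volume too thin: {count} slices spaced by {spacing} need at "
            f"least S = {span}, got S = {n_slices}")
    if start is None:
        start = (n_slices - span) // 2
    if start < 0 or start + span > n_slices:
        raise ValueError(f"start {start} places the window outside [0, {n_slices})")
    return start + spacing * np.arange(count)


# Axis permutation taking an axial-stored (H, W, S) array into each viewing
# plane, chosen so each output's first two axes are the displayed slice.
_PERM_FROM_AXIAL = {
    "axial": (0, 1, 2),
    "coronal": (1, 2, 0),   # fix a row of the axial slice -> W x S images
    "sagittal": (2, 0, 1),  # fix a column of the axial slice -> S x H images
}


def reslice(vol: Volume, plane: str) -> Volume:
    """Re-express a volume in another viewing plane by pure axis permutation.

    No interpolation is performed; every voxel value is preserved, and
    reslicing back returns the original array exactly.
    """
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    inv = np.argsort(_PERM_FROM_AXIAL[vol.plane])
    perm = tuple(np.asarray(inv)[list(_PERM_FROM_AXIAL[plane])])
    out = type(vol)(data=np.ascontiguousarray(vol.data.transpose(perm)),
                    plane=plane, spacing=None if vol.spacing is None else
                    tuple(np.asarray(vol.spacing)[list(perm)]))
    return out


@dataclass
class PatchGrid:
    """Uniform 2D patches plus placement metadata for exact reassembly."""

    patches: np.ndarray                      # (n, P, P)
    placements: list[tuple[int, int, int]]   # (slice index, row, col) offsets
    pad: PadRecord
    original_shape: tuple[int, int]          # pre-padding (H, W)
    padded_side: int
    mode: str                                # "quadrant" | "overlap"
    stride: int | None = None

    @property
    def patch_size(self) -> int:
        return self.patches.shape[-1]

    def to_json(self) -> str:
        return json.dumps({
            "placements": [list(p) for p in self.placements],
            "pad": list(self.pad),
            "original_shape": list(self.original_shape),
            "padded_side": self.padded_side,
            "mode": self.mode,
            "stride": self.stride,
            "patch_size": self.patch_size,
        })

    def save(self, stem) -> None:
        """Write the patch stack (`<stem>.npy`) and a JSON sidecar."""
        np.save(f"{stem}.npy", self.patches)
        with open(f"{stem}.json", "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, stem) -> "PatchGrid":
        patches = np.load(f"{stem}.npy")
        with open(f"{stem}.json") as fh:
            doc = json.load(fh)
        return cls(patches=patches,
                   placements=[tuple(p) for p in doc["placements"]],
                   pad=PadRecord(*doc["pad"]),
                   original_shape=tuple(doc["original_shape"]),
                   padded_side=doc["padded_side"],
                   mode=doc["mode"], stride=doc["stride"])


def divide_patches(slice2d: np.ndarray, patch_size: int = 128,
                   mode: str = "quadrant", stride: int = 8,
                   slice_index: int = 0,
                   pad: PadRecord | None = None,
                   original_shape: tuple[int, int] | None = None) -> PatchGrid:
    """Divide a square slice into uniform patches.

    ``quadrant`` tiles the slice with non-overlapping patches in row-major
    order (top-left, top-right, bottom-left, bottom-right on a 2x2 grid);
    ``overlap`` slides a window at the given stride.  ``pad`` and
    ``original_shape`` carry the provenance of a previously padded slice so
    that reassembly can crop back; they default to "no padding".
    """
    slice2d = np.asarray(slice2d)
    if slice2d.ndim != 2 or slice2d.shape[0] != slice2d.shape[1]:
        raise ValueError(f"expected a square 2D slice, got {slice2d.shape}")
    side = slice2d.shape[0]
    if mode == "quadrant":
        if side % patch_size:
            raise ValueError(
                f"side {side} is not divisible by patch size {patch_size}")
        offsets = range(0, side, patch_size)
        stride_out = None
    elif mode == "overlap":
        if patch_size > side:
            raise ValueError("patch size exceeds the slice")
        if (side - patch_size) % stride:
            raise ValueError(
                f"stride {stride} does not tile side {side} with patch "
                f"{patch_size}: (side - patch) must be divisible by stride")
        offsets = range(0, side - patch_size + 1, stride)
        stride_out = stride
    else:
        raise ValueError(f"unknown mode {mode!r}")

    patches, placements = [], []
    for r in offsets:
        for c in offsets:
            patches.append(slice2d[r:r + patch_size, c:c + patch_size])
            placements.append((slice_index, r, c))
    return PatchGrid(
        patches=np.stack(patches),
        placements=placements,
        pad=pad if pad is not None else PadRecord(0, 0, 0, 0),
        original_shape=(original_shape if original_shape is not None
                        else (side, side)),
        padded_side=side, mode=mode, stride=stride_out)


def reassemble(grid: PatchGrid, per_patch: np.ndarray | None = None):
    """Place per-patch predictions back onto the (cropped) original slice.

    ``per_patch`` may be the raw patch values, shape (n, P, P) — placed back
    (averaging where windows overlap) and cropped, reproducing the input
    exactly in quadrant mode — or per-patch class probabilities, shape
    (n, C, P, P): probabilities are averaged per pixel over every covering
    window, then argmaxed into a label slice.  Defaults to the grid's own
    patches.
    """
    if per_patch is None:
        per_patch = grid.patches
    per_patch = np.asarray(per_patch)
    n, p = per_patch.shape[0], per_patch.shape[-1]
    if n != len(grid.placements) or p != grid.patch_size:
        raise ValueError(
            f"{n} predictions of size {p} do not match the grid "
            f"({len(grid.placements)} patches of size {grid.patch_size})")
    probs = per_patch.ndim == 4
    side = grid.padded_side
    shape = (per_patch.shape[1], side, side) if probs else (side, side)
    acc = np.zeros(shape, dtype=np.float64)
    cover = np.zeros((side, side), dtype=np.int64)
    for patch, (_s, r, c) in zip(per_patch, grid.placements):
        acc[..., r:r + p, c:c + p] += patch
        cover[r:r + p, c:c + p] += 1
    if (cover == 0).any():
        raise ValueError("patch placements do not cover the padded slice")
    acc /= cover
    acc = crop_pad(acc, grid.pad)
    if probs:
        return acc.argmax(axis=0)
    return acc.astype(per_patch.dtype)
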