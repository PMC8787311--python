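"""Image-stack I/O and elementary brightfield transforms.

A z-stack of Golgi-impregnated tissue is held as an :class:`ImageStack`:
a ``[z][y][x]`` voxel grid plus the physical voxel spacing.  Stacks are
stored on disk as multi-page TIFF (one page per focal plane, page order =
z order) with a JSON sidecar carrying the spacing, because plain TIFF has
no portable z-spacing tag.

The transforms here are the elementary ones a brightfield workflow needs
before any segmentation: conversion to 8-bit monochrome, luminosity
inversion (dark silver-impregnated structure becomes bright signal), and
the 2D composite across focal planes.  For brightfield the composite
defaults to the per-pixel *minimum* across z — the darkest value at each
pixel — so in-focus dark structure from any plane survives; literal
summation is available but saturates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Literal

import numpy as np
import tifffile

__all__ = [
    "VoxelSpacing",
    "ImageStack",
    "read_stack",
    "write_stack",
    "to_monochrome8",
    "invert_luminosity",
    "composite_projection",
]

#: ITU-R 601 luminance weights for RGB collapse.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in micrometres; dz may differ from dx, dy."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self}")

    def as_dict(self) -> dict[str, float]:
        return {"dx": self.dx, "dy": self.dy, "dz": self.dz}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "VoxelSpacing":
        return cls(dx=float(d["dx"]), dy=float(d["dy"]), dz=float(d["dz"]))


@dataclass
class ImageStack:
    """A 3D grayscale (or RGB, pre-conversion) voxel grid with spacing.

    ``voxels`` is ``[z][y][x]`` (grayscale) or ``[z][y][x][c]`` (RGB before
    :func:`to_monochrome8`).  Intensities are uint8 in 0..255, uint16, or
    float in 0..1.  Physical coordinate of voxel (i, j, k) is
    (k*dx, j*dy, i*dz), voxel-centre convention, origin at the first
    slice's top-left.
    """

    voxels: np.ndarray
    spacing: VoxelSpacing
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim not in (3, 4):
            raise ValueError(f"expected [z][y][x] or [z][y][x][c] array, got ndim={v.ndim}")
        if v.shape[0] < 1 or v.shape[1] < 1 or v.shape[2] < 1:
            raise ValueError(f"stack must have at least one nonempty slice, got shape {v.shape}")
        if v.ndim == 4 and v.shape[3] not in (3, 4):
            raise ValueError(f"channel axis must have 3 or 4 samples, got {v.shape[3]}")
        if np.issubdtype(v.dtype, np.floating):
            lo, hi = float(v.min()), float(v.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"float stack must lie in [0, 1], got range [{lo}, {hi}]")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def is_8bit(self) -> bool:
        return self.voxels.dtype == np.uint8 and self.voxels.ndim == 3


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_stack(path: str | Path, spacing: VoxelSpacing | None = None) -> ImageStack:
    """Read a single- or multi-page TIFF as an :class:`ImageStack`.

    ``spacing`` may be omitted when a JSON sidecar written by
    :func:`write_stack` sits next to the file.  RGB input is kept as-is;
    callers convert explicitly with :func:`to_monochrome8`.
    """
    path = Path(path)
    if spacing is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"no spacing given and no sidecar at {sidecar}")
        spacing = VoxelSpacing.from_dict(json.loads(sidecar.read_text()))
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise ValueError(f"{path}: TIFF contains no pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: pages have inconsistent dimensions {sorted(shapes)}")
    vox = np.stack(pages, axis=0)
    if vox.ndim == 4 and vox.shape[0] == 1 and vox.shape[3] not in (3, 4):
        raise ValueError(f"{path}: unsupported sample layout {vox.shape}")
    return ImageStack(vox, spacing, meta={"source": str(path), "bit_depth": vox.dtype.name})


def write_stack(stack: ImageStack, path: str | Path, *, quantize: bool = False) -> Path:
    """Write a stack as an uncompressed multi-page TIFF plus JSON sidecar.

    Float stacks are only written when ``quantize=True`` (scaled to 8-bit);
    writing floats silently would break round-trip identity guarantees.
    """
    path = Path(path)
    vox = stack.voxels
    if np.issubdtype(vox.dtype, np.floating):
        if not quantize:
            raise ValueError("float stack: pass quantize=True to write as 8-bit")
        vox = np.clip(np.rint(vox * 255.0), 0, 255).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vox, photometric="minisblack" if vox.ndim == 3 else "rgb")
    sidecar = {**stack.spacing.as_dict(), "bit_depth": vox.dtype.name}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def to_monochrome8(stack: ImageStack) -> ImageStack:
    """Convert to 8-bit single-channel.

    RGB collapses by ITU-R 601 luminance; 16-bit rescales by a full-range
    linear map (65535 -> 255); floats in 0..1 scale by 255.  Already-8-bit
    grayscale input is returned unchanged.
    """
    v = stack.voxels
    if v.ndim == 4:  # RGB(A): drop alpha, collapse by luminance
        rgb = v[..., :3].astype(np.float64)
        v = rgb @ _LUMA_WEIGHTS
        if stack.voxels.dtype == np.uint16:
            v = v / 257.0
        elif np.issubdtype(stack.voxels.dtype, np.floating):
            v = v * 255.0
        v = np.clip(np.rint(v), 0, 255).astype(np.uint8)
    elif v.dtype == np.uint8:
        return stack
    elif v.dtype == np.uint16:
        v = np.rint(v.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    elif np.issubdtype(v.dtype, np.floating):
        v = np.clip(np.rint(v * 255.0), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unsupported dtype {v.dtype}")
    meta = dict(stack.meta)
    meta["bit_depth_of_origin"] = stack.voxels.dtype.name
    return ImageStack(v, stack.spacing, meta)


def invert_luminosity(stack: ImageStack) -> ImageStack:
    """Invert an 8-bit stack: v -> 255 - v.  An involution."""
    if not stack.is_8bit:
        raise ValueError("invert_luminosity requires an 8-bit grayscale stack")
    return replace(stack, voxels=(255 - stack.voxels))


def composite_projection(
    stack: ImageStack,
    mode: Literal["min", "mean", "sum-clipped"] = "min",
) -> np.ndarray:
    """Composite all focal planes into one 2D image.

    ``min`` (default) keeps the darkest value across depth — the brightfield
    analogue of focal-plane compositing, since impregnated structure is dark
    on a bright ground.  ``mean`` averages; ``sum-clipped`` sums and clips
    to the 8-bit range.
    """
    v = stack.voxels
    if mode == "min":
        return v.min(axis=0)
    if mode == "mean":
        out = v.mean(axis=0)
        return np.rint(out).astype(v.dtype) if np.issubdtype(v.dtype, np.integer) else out
    if mode == "sum-clipped":
        out = v.sum(axis=0, dtype=np.float64)
        if v.dtype == np.uint8:
            return np.clip(out, 0, 255).astype(np.uint8)
        return out
    raise ValueError(f"unknown composite mode {mode!r}")
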