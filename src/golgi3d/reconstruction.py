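"""3D spine-reconstruction pipeline for brightfield z-stacks.

Turns a raw 8-bit brightfield stack (dark impregnated structure on a
bright ground) into a clean binary volume of dendritic shaft + spines by
the following staged procedure:

(a) outlier removal — local-median replacement of voxels deviating more
    than ``k`` robust standard deviations from their neighbourhood median;
(b) edge enhancement — unsharp masking followed by an edge-aware
    recursive domain-transform smoothing pass;
(c) binarization — per-slice adaptive (local-mean) thresholding;
(d) pruning of false positives — removal of connected components that are
    both small and detached from the principal structure;
(e) per-slice 2D flood fill of enclosed background;
(f) cubic interpolation along z to smooth inter-slice transitions;
(g) export of the final volume (non-interactive; the mask is written for
    any external renderer).

Every stage records itself in the volume's provenance list.  All numeric
parameters live in :class:`PipelineConfig`; none of them is dictated by
the physics, so they are centralized and documented rather than buried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .image_io import ImageStack, VoxelSpacing

__all__ = [
    "BinaryVolume",
    "PipelineConfig",
    "remove_outliers",
    "enhance_edges",
    "binarize_adaptive",
    "prune_false_positives",
    "flood_fill_slices",
    "interpolate_z",
    "reconstruct_spines",
]

#: 26-connectivity structuring element for 3D component labelling.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 4-connectivity structure for 2D background flood fill.
STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class BinaryVolume:
    """3D boolean mask aligned to an :class:`ImageStack`."""

    mask: np.ndarray
    spacing: VoxelSpacing
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={m.ndim}")
        self.mask = m.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def with_stage(self, name: str, mask: np.ndarray, **params) -> "BinaryVolume":
        return BinaryVolume(
            mask, self.spacing, self.provenance + [{"stage": name, **params}]
        )

    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PipelineConfig:
    """Free parameters of stages (a)-(g).

    Defaults are scaled to the spine-imaging geometry this pipeline
    targets (0.1 μm z-steps, sub-micrometre spine necks); see the methods
    note for the reasoning behind each value.
    """

    outlier_window: int = 3          # voxels, odd
    outlier_k: float = 4.0           # robust-z replacement threshold
    outlier_floor: float = 0.15      # min robust scale (normalized intensity);
    # keeps sub-μm necks — thin dark tubes are "outliers" to a 3^3 median
    # but are structure; only extreme impulses exceed k*floor
    median_subvolume: int = 0        # optional median prefilter size (0 = off)
    unsharp_amount: float = 0.6
    unsharp_sigma: float = 0.2       # μm
    edge_aware_sigma_s: float = 0.5  # μm, spatial
    edge_aware_sigma_r: float = 0.1  # normalized intensity range
    edge_aware_iterations: int = 3
    unsharp_first: bool = True       # order of the two step-(b) passes
    adaptive_block: int = 31         # px, odd
    adaptive_offset: float = 5.0 / 255.0   # normalized intensity
    min_object_voxels: int = 30
    attach_radius: float = 0.5       # μm
    zfactor: int = 3
    polarity: Literal["dark_foreground", "bright_foreground"] = "dark_foreground"

    def __post_init__(self) -> None:
        for name in ("outlier_window", "adaptive_block"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {v}")
        if self.zfactor < 1:
            raise ValueError(f"zfactor must be >= 1, got {self.zfactor}")


def _as_float(stack: ImageStack) -> np.ndarray:
    v = stack.voxels
    if v.dtype == np.uint8:
        return v.astype(np.float64) / 255.0
    if np.issubdtype(v.dtype, np.floating):
        return v.astype(np.float64)
    raise ValueError(f"expected 8-bit or normalized float stack, got {v.dtype}")


def _like_input(stack: ImageStack, arr: np.ndarray) -> ImageStack:
    if stack.voxels.dtype == np.uint8:
        arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    else:
        arr = np.clip(arr, 0.0, 1.0)
    return replace(stack, voxels=arr)


# ---------------------------------------------------------------------------
# (a) outlier removal
# ---------------------------------------------------------------------------

def remove_outliers(
    stack: ImageStack, window: int = 3, k: float = 4.0,
    median_subvolume: int = 0, scale_floor: float = 0.15,
) -> ImageStack:
    """Replace voxels deviating more than ``k`` robust SD from the local median.

    The local spread is the MAD within the window scaled to a Gaussian SD
    (x1.4826) and floored at ``scale_floor``.  The floor matters: to a
    3^3 median window a sub-μm dendritic neck is indistinguishable from
    an impulse, so the stage is kept conservative — it removes extreme
    hot/dead voxels while structured small dark objects are left for the
    component-pruning stage.  An optional 3D median prefilter over
    ``median_subvolume``-sized subvolumes runs first.
    """
    if window > min(stack.voxels.shape[:3]):
        raise ValueError(f"window {window} exceeds stack extent {stack.voxels.shape}")
    img = _as_float(stack)
    if median_subvolume >= 3:
        img = ndimage.median_filter(img, size=median_subvolume, mode="nearest")
    med = ndimage.median_filter(img, size=window, mode="nearest")
    mad = ndimage.median_filter(np.abs(img - med), size=window, mode="nearest")
    scale = np.maximum(1.4826 * mad, scale_floor)
    out = np.where(np.abs(img - med) > k * scale, med, img)
    return _like_input(stack, out)


# ---------------------------------------------------------------------------
# (b) edge enhancement: unsharp masking + domain-transform smoothing
# ---------------------------------------------------------------------------

def _domain_transform_2d(
    img: np.ndarray, sigma_s: float, sigma_r: float, iterations: int
) -> np.ndarray:
    """Edge-aware recursive filtering of each slice (recursive domain transform).

    Smooths within near-constant regions while halting at intensity
    discontinuities.  ``img`` is [z][y][x] float; sigma_s in pixels.
    Each iteration runs one horizontal and one vertical recursive pass
    with the per-iteration sigma schedule of the original formulation.
    """
    out = img.copy()
    for it in range(iterations):
        # sigma for this iteration (geometric halving, total variance preserved)
        sigma_i = sigma_s * (3.0 ** 0.5) * (2.0 ** (iterations - it - 1)) / (
            (4.0 ** iterations - 1) ** 0.5
        )
        a = np.exp(-(2.0 ** 0.5) / sigma_i)
        for axis in (2, 1):  # x pass then y pass
            diff = np.abs(np.diff(out, axis=axis))
            dt = 1.0 + (sigma_s / sigma_r) * diff  # domain-transform derivative
            w = a ** dt
            out = _recursive_pass(out, w, axis)
    return out


def _recursive_pass(img: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    """Causal + anticausal first-order recursive filter with per-edge weights."""
    img = np.moveaxis(img, axis, -1).copy()
    w = np.moveaxis(w, axis, -1)
    n = img.shape[-1]
    for i in range(1, n):  # left -> right
        img[..., i] += w[..., i - 1] * (img[..., i - 1] - img[..., i])
    for i in range(n - 2, -1, -1):  # right -> left
        img[..., i] += w[..., i] * (img[..., i + 1] - img[..., i])
    return np.moveaxis(img, -1, axis)


def enhance_edges(
    stack: ImageStack,
    unsharp_amount: float = 0.6,
    unsharp_sigma: float = 0.2,
    edge_aware_sigma_s: float = 0.5,
    edge_aware_sigma_r: float = 0.1,
    iterations: int = 3,
    unsharp_first: bool = True,
) -> ImageStack:
    """Unsharp masking plus edge-aware smoothing (order configurable).

    Unsharp: ``out = clip(in + amount * (in - G_sigma(in)))`` with sigma
    given in μm and converted per-axis to voxels.  The edge-aware pass is
    a recursive domain-transform filter applied per slice; sigma_r is in
    normalized intensity units and ``sigma_r = inf`` (or <= 0) disables it.
    """
    img = _as_float(stack)
    sp = stack.spacing

    def unsharp(x: np.ndarray) -> np.ndarray:
        if unsharp_amount == 0:
            return x
        sig = (unsharp_sigma / sp.dz, unsharp_sigma / sp.dy, unsharp_sigma / sp.dx)
        blur = ndimage.gaussian_filter(x, sigma=sig, mode="nearest")
        return np.clip(x + unsharp_amount * (x - blur), 0.0, 1.0)

    def edge_aware(x: np.ndarray) -> np.ndarray:
        if not np.isfinite(edge_aware_sigma_r) or edge_aware_sigma_r <= 0:
            return x
        sigma_px = edge_aware_sigma_s / ((sp.dx + sp.dy) / 2.0)
        return _domain_transform_2d(x, sigma_px, edge_aware_sigma_r, iterations)

    out = edge_aware(unsharp(img)) if unsharp_first else unsharp(edge_aware(img))
    return _like_input(stack, out)


# ---------------------------------------------------------------------------
# (c) adaptive binarization
# ---------------------------------------------------------------------------

def binarize_adaptive(
    stack: ImageStack,
    block: int = 31,
    offset: float = 5.0 / 255.0,
    polarity: Literal["dark_foreground", "bright_foreground"] = "dark_foreground",
) -> BinaryVolume:
    """Per-slice adaptive threshold: local mean over ``block`` minus ``offset``.

    ``dark_foreground`` marks voxels strictly below (local mean - offset);
    ``bright_foreground`` marks voxels strictly above (local mean + offset).
    Constant regions therefore yield background.  Borders use
    edge-replicated neighbourhoods.
    """
    if block < 3 or block % 2 == 0:
        raise ValueError(f"block must be odd and >= 3, got {block}")
    img = _as_float(stack)
    local_mean = np.empty_like(img)
    for i in range(img.shape[0]):  # slice-wise 2D neighbourhoods
        local_mean[i] = ndimage.uniform_filter(img[i], size=block, mode="nearest")
    if polarity == "dark_foreground":
        mask = img < (local_mean - offset)
    elif polarity == "bright_foreground":
        mask = img > (local_mean + offset)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return BinaryVolume(mask, stack.spacing).with_stage(
        "binarize_adaptive", mask, block=block, offset=offset, polarity=polarity
    )


# ---------------------------------------------------------------------------
# (d) pruning false positives
# ---------------------------------------------------------------------------

def prune_false_positives(
    volume: BinaryVolume, min_object_voxels: int = 30, attach_radius: float = 0.5
) -> BinaryVolume:
    """Keep 26-connected components that are large or attached to the largest.

    A component survives iff its size is >= ``min_object_voxels`` OR its
    minimum distance to the largest component is <= ``attach_radius`` μm.
    Output is a subset of the input.
    """
    labels, n = ndimage.label(volume.mask, structure=STRUCT_26)
    if n == 0:
        warnings.warn("prune_false_positives: empty input volume", stacklevel=2)
        return volume.with_stage(
            "prune_false_positives", volume.mask,
            min_object_voxels=min_object_voxels, attach_radius=attach_radius,
        )
    sizes = ndimage.sum_labels(volume.mask, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    sp = volume.spacing
    # distance from everywhere to the largest component, in μm
    dist = ndimage.distance_transform_edt(
        labels != largest, sampling=(sp.dz, sp.dy, sp.dx)
    )
    min_dist = ndimage.minimum(dist, labels, index=np.arange(1, n + 1))
    keep = (sizes >= min_object_voxels) | (min_dist <= attach_radius)
    keep_lut = np.concatenate([[False], keep])
    mask = keep_lut[labels]
    return volume.with_stage(
        "prune_false_positives", mask,
        min_object_voxels=min_object_voxels, attach_radius=attach_radius,
    )


# ---------------------------------------------------------------------------
# (e) per-slice flood fill
# ---------------------------------------------------------------------------

def flood_fill_slices(volume: BinaryVolume) -> BinaryVolume:
    """Fill, per slice, background regions not 4-connected to the slice border.

    Output is a superset of the input; idempotent.
    """
    mask = np.empty_like(volume.mask)
    for i in range(volume.mask.shape[0]):
        mask[i] = ndimage.binary_fill_holes(volume.mask[i], structure=STRUCT_4)
    return volume.with_stage("flood_fill_slices", mask)


# ---------------------------------------------------------------------------
# (f) z interpolation
# ---------------------------------------------------------------------------

def interpolate_z(volume: BinaryVolume, zfactor: int = 3) -> BinaryVolume:
    """Upsample the mask along z by cubic interpolation of the 0/1 field.

    Produces ``(n-1)*zfactor + 1`` slices, rethresholded at 0.5; original
    slice positions are spline knots, so slices ``0, zfactor, 2*zfactor,
    ...`` reproduce the input exactly and ``dz`` is divided by ``zfactor``.
    Falls back to linear interpolation (with a warning) below 4 slices.
    """
    if zfactor < 1 or int(zfactor) != zfactor:
        raise ValueError(f"zfactor must be a positive integer, got {zfactor}")
    if zfactor == 1:
        return volume.with_stage("interpolate_z", volume.mask, zfactor=1)
    n = volume.mask.shape[0]
    field_ = volume.mask.astype(np.float64)
    zs = np.arange(n, dtype=np.float64)
    new_z = np.linspace(0.0, n - 1.0, (n - 1) * zfactor + 1)
    if n < 4:
        warnings.warn(
            "interpolate_z: fewer than 4 slices, falling back to linear", stacklevel=2
        )
        idx = np.searchsorted(zs, new_z, side="right") - 1
        idx = np.clip(idx, 0, n - 2)
        t = (new_z - idx)[:, None, None]
        vals = field_[idx] * (1 - t) + field_[idx + 1] * t
    else:
        vals = CubicSpline(zs, field_, axis=0)(new_z)
    mask = vals >= 0.5
    sp = volume.spacing
    new_spacing = VoxelSpacing(sp.dx, sp.dy, sp.dz / zfactor)
    return BinaryVolume(
        mask, new_spacing, volume.provenance + [{"stage": "interpolate_z", "zfactor": zfactor}]
    )


# ---------------------------------------------------------------------------
# orchestration (a) -> (g)
# ---------------------------------------------------------------------------

def reconstruct_spines(
    stack: ImageStack, config: PipelineConfig | None = None
) -> tuple[BinaryVolume, dict]:
    """Run stages (a)-(f) in order and summarize; stage (g) is export.

    Returns the final volume (provenance lists every stage with its
    parameters) and a summary dict: component count, foreground fraction
    and per-stage voxel counts.
    """
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {}

    work = stack
    if work.voxels.ndim == 4:
        raise ValueError("reconstruct_spines expects a monochrome stack")
    if cfg.polarity == "bright_foreground":
        pass  # handled inside binarize

    work = remove_outliers(work, cfg.outlier_window, cfg.outlier_k,
                           cfg.median_subvolume, cfg.outlier_floor)
    work = enhance_edges(
        work, cfg.unsharp_amount, cfg.unsharp_sigma,
        cfg.edge_aware_sigma_s, cfg.edge_aware_sigma_r,
        cfg.edge_aware_iterations, cfg.unsharp_first,
    )
    vol = binarize_adaptive(work, cfg.adaptive_block, cfg.adaptive_offset, cfg.polarity)
    # record the image-domain stages in provenance ahead of the binarization entry
    vol.provenance = [
        {"stage": "remove_outliers", "window": cfg.outlier_window, "k": cfg.outlier_k,
         "median_subvolume": cfg.median_subvolume},
        {"stage": "enhance_edges", "unsharp_amount": cfg.unsharp_amount,
         "unsharp_sigma": cfg.unsharp_sigma, "sigma_s": cfg.edge_aware_sigma_s,
         "sigma_r": cfg.edge_aware_sigma_r, "unsharp_first": cfg.unsharp_first},
    ] + vol.provenance
    counts["binarize_adaptive"] = vol.voxel_count()
    vol = prune_false_positives(vol, cfg.min_object_voxels, cfg.attach_radius)
    counts["prune_false_positives"] = vol.voxel_count()
    vol = flood_fill_slices(vol)
    counts["flood_fill_slices"] = vol.voxel_count()
    vol = interpolate_z(vol, cfg.zfactor)
    counts["interpolate_z"] = vol.voxel_count()

    _, n_comp = ndimage.label(vol.mask, structure=STRUCT_26)
    summary = {
        "n_components": int(n_comp),
        "foreground_fraction": float(vol.mask.mean()),
        "stage_voxel_counts": counts,
    }
    return vol, summary
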