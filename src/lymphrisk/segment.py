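"""Tissue/background segmentation and patch-grid extraction for H&E slides.

A scanned slide is mostly white glass; tissue is the stained (saturated)
part. We threshold the HSV saturation channel, clean the binary mask with a
median filter and a morphological opening, and tile the tissue area into a
non-overlapping grid of 512x512 patches whose coordinates are persisted in
an HDF5 store.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from PIL import Image
from scipy.ndimage import binary_opening, median_filter
from skimage.color import rgb2hsv
from skimage.morphology import disk

__all__ = [
    "TissueMask",
    "PatchGrid",
    "compute_tissue_mask",
    "extract_patch_grid",
    "save_patch_store",
    "load_patch_store",
    "read_slide",
]

DEFAULT_SAT_THRESHOLD = 35  # 8-bit saturation units
DEFAULT_PATCH_SIZE = 512
DEFAULT_MEDIAN_KERNEL = 7
DEFAULT_OPEN_RADIUS = 4
DEFAULT_MASK_DOWNSAMPLE = 16


@dataclass
class TissueMask:
    """Binary tissue raster at ``downsample_factor`` relative to level-0 pixels."""

    mask: np.ndarray  # bool, (H/d, W/d)
    downsample_factor: int = 1
    params: dict = field(default_factory=dict)

    @property
    def area_pixels(self) -> int:
        """Tissue area expressed in level-0 pixels."""
        return int(self.mask.sum()) * self.downsample_factor**2


@dataclass
class PatchGrid:
    """Non-overlapping patch coordinates (level-0, top-left anchored, half-open)."""

    slide_id: str
    patch_size: int
    coords: np.ndarray  # (N, 2) int64, columns (x, y)
    slide_width: int
    slide_height: int
    slide_path: str = ""
    downsample: int = 1
    mask_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coords)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatchGrid):
            return NotImplemented
        return (
            self.slide_id == other.slide_id
            and self.patch_size == other.patch_size
            and np.array_equal(self.coords, other.coords)
            and self.slide_width == other.slide_width
            and self.slide_height == other.slide_height
            and self.slide_path == other.slide_path
            and self.downsample == other.downsample
            and self.mask_params == other.mask_params
        )


def read_slide(path: str) -> np.ndarray:
    """Read a flat PNG/TIFF slide as an 8-bit RGB array.

    Pyramidal files are read at their base level; this package targets
    desk-scale rasters rather than gigapixel pyramids.
    """
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit channels, got dtype {image.dtype}")
    return image


def compute_tissue_mask(
    image: np.ndarray,
    sat_threshold: float = DEFAULT_SAT_THRESHOLD,
    median_kernel: int = DEFAULT_MEDIAN_KERNEL,
    open_radius: int = DEFAULT_OPEN_RADIUS,
    downsample: int = DEFAULT_MASK_DOWNSAMPLE,
) -> TissueMask:
    """Threshold HSV saturation to separate stained tissue from white glass.

    Parameters
    ----------
    image
        8-bit RGB slide raster.
    sat_threshold
        Saturation cut on a 0-255 scale; pixels at or above it are tissue.
    median_kernel
        Odd side length of the median filter applied to the saturation
        channel before thresholding (noise removal that preserves edges).
    open_radius
        Disc radius of the binary opening (erosion then dilation) that
        removes specks and closes pinholes in the thresholded mask.
    downsample
        Integer factor at which the mask is computed relative to level-0.
    """
    image = _as_rgb(image)
    if image.size == 0:
        raise ValueError("empty image")
    if median_kernel % 2 == 0:
        raise ValueError("median_kernel must be odd")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")

    small = image[::downsample, ::downsample]
    sat = rgb2hsv(small)[..., 1] * 255.0
    if median_kernel > 1:
        sat = median_filter(sat, size=median_kernel, mode="nearest")
    mask = sat >= sat_threshold
    if open_radius > 0:
        mask = binary_opening(mask, structure=disk(open_radius))
    params = {
        "sat_threshold": float(sat_threshold),
        "median_kernel": int(median_kernel),
        "open_radius": int(open_radius),
        "downsample": int(downsample),
    }
    return TissueMask(mask=mask, downsample_factor=downsample, params=params)


def extract_patch_grid(
    tissue: TissueMask,
    slide_width: int,
    slide_height: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_tissue_fraction: float = 0.25,
    slide_id: str = "",
    slide_path: str = "",
) -> PatchGrid:
    """Tile the slide into a stride-``patch_size`` grid and keep tissue patches.

    A grid cell is kept when the fraction of its footprint covered by the
    tissue mask (evaluated at mask resolution) is at least
    ``min_tissue_fraction``. Cells extending past the slide boundary are
    discarded so every patch is fully inside the slide.
    """
    d = tissue.downsample_factor
    mask = tissue.mask
    coords = []
    for y in range(0, slide_height - patch_size + 1, patch_size):
        for x in range(0, slide_width - patch_size + 1, patch_size):
            my0, my1 = y // d, -(-(y + patch_size) // d)
            mx0, mx1 = x // d, -(-(x + patch_size) // d)
            window = mask[my0 : min(my1, mask.shape[0]), mx0 : min(mx1, mask.shape[1])]
            denom = max((my1 - my0) * (mx1 - mx0), 1)
            if window.size and window.sum() / denom >= min_tissue_fraction:
                coords.append((x, y))
    coords_arr = (
        np.array(coords, dtype=np.int64) if coords else np.empty((0, 2), dtype=np.int64)
    )
    return PatchGrid(
        slide_id=slide_id,
        patch_size=patch_size,
        coords=coords_arr,
        slide_width=slide_width,
        slide_height=slide_height,
        slide_path=slide_path,
        downsample=d,
        mask_params=dict(tissue.params),
    )


def save_patch_store(grid: PatchGrid, path: str) -> None:
    """Persist patch coordinates and slide metadata to an HDF5 store."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=grid.coords, dtype=np.int64)
        f.attrs["patch_size"] = grid.patch_size
        f.attrs["downsample"] = grid.downsample
        f.attrs["slide_width"] = grid.slide_width
        f.attrs["slide_height"] = grid.slide_height
        f.attrs["slide_path"] = grid.slide_path
        f.attrs["slide_id"] = grid.slide_id
        f.attrs["mask_params"] = json.dumps(grid.mask_params, sort_keys=True)


def load_patch_store(path: str) -> PatchGrid:
    """Load a :class:`PatchGrid` previously written by :func:`save_patch_store`."""
    with h5py.File(path, "r") as f:
        if "coords" not in f:
            raise KeyError(f"patch store {path!r} is missing dataset '/coords'")
        required = ("patch_size", "slide_width", "slide_height")
        for attr in required:
            if attr not in f.attrs:
                raise KeyError(f"patch store {path!r} is missing attribute {attr!r}")
        return PatchGrid(
            slide_id=str(f.attrs.get("slide_id", "")),
            patch_size=int(f.attrs["patch_size"]),
            coords=f["coords"][...],
            slide_width=int(f.attrs["slide_width"]),
            slide_height=int(f.attrs["slide_height"]),
            slide_path=str(f.attrs.get("slide_path", "")),
            downsample=int(f.attrs.get("downsample", 1)),
            mask_params=json.loads(f.attrs.get("mask_params", "{}")),
        )
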