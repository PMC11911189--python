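"""Interpretability: attention heatmaps on slide coordinates and
cell-density summaries from externally produced nuclear annotations.

Attention scores are min-max normalised to [0, 1] and rendered as a
diverging blue-to-red overlay on the source slide (red = high attention).
Nuclear centroids (from any segmenter that writes the JSON sidecar format)
are counted inside the tissue mask per cell type and expressed as nuclei
per mm^2; groups are compared with a two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from scipy.stats import mannwhitneyu

from .segment import PatchGrid, TissueMask

__all__ = [
    "CELL_TYPES",
    "NucleusRecord",
    "DensitySummary",
    "normalize_attention",
    "render_heatmap",
    "cell_density",
    "compare_density_groups",
    "load_nuclei",
    "save_nuclei",
]

CELL_TYPES = (
    "Neoplastic",
    "Inflammatory",
    "Connective",
    "Dead",
    "Non-Neoplastic Epithelial",
)

DEFAULT_COLORMAP = "coolwarm"  # diverging, blue (low) -> red (high)


@dataclass
class NucleusRecord:
    x: float
    y: float
    cell_type: str

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )


@dataclass
class DensitySummary:
    """Per-slide counts and densities (nuclei / mm^2) over the tissue mask."""

    counts: dict[str, int]
    densities: dict[str, float]
    mask_area_mm2: float
    n_outside_mask: int = 0
    slide_id: str = ""


def normalize_attention(A) -> np.ndarray:
    """Min-max scale attention to [0, 1]; a constant vector maps to 0.5."""
    A = np.asarray(A, dtype=float).ravel()
    if A.size == 0:
        raise ValueError("empty attention vector")
    lo, hi = A.min(), A.max()
    if hi == lo:
        return np.full_like(A, 0.5)
    return (A - lo) / (hi - lo)


def render_heatmap(
    grid: PatchGrid,
    scores,
    base_image: np.ndarray,
    colormap: str = DEFAULT_COLORMAP,
    alpha: float = 0.5,
) -> np.ndarray:
    """Tint each patch footprint by its normalised attention score.

    Each patch is blended as ``(1 - alpha) * base + alpha * color(score)``;
    pixels outside every patch footprint are untouched. Score 0 maps to the
    blue end of the diverging map and 1 to the red end.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) != len(grid):
        raise ValueError(
            f"score count {len(scores)} != patch count {len(grid)}"
        )
    out = np.asarray(base_image).copy()
    if alpha == 0:
        return out
    cmap = colormaps[colormap]
    p = grid.patch_size
    outf = out.astype(np.float64)
    for (x, y), score in zip(grid.coords, scores):
        color = np.asarray(cmap(float(score))[:3]) * 255.0
        block = outf[y : y + p, x : x + p]
        outf[y : y + p, x : x + p] = (1.0 - alpha) * block + alpha * color
    return np.clip(np.rint(outf), 0, 255).astype(np.uint8)


def cell_density(
    records: list[NucleusRecord],
    mask: TissueMask,
    microns_per_pixel: float,
    slide_id: str = "",
) -> DensitySummary:
    """Per-type nuclear density over the tissue-mask area.

    A centroid counts when the mask pixel under it (at mask resolution) is
    tissue; records outside the mask are excluded and tallied separately.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be positive")
    area_px = int(mask.mask.sum())
    if area_px == 0:
        raise ValueError("empty tissue mask: density undefined")
    d = mask.downsample_factor
    mm_per_mask_px = microns_per_pixel * d / 1000.0
    area_mm2 = area_px * mm_per_mask_px**2

    counts = {t: 0 for t in CELL_TYPES}
    outside = 0
    H, W = mask.mask.shape
    for rec in records:
        mx, my = int(rec.x // d), int(rec.y // d)
        if 0 <= my < H and 0 <= mx < W and mask.mask[my, mx]:
            counts[rec.cell_type] += 1
        else:
            outside += 1
    densities = {t: counts[t] / area_mm2 for t in CELL_TYPES}
    return DensitySummary(
        counts=counts,
        densities=densities,
        mask_area_mm2=area_mm2,
        n_outside_mask=outside,
        slide_id=slide_id,
    )


def compare_density_groups(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected).

    ``group_a`` / ``group_b`` are per-slide density values for one cell
    type. Returns (U statistic of the first group, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def save_nuclei(records: list[NucleusRecord], path: str) -> None:
    with open(path, "w") as f:
        json.dump(
            [{"x": r.x, "y": r.y, "type": r.cell_type} for r in records], f
        )


def load_nuclei(path: str) -> list[NucleusRecord]:
    with open(path) as f:
        return [NucleusRecord(d["x"], d["y"], d["type"]) for d in json.load(f)]
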