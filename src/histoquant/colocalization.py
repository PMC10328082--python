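"""Pearson / Spearman colocalization over a masked region.

Voxels are pooled across the ROI's z-range by default (a single defensible
whole-cell convention); a per-slice mode averages the per-slice coefficient
instead.  No intensity thresholding is applied.  Channels with zero
variance yield ``nan`` (an explicit undefined marker) rather than 0, which
would bias downstream means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .imaging_io import ImageStack, Polygon, Roi, roi_mask_2d

__all__ = ["ColocResult", "pearson_coloc", "spearman_coloc", "region_grid"]


@dataclass(frozen=True)
class ColocResult:
    """Correlation between two channels over one ROI."""

    pearson_r: float
    spearman_rho: float
    n_voxels: int
    roi_name: str

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.pearson_r) and np.isnan(self.spearman_rho))


def _pooled_values(
    stack: ImageStack, roi: Roi, ch_a: str, ch_b: str
) -> tuple[np.ndarray, np.ndarray]:
    z0, z1 = roi.z_range
    if z1 >= stack.n_slices:
        raise ValueError(f"roi z_range {roi.z_range} outside stack")
    mask = roi_mask_2d(roi, stack.shape_yx)
    a = stack.channel(ch_a)[z0 : z1 + 1][:, mask].ravel()
    b = stack.channel(ch_b)[z0 : z1 + 1][:, mask].ravel()
    if a.size < 2:
        raise ValueError(f"ROI {roi.name!r} yields {a.size} voxels; need >= 2")
    return a.astype(np.float64), b.astype(np.float64)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return _sps.rankdata(x, method="average")


def pearson_coloc(
    stack: ImageStack, roi: Roi, ch_a: str, ch_b: str, mode: str = "pooled"
) -> ColocResult:
    """Sample Pearson correlation of two channels over the ROI voxels.

    ``mode='pooled'`` correlates all voxels of the z-range at once;
    ``mode='per-slice'`` averages the per-slice coefficients (slices where
    either channel is constant are skipped).
    """
    return _coloc(stack, roi, ch_a, ch_b, mode, rank=False)


def spearman_coloc(
    stack: ImageStack, roi: Roi, ch_a: str, ch_b: str, mode: str = "pooled"
) -> ColocResult:
    """Spearman rho: Pearson correlation of mid-ranks (ties get average rank)."""
    return _coloc(stack, roi, ch_a, ch_b, mode, rank=True)


def _coloc(
    stack: ImageStack, roi: Roi, ch_a: str, ch_b: str, mode: str, rank: bool
) -> ColocResult:
    if mode not in ("pooled", "per-slice"):
        raise ValueError(f"mode must be 'pooled' or 'per-slice', got {mode!r}")
    if mode == "pooled":
        a, b = _pooled_values(stack, roi, ch_a, ch_b)
        n = a.size
        if rank:
            r = _pearson(_midrank(a), _midrank(b))
            return ColocResult(float("nan"), r, n, roi.name)
        return ColocResult(_pearson(a, b), float("nan"), n, roi.name)

    z0, z1 = roi.z_range
    mask = roi_mask_2d(roi, stack.shape_yx)
    coeffs = []
    n = 0
    for z in range(z0, z1 + 1):
        a = stack.channel(ch_a)[z][mask].astype(np.float64)
        b = stack.channel(ch_b)[z][mask].astype(np.float64)
        n += a.size
        if rank:
            a, b = _midrank(a), _midrank(b)
        c = _pearson(a, b)
        if not np.isnan(c):
            coeffs.append(c)
    val = float(np.mean(coeffs)) if coeffs else float("nan")
    if rank:
        return ColocResult(float("nan"), val, n, roi.name)
    return ColocResult(val, float("nan"), n, roi.name)


def region_grid(stack: ImageStack, side_um: float = 150.0) -> list[Roi]:
    """Non-overlapping square ROIs of physical side ``side_um`` tiling the field.

    The side is ``round(side_um / pixel_size_um)`` pixels; partial edge
    tiles are excluded, so every returned region has an identical pixel
    count.
    """
    side_px = int(round(side_um / stack.pixel_size_um))
    if side_px < 1:
        raise ValueError(f"region side {side_um} um is smaller than one pixel")
    h, w = stack.shape_yx
    z_range = (0, stack.n_slices - 1)
    rois = []
    for gy, y0 in enumerate(range(0, h - side_px + 1, side_px)):
        for gx, x0 in enumerate(range(0, w - side_px + 1, side_px)):
            verts = (
                (x0, y0),
                (x0 + side_px, y0),
                (x0 + side_px, y0 + side_px),
                (x0, y0 + side_px),
            )
            rois.append(Roi(f"region_{gy}_{gx}", Polygon(verts), z_range))
    return rois
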