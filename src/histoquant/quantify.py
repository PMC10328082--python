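"""Background-corrected integrated density — the primitive under every ratio.

The raw integrated density of a cell is the sum of its channel intensities
over the ROI footprint and every z slice in the ROI's range ("sum of
slices").  Background is measured with an equal-area ROI placed over a
signal-free area and summed over the same z extent; the corrected total is
the plain difference.  Sums accumulate in 64-bit (integer input stays
bit-exact; 16-bit stacks can overflow 32-bit accumulators).  Negative
corrected totals are kept and flagged, never clamped — clamping would bias
ratio denominators upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import ImageStack, Roi, roi_mask_2d

__all__ = [
    "RoiTotal",
    "CellMeasurement",
    "integrated_density",
    "background_corrected_total",
    "measure_cell",
]


@dataclass(frozen=True)
class RoiTotal:
    """One background-corrected channel total."""

    raw_total: float
    background_total: float
    n_slices: int
    roi_area_px: int

    @property
    def corrected_total(self) -> float:
        return self.raw_total - self.background_total

    @property
    def negative(self) -> bool:
        return self.corrected_total < 0


@dataclass
class CellMeasurement:
    """One cell's corrected per-channel totals plus geometry and flags."""

    cell_id: str
    centroid_um: tuple[float, float]
    diameter_um: float
    totals: dict[str, float]
    edu_positive: bool | None = None
    specimen: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError(f"diameter_um must be > 0, got {self.diameter_um}")

    def total(self, channel: str) -> float:
        try:
            return self.totals[channel]
        except KeyError:
            raise KeyError(
                f"cell {self.cell_id!r} has no total for channel {channel!r}"
            ) from None


def _roi_footprint(stack: ImageStack, roi: Roi) -> tuple[np.ndarray, int, int]:
    z0, z1 = roi.z_range
    if z1 >= stack.n_slices:
        raise ValueError(f"roi z_range {roi.z_range} outside stack")
    mask = roi_mask_2d(roi, stack.shape_yx)
    area = int(mask.sum())
    if area == 0:
        raise ValueError(f"ROI {roi.name!r} selects no pixels")
    return mask, z0, z1


def integrated_density(stack: ImageStack, roi: Roi, channel: str) -> float:
    """Sum of the channel over the ROI pixels and its whole z-range."""
    mask, z0, z1 = _roi_footprint(stack, roi)
    ch = stack.channel(channel)
    block = ch[z0 : z1 + 1][:, mask]
    if np.issubdtype(block.dtype, np.integer):
        return float(block.sum(dtype=np.int64))
    return float(block.sum(dtype=np.float64))


def background_corrected_total(
    stack: ImageStack, signal_roi: Roi, background_roi: Roi, channel: str
) -> RoiTotal:
    """Integrated density of the signal ROI minus an equal-area background ROI.

    The two ROIs must match in pixel count (within 1 pixel; a larger
    mismatch signals a mis-specified background ROI) and span the same
    number of slices.
    """
    sig_mask, sz0, sz1 = _roi_footprint(stack, signal_roi)
    bg_mask, bz0, bz1 = _roi_footprint(stack, background_roi)
    sig_area, bg_area = int(sig_mask.sum()), int(bg_mask.sum())
    if abs(sig_area - bg_area) > 1:
        raise ValueError(
            f"background ROI area {bg_area} px differs from signal ROI area "
            f"{sig_area} px by more than 1 pixel"
        )
    if (sz1 - sz0) != (bz1 - bz0):
        raise ValueError("signal and background ROIs span different z extents")
    raw = integrated_density(stack, signal_roi, channel)
    bg = integrated_density(stack, background_roi, channel)
    return RoiTotal(raw, bg, sz1 - sz0 + 1, sig_area)


def measure_cell(
    stack: ImageStack,
    cell_roi: Roi,
    background_roi: Roi,
    channels: list[str],
    *,
    edu_channel: str | None = None,
    edu_mean_cutoff: float = 100.0,
    specimen: str | None = None,
) -> CellMeasurement:
    """Aggregate corrected totals, geometry and the EdU flag for one cell.

    The centroid is the mean of the ROI pixel centers scaled by the pixel
    size; the diameter is the equivalent-circle diameter of the ROI area.
    EdU positivity is the mean EdU intensity over the ROI exceeding
    ``edu_mean_cutoff`` (a per-cell boolean thereafter).
    """
    mask, z0, z1 = _roi_footprint(stack, cell_roi)
    ys, xs = np.nonzero(mask)
    px = stack.pixel_size_um
    centroid = (float((xs + 0.5).mean() * px), float((ys + 0.5).mean() * px))
    area_px = ys.size
    diameter = 2.0 * np.sqrt(area_px / np.pi) * px

    totals: dict[str, float] = {}
    flags: list[str] = []
    for ch in channels:
        rt = background_corrected_total(stack, cell_roi, background_roi, ch)
        totals[ch] = rt.corrected_total
        if rt.negative:
            flags.append(f"negative_total:{ch}")

    edu_positive: bool | None = None
    if edu_channel is not None:
        edu = stack.channel(edu_channel)[z0 : z1 + 1][:, mask]
        bg_mask, bz0, bz1 = _roi_footprint(stack, background_roi)
        edu_bg = stack.channel(edu_channel)[bz0 : bz1 + 1][:, bg_mask]
        edu_positive = bool(edu.mean() - edu_bg.mean() > edu_mean_cutoff)

    return CellMeasurement(
        cell_id=cell_roi.name,
        centroid_um=centroid,
        diameter_um=float(diameter),
        totals=totals,
        edu_positive=edu_positive,
        specimen=specimen,
        flags=flags,
    )
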