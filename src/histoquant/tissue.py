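"""Field-level analyses: cluster statistics, censuses and line profiles.

Clustering of marker-positive cells is single-linkage: two cells are
adjacent when their centroids are within the adjacency radius, and
clusters are the connected components of that graph.  The default radius
(10 um, roughly one stem-cell nucleus diameter) is an explicit, reported
parameter — adjacency is otherwise undefined in common practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .imaging_io import ImageStack, Roi, roi_mask_2d

__all__ = [
    "ClusterSet",
    "ProfileTrace",
    "DEFAULT_ADJACENCY_RADIUS_UM",
    "cluster_cells",
    "cluster_size_distribution",
    "single_cell_fraction",
    "count_positive",
    "percent_positive",
    "profile_trace",
    "block_average",
]

DEFAULT_ADJACENCY_RADIUS_UM = 10.0
SIZE_BINS = ("1", "2", "3+")


@dataclass
class ClusterSet:
    """Partition of marker-positive cells into single-linkage clusters."""

    cell_ids: tuple[str, ...]
    positions_um: np.ndarray  # (n, 2) of (x, y)
    adjacency_radius_um: float
    labels: np.ndarray  # cluster index per cell

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    @property
    def size_histogram(self) -> dict[str, int]:
        sizes = self.cluster_sizes
        return {
            "1": int((sizes == 1).sum()),
            "2": int((sizes == 2).sum()),
            "3+": int((sizes >= 3).sum()),
        }

    def clusters(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_clusters)]
        for cid, lab in zip(self.cell_ids, self.labels):
            out[lab].append(cid)
        return out


def cluster_cells(
    cell_ids: Sequence[str],
    positions_um: np.ndarray,
    adjacency_radius_um: float = DEFAULT_ADJACENCY_RADIUS_UM,
) -> ClusterSet:
    """Single-linkage connected components under centroid distance <= radius."""
    if adjacency_radius_um <= 0:
        raise ValueError("adjacency radius must be > 0")
    pos = np.asarray(positions_um, dtype=np.float64).reshape(-1, 2)
    n = pos.shape[0]
    if len(cell_ids) != n:
        raise ValueError("cell_ids and positions length mismatch")
    if n == 0:
        return ClusterSet((), pos, adjacency_radius_um, np.zeros(0, dtype=int))
    pairs = cKDTree(pos).query_pairs(r=adjacency_radius_um, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    # relabel components in order of first appearance for determinism
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels], dtype=int)
    return ClusterSet(tuple(cell_ids), pos, adjacency_radius_um, labels)


def cluster_size_distribution(cs: ClusterSet) -> dict[str, float]:
    """Percentages of 1-, 2- and >=3-cell clusters (denominator: clusters)."""
    if cs.n_clusters == 0:
        raise ValueError("empty cluster set")
    hist = cs.size_histogram
    return {k: 100.0 * v / cs.n_clusters for k, v in hist.items()}


def single_cell_fraction(cs: ClusterSet) -> float:
    """Percentage of cells that sit in size-1 clusters (denominator: cells)."""
    if cs.n_cells == 0:
        raise ValueError("no positive cells")
    sizes = cs.cluster_sizes
    singles = int(sizes[sizes == 1].sum())
    return 100.0 * singles / cs.n_cells


def count_positive(
    cells: pd.DataFrame,
    marker: str,
    region: Roi | None = None,
    pixel_size_um: float | None = None,
) -> int:
    """Number of marker-positive cells whose centroid falls in the region.

    ``cells`` needs columns ``x_um``, ``y_um`` and a boolean column named
    after the marker.  ``region`` is an ROI in pixel coordinates, so
    ``pixel_size_um`` is required with it; ``region=None`` counts the
    whole field.
    """
    if marker not in cells.columns:
        raise KeyError(f"unknown marker {marker!r}; columns: {list(cells.columns)}")
    pos = cells[cells[marker].astype(bool)]
    if region is None:
        return int(len(pos))
    if pixel_size_um is None:
        raise ValueError("pixel_size_um is required when a region ROI is given")
    if pos.empty:
        return 0
    xs = (pos["x_um"].to_numpy() / pixel_size_um).astype(int)
    ys = (pos["y_um"].to_numpy() / pixel_size_um).astype(int)
    shape = (int(ys.max()) + 1, int(xs.max()) + 1)
    mask = roi_mask_2d(region, shape)
    inside = mask[ys, xs]
    return int(inside.sum())


def percent_positive(
    positives: Sequence[int], totals: Sequence[int]
) -> dict:
    """Per-region percent positive plus mean +/- SEM across regions.

    Regions with zero total are excluded (with a warning entry in the
    output) rather than producing a division by zero.
    """
    pos = np.asarray(positives, dtype=np.float64)
    tot = np.asarray(totals, dtype=np.float64)
    if pos.shape != tot.shape:
        raise ValueError("positives and totals length mismatch")
    keep = tot > 0
    excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all regions have zero total")
    pct = 100.0 * pos[keep] / tot[keep]
    sem = float(pct.std(ddof=1) / np.sqrt(pct.size)) if pct.size > 1 else 0.0
    return {
        "per_region_percent": pct.tolist(),
        "mean": float(pct.mean()),
        "sem": sem,
        "n_regions": int(pct.size),
        "excluded_zero_total": excluded,
    }


@dataclass
class ProfileTrace:
    """Mean intensity along a midline path, averaged across a sampling band."""

    positions_px: np.ndarray
    mean_intensity: np.ndarray
    width_px: int

    def __len__(self) -> int:
        return self.positions_px.shape[0]


def _resample_polyline(vertices: np.ndarray, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Points every ``step`` px along the polyline, with unit tangents."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate path")
    s = np.arange(0.0, total + 1e-9, step)
    xs = np.interp(s, cum, vertices[:, 0])
    ys = np.interp(s, cum, vertices[:, 1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    tang = seg[idx] / seg_len[idx, None]
    return np.column_stack([xs, ys]), tang


def profile_trace(
    image: ImageStack | np.ndarray,
    path_xy: Sequence[tuple[float, float]],
    width_px: int = 500,
    channel: str | None = None,
) -> ProfileTrace:
    """Band-averaged intensity profile along a polyline path.

    A z-stack is max-projected first.  At each unit step along the path the
    trace value is the mean intensity over ``width_px`` samples placed at
    unit spacing along the perpendicular, centered on the path; samples
    falling outside the field are excluded from the mean (not zero-padded,
    which would bias edges downward).
    """
    if isinstance(image, ImageStack):
        if channel is None:
            raise ValueError("channel name required for an ImageStack input")
        img = np.asarray(image.channel(channel)).max(axis=0)
    else:
        img = np.asarray(image)
        if img.ndim == 3:
            img = img.max(axis=0)
    verts = np.asarray(path_xy, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[0] < 2:
        raise ValueError("path needs at least 2 vertices")
    pts, tang = _resample_polyline(verts)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(width_px, dtype=np.float64) - (width_px - 1) / 2.0

    h, w = img.shape
    # (n_pos, width) sample coordinates
    sx = pts[:, 0:1] + offsets[None, :] * normal[:, 0:1]
    sy = pts[:, 1:2] + offsets[None, :] * normal[:, 1:2]
    ix = np.floor(sx).astype(int)
    iy = np.floor(sy).astype(int)
    valid = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    vals = np.zeros_like(sx)
    vals[valid] = img[iy[valid], ix[valid]]
    counts = valid.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("path positions with no in-field samples")
    means = vals.sum(axis=1) / counts
    positions = np.arange(len(pts), dtype=float)
    return ProfileTrace(positions_px=positions, mean_intensity=means, width_px=int(width_px))


def block_average(
    trace: ProfileTrace | np.ndarray, block: int = 1000
) -> np.ndarray:
    """Means of non-overlapping consecutive blocks; trailing partial block
    dropped.  The mean of the block means equals the trace mean whenever
    the length is an exact multiple of the block size."""
    x = trace.mean_intensity if isinstance(trace, ProfileTrace) else np.asarray(trace, dtype=np.float64)
    if block < 1:
        raise ValueError("block must be >= 1")
    n_blocks = len(x) // block
    if n_blocks == 0:
        raise ValueError(f"trace of length {len(x)} shorter than one block ({block})")
    return x[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
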