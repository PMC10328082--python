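"""Seeded synthetic microscopy with planted ground truth.

Every measured configuration downstream has a generator here:

* :func:`make_mitotic_early` — one early-mitotic nucleus, two channels whose
  spatial co-occupancy is controlled by ``overlap_mix`` in [0, 1].
* :func:`make_mitotic_late` — two separated chromatid masses with the
  old-channel total split ``f : 1 - f``.
* :func:`make_pair` — an adjacent postmitotic cell pair with planted Delta
  reporter levels, old/new histone totals and EdU flags.
* :func:`plan_field` / :func:`render_field` — 2D tissue fields of
  marker-positive cells with planted cluster structure and an intensity
  profile along the long axis.

Noise model (applied per channel, per voxel):

    v = Poisson(gain * signal) / gain + Normal(0, read_sigma) + baseline

clipped to [0, 65535].  ``gain = 0`` disables the Poisson term (used for
noise-free tests).  Planted totals are always recorded *before* noise, so
the expected background-corrected ROI total equals the planted total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging_io import Ellipse, ImageStack, Roi

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "PairParams",
    "ClusterSpec",
    "FieldParams",
    "DEFAULT_NOISE",
    "NO_NOISE",
    "apply_noise",
    "make_mitotic_early",
    "make_mitotic_late",
    "make_pair",
    "plan_field",
    "render_field",
    "make_midgut_field",
    "sample_cluster_sizes",
    "make_ratio_table",
    "make_log2_table",
]

_CLIP_MAX = 65535.0


@dataclass(frozen=True)
class NoiseModel:
    """Photon gain, Gaussian read noise and a constant baseline offset."""

    gain: float = 0.2
    read_sigma: float = 2.0
    baseline: float = 50.0

    def __post_init__(self) -> None:
        if self.gain < 0 or self.read_sigma < 0 or self.baseline < 0:
            raise ValueError("noise parameters must be non-negative")


#: Defaults calibrated so the documented Monte-Carlo recovery tolerances hold.
DEFAULT_NOISE = NoiseModel()
#: Exact pass-through (no Poisson, no read noise, no baseline).
NO_NOISE = NoiseModel(gain=0.0, read_sigma=0.0, baseline=0.0)


@dataclass
class GroundTruth:
    """Planted parameters and derived expectations for one synthetic scene."""

    scenario: str
    seed: int
    noise: NoiseModel
    params: dict = field(default_factory=dict)
    rois: dict = field(default_factory=dict)
    cells: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "noise": asdict(self.noise),
            "params": self.params,
            "cells": self.cells,
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=float)


def apply_noise(
    signal: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply the Poisson + Gaussian + baseline model and clip to [0, 65535]."""
    out = np.asarray(signal, dtype=np.float64)
    if noise.gain > 0:
        out = rng.poisson(noise.gain * out).astype(np.float64) / noise.gain
    else:
        out = out.copy()
    if noise.read_sigma > 0:
        out += rng.normal(0.0, noise.read_sigma, size=out.shape)
    out += noise.baseline
    np.clip(out, 0.0, _CLIP_MAX, out=out)
    return out


def _ellipsoid_mask(
    shape_zyx: tuple[int, int, int],
    center_zyx: tuple[float, float, float],
    radii_zyx: tuple[float, float, float],
) -> np.ndarray:
    zz, yy, xx = np.mgrid[0 : shape_zyx[0], 0 : shape_zyx[1], 0 : shape_zyx[2]]
    cz, cy, cx = center_zyx
    rz, ry, rx = radii_zyx
    return (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0


def _normalized_weight(field3d: np.ndarray, total: float) -> np.ndarray:
    s = field3d.sum()
    if s <= 0:
        raise ValueError("weight field sums to zero")
    return field3d * (total / s)


# ---------------------------------------------------------------------------
# Early mitosis: one nucleus, controllable channel co-occupancy
# ---------------------------------------------------------------------------

def make_mitotic_early(
    overlap_mix: float,
    *,
    shape: tuple[int, int, int] = (8, 64, 64),
    nucleus_radii_px: tuple[float, float, float] = (3.0, 18.0, 18.0),
    totals: tuple[float, float] = (200_000.0, 200_000.0),
    blur_px: float = 1.0,
    pixel_size_um: float = 0.25,
    z_step_um: float = 0.5,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """One two-channel nucleus whose channels co-occupy space by ``overlap_mix``.

    ``overlap_mix = 1`` gives both channels identical spatial weights;
    ``overlap_mix = 0`` confines them to disjoint halves of the nucleus, so
    the Pearson correlation over the nucleus mask is negative.  Expected
    correlation increases monotonically with the mix.
    """
    if not 0.0 <= overlap_mix <= 1.0:
        raise ValueError(f"overlap_mix must be in [0, 1], got {overlap_mix}")
    nz, ny, nx = shape
    center = ((nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2)
    if 2 * nucleus_radii_px[1] >= ny or 2 * nucleus_radii_px[2] >= nx:
        raise ValueError("nucleus larger than frame")
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape, center, nucleus_radii_px)

    # shared texture plus two disjoint half-nucleus domains (blurred edges)
    shared = gaussian_filter(rng.random(shape), 2.0) * mask
    half_a = gaussian_filter((mask & (np.mgrid[0:nz, 0:ny, 0:nx][2] < center[2])).astype(float), blur_px) * mask
    half_b = gaussian_filter((mask & (np.mgrid[0:nz, 0:ny, 0:nx][2] >= center[2])).astype(float), blur_px) * mask

    w_old = overlap_mix * shared + (1.0 - overlap_mix) * half_a * (shared + 0.1)
    w_new = overlap_mix * shared + (1.0 - overlap_mix) * half_b * (shared + 0.1)
    old = _normalized_weight(w_old, totals[0])
    new = _normalized_weight(w_new, totals[1])

    data = np.stack([apply_noise(old, noise, rng), apply_noise(new, noise, rng)])
    stack = ImageStack(data, pixel_size_um, z_step_um, ("old", "new"))

    nucleus_roi = Roi(
        "nucleus",
        Ellipse(
            (center[2] + 0.5, center[1] + 0.5),
            (nucleus_radii_px[2] + 1, nucleus_radii_px[1] + 1),
        ),
        (0, nz - 1),
    )
    truth = GroundTruth(
        scenario="mitotic_early",
        seed=seed,
        noise=noise,
        params={
            "overlap_mix": overlap_mix,
            "totals": {"old": totals[0], "new": totals[1]},
        },
        rois={"nucleus": nucleus_roi},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Late mitosis: two chromatid masses with a planted partition fraction
# ---------------------------------------------------------------------------

def make_mitotic_late(
    partition_fraction_f: float,
    *,
    total_old: float = 400_000.0,
    total_new: float = 400_000.0,
    shape: tuple[int, int, int] = (8, 96, 96),
    mass_radii_px: tuple[float, float, float] = (2.5, 8.0, 8.0),
    separation_px: float = 40.0,
    blur_px: float = 1.0,
    pixel_size_um: float = 0.25,
    z_step_um: float = 0.5,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Two sister-chromatid masses; old-channel signal split ``f : 1 - f``.

    Ground truth records the planted segregation ratio
    ``max(f, 1 - f) / min(f, 1 - f)`` and per-mass planted totals (before
    noise, which sum exactly to ``total_old``).  Ellipse ROIs around each
    mass plus an equal-area background ROI ship with the scene.
    """
    if not 0.0 < partition_fraction_f < 1.0:
        raise ValueError(f"partition fraction must be in (0, 1), got {partition_fraction_f}")
    nz, ny, nx = shape
    min_sep = 2 * (mass_radii_px[2] + 3 * blur_px)
    if separation_px < min_sep:
        raise ValueError(
            f"separation {separation_px} px below minimum {min_sep:.1f} px; masses overlap"
        )
    cz, cy = (nz - 1) / 2, (ny - 1) / 2
    cx_a = (nx - 1) / 2 - separation_px / 2
    cx_b = (nx - 1) / 2 + separation_px / 2
    rng = np.random.default_rng(seed)

    def _mass(cx: float) -> np.ndarray:
        m = _ellipsoid_mask(shape, (cz, cy, cx), mass_radii_px).astype(float)
        m *= 0.5 + gaussian_filter(rng.random(shape), 2.0)
        return gaussian_filter(m, blur_px)

    wa, wb = _mass(cx_a), _mass(cx_b)
    f = partition_fraction_f
    old = _normalized_weight(wa, f * total_old) + _normalized_weight(wb, (1 - f) * total_old)
    new = _normalized_weight(wa, total_new / 2) + _normalized_weight(wb, total_new / 2)

    data = np.stack([apply_noise(old, noise, rng), apply_noise(new, noise, rng)])
    stack = ImageStack(data, pixel_size_um, z_step_um, ("old", "new"))

    roi_rx = mass_radii_px[2] + 4 * blur_px + 2
    roi_ry = mass_radii_px[1] + 4 * blur_px + 2
    z_range = (0, nz - 1)
    roi_a = Roi("mass_A", Ellipse((cx_a + 0.5, cy + 0.5), (roi_rx, roi_ry)), z_range)
    roi_b = Roi("mass_B", Ellipse((cx_b + 0.5, cy + 0.5), (roi_rx, roi_ry)), z_range)
    # integer translation of mass A's ROI into a signal-free corner keeps the
    # pixel count identical (translation invariance of pixel-center containment)
    dx = int(round((roi_rx + 1) - (cx_a + 0.5)))
    dy = int(round((roi_ry + 1) - (cy + 0.5)))
    roi_bg = roi_a.translated(dx, dy)
    roi_bg.name = "background"

    planted_ratio = max(f, 1 - f) / min(f, 1 - f)
    truth = GroundTruth(
        scenario="mitotic_late",
        seed=seed,
        noise=noise,
        params={
            "partition_fraction_f": f,
            "planted_ratio": planted_ratio,
            "totals_old": {"A": f * total_old, "B": (1 - f) * total_old},
            "totals_new": {"A": total_new / 2, "B": total_new / 2},
        },
        rois={"A": roi_a, "B": roi_b, "background": roi_bg},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Postmitotic pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairParams:
    """Planted per-cell levels for one postmitotic pair (cell order is spatial,
    left then right; Delta ordering happens downstream)."""

    delta: tuple[float, float] = (300_000.0, 100_000.0)
    old: tuple[float, float] = (300_000.0, 200_000.0)
    new: tuple[float, float] = (150_000.0, 220_000.0)
    separation_um: float = 4.5
    diameters_um: tuple[float, float] = (4.0, 4.0)
    edu: tuple[bool, bool] = (False, False)


def make_pair(
    pair_params: PairParams = PairParams(),
    *,
    shape: tuple[int, int, int] = (8, 64, 96),
    pixel_size_um: float = 0.25,
    z_step_um: float = 0.5,
    edu_amplitude: float = 300.0,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Two adjacent nuclei with channels old / new / DlnLacZ / EdU.

    Ground truth records planted totals per cell, the Delta ratio with its
    class (``> 2`` asymmetric), old/new log2 ratios of the Delta-high over
    the Delta-low cell, and the quadrant those ratios fall into.
    """
    p = pair_params
    nz, ny, nx = shape
    sep_px = p.separation_um / pixel_size_um
    radii_px = [d / 2 / pixel_size_um for d in p.diameters_um]
    if sep_px < sum(radii_px):
        raise ValueError(
            f"separation {p.separation_um} um smaller than the nucleus radii; nuclei overlap"
        )
    cz, cy = (nz - 1) / 2, (ny - 1) / 2
    cx1 = (nx - 1) / 2 - sep_px / 2
    cx2 = (nx - 1) / 2 + sep_px / 2
    if cx1 - radii_px[0] < 1 or cx2 + radii_px[1] > nx - 2:
        raise ValueError("pair does not fit inside the frame")
    rng = np.random.default_rng(seed)

    def _nucleus(cx: float, r_px: float) -> np.ndarray:
        rz = max(1.0, r_px * pixel_size_um / z_step_um)
        m = _ellipsoid_mask(shape, (cz, cy, cx), (rz, r_px, r_px)).astype(float)
        m *= 0.5 + gaussian_filter(rng.random(shape), 2.0)
        return gaussian_filter(m, 0.8)

    w1, w2 = _nucleus(cx1, radii_px[0]), _nucleus(cx2, radii_px[1])

    def _pair_channel(v1: float, v2: float) -> np.ndarray:
        return _normalized_weight(w1, v1) + _normalized_weight(w2, v2)

    old = _pair_channel(*p.old)
    new = _pair_channel(*p.new)
    dl = _pair_channel(*p.delta)
    edu = np.zeros(shape)
    for w, flag in ((w1, p.edu[0]), (w2, p.edu[1])):
        if flag:
            # binary-amplitude convention: core of the nucleus, not blur tails
            edu += np.where(w > 0.05 * w.max(), edu_amplitude, 0.0)

    data = np.stack([apply_noise(c, noise, rng) for c in (old, new, dl, edu)])
    stack = ImageStack(data, pixel_size_um, z_step_um, ("old", "new", "DlnLacZ", "EdU"))

    z_range = (0, nz - 1)
    rois = {}
    cells = []
    for i, (cx, r_px) in enumerate(((cx1, radii_px[0]), (cx2, radii_px[1])), start=1):
        roi_r = r_px + 2
        rois[f"cell{i}"] = Roi(
            f"cell{i}", Ellipse((cx + 0.5, cy + 0.5), (roi_r, roi_r)), z_range
        )
        cells.append(
            {
                "cell_id": f"cell{i}",
                "centroid_um": ((cx + 0.5) * pixel_size_um, (cy + 0.5) * pixel_size_um),
                "diameter_um": p.diameters_um[i - 1],
                "totals": {
                    "old": p.old[i - 1],
                    "new": p.new[i - 1],
                    "DlnLacZ": p.delta[i - 1],
                },
                "edu_positive": bool(p.edu[i - 1]),
            }
        )
    # equal-area background: integer translation of cell1's ROI to the corner
    roi1 = rois["cell1"]
    r1 = roi1.geometry.radii[0]
    bg = roi1.translated(
        int(round((r1 + 1) - roi1.geometry.center[0])),
        int(round((r1 + 1) - roi1.geometry.center[1])),
    )
    bg.name = "background"
    rois["background"] = bg

    hi, lo = (0, 1) if p.delta[0] >= p.delta[1] else (1, 0)
    delta_ratio = p.delta[hi] / p.delta[lo]
    old_log2 = float(np.log2(p.old[hi] / p.old[lo]))
    new_log2 = float(np.log2(p.new[hi] / p.new[lo]))
    truth = GroundTruth(
        scenario="pair",
        seed=seed,
        noise=noise,
        params={
            "delta_ratio": delta_ratio,
            "delta_class": "asymmetric" if delta_ratio > 2 else "symmetric",
            "old_log2": old_log2,
            "new_log2": new_log2,
            "quadrant": _quadrant_label(old_log2, new_log2),
            "delta_high_cell": f"cell{hi + 1}",
        },
        rois=rois,
        cells=cells,
    )
    return stack, truth


def _quadrant_label(old_log2: float, new_log2: float) -> str:
    if old_log2 == 0 and new_log2 == 0:
        return "origin"
    if old_log2 >= 0:
        return "I" if new_log2 >= 0 else "IV"
    return "II" if new_log2 >= 0 else "III"


# ---------------------------------------------------------------------------
# Tissue fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster of marker-positive cells."""

    centroid_um: tuple[float, float]
    n_cells: int


@dataclass
class FieldParams:
    """Layout of a planted 2D tissue field.

    ``eyfp_profile`` is the planted mean eYFP amplitude as a function of x,
    given either as a 1-D array of length ``shape_yx[1]`` or a callable of
    the x pixel coordinate.
    """

    shape_yx: tuple[int, int] = (256, 1024)
    pixel_size_um: float = 1.0
    clusters: Sequence[ClusterSpec] = ()
    cluster_spread_um: float = 4.0
    n_ee: int = 0
    n_ec: int = 0
    n_mitotic: int = 0
    eyfp_profile: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None
    cell_radius_px: float = 3.0
    ec_radius_px: float = 6.0
    amplitude: float = 2000.0


def plan_field(params: FieldParams, seed: int = 0) -> GroundTruth:
    """Lay out every planted cell (no rendering): id, type, position, cluster.

    Delta-positive cells are placed within ``cluster_spread_um`` of their
    cluster centroid so they stay inside any downstream adjacency radius at
    least as large; centroids must keep clusters inside the field.
    """
    h, w = params.shape_yx
    px = params.pixel_size_um
    rng = np.random.default_rng(seed)
    margin = params.cluster_spread_um + params.cell_radius_px * px
    cells: list[dict] = []
    cid = 0
    for k, spec in enumerate(params.clusters):
        cx, cy = spec.centroid_um
        if not (margin <= cx <= w * px - margin and margin <= cy <= h * px - margin):
            raise ValueError(f"cluster {k} at {spec.centroid_um} straddles the field border")
        for j in range(spec.n_cells):
            # members uniform in a disc of radius spread/2 -> pairwise <= spread
            r = params.cluster_spread_um / 2 * np.sqrt(rng.random())
            th = rng.random() * 2 * np.pi
            cells.append(
                {
                    "cell_id": f"dl{cid}",
                    "type": "delta",
                    "cluster_id": k,
                    "x_um": cx + r * np.cos(th),
                    "y_um": cy + r * np.sin(th),
                    "delta_positive": True,
                }
            )
            cid += 1
    for kind, n in (("ee", params.n_ee), ("ec", params.n_ec), ("mitotic", params.n_mitotic)):
        for j in range(n):
            cells.append(
                {
                    "cell_id": f"{kind}{j}",
                    "type": kind,
                    "cluster_id": None,
                    "x_um": float(rng.uniform(margin, w * px - margin)),
                    "y_um": float(rng.uniform(margin, h * px - margin)),
                    "delta_positive": False,
                }
            )
    return GroundTruth(
        scenario="midgut_field",
        seed=seed,
        noise=DEFAULT_NOISE,
        params={
            "shape_yx": list(params.shape_yx),
            "pixel_size_um": px,
            "n_clusters": len(params.clusters),
            "cluster_sizes": [s.n_cells for s in params.clusters],
        },
        cells=cells,
    )


_FIELD_CHANNELS = ("DlnLacZ", "eYFP", "H3S10ph", "Prospero", "DAPI")


def render_field(
    params: FieldParams,
    truth: GroundTruth,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int | None = None,
) -> ImageStack:
    """Render a planned field into a single-z multi-channel image."""
    h, w = params.shape_yx
    px = params.pixel_size_um
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    chans = {name: np.zeros((h, w)) for name in _FIELD_CHANNELS}
    yy, xx = np.mgrid[0:h, 0:w]

    def _blob(ch: np.ndarray, x_um: float, y_um: float, r_px: float, amp: float) -> None:
        cx, cy = x_um / px, y_um / px
        d2 = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2
        ch += amp * np.exp(-d2 / (2 * (r_px / 2) ** 2))

    amp = params.amplitude
    for c in truth.cells:
        x, y = c["x_um"], c["y_um"]
        if c["type"] == "delta":
            _blob(chans["DlnLacZ"], x, y, params.cell_radius_px, amp)
            _blob(chans["DAPI"], x, y, params.cell_radius_px, amp)
        elif c["type"] == "ee":
            _blob(chans["Prospero"], x, y, params.cell_radius_px, amp)
            _blob(chans["DAPI"], x, y, params.cell_radius_px, amp)
        elif c["type"] == "ec":
            _blob(chans["DAPI"], x, y, params.ec_radius_px, amp)
        elif c["type"] == "mitotic":
            _blob(chans["H3S10ph"], x, y, params.cell_radius_px, amp)
            _blob(chans["DAPI"], x, y, params.cell_radius_px, amp)

    if params.eyfp_profile is not None:
        prof = params.eyfp_profile
        xcoord = np.arange(w, dtype=float)
        profile = prof(xcoord) if callable(prof) else np.asarray(prof, dtype=float)
        if profile.shape != (w,):
            raise ValueError(f"eyfp_profile must have length {w}")
        chans["eYFP"] += np.broadcast_to(profile, (h, w))

    data = np.stack(
        [apply_noise(chans[name][np.newaxis], noise, rng) for name in _FIELD_CHANNELS]
    )
    return ImageStack(data, px, 1.0, _FIELD_CHANNELS)


def make_midgut_field(
    params: FieldParams,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Plan and render a field in one call."""
    truth = plan_field(params, seed=seed)
    truth.noise = noise
    stack = render_field(params, truth, noise=noise)
    return stack, truth


def sample_cluster_sizes(
    probs: Mapping[int, float], n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw cluster sizes from a size -> probability table (must sum to 1)."""
    sizes = np.array(sorted(probs), dtype=int)
    p = np.array([probs[s] for s in sizes], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    return rng.choice(sizes, size=n_clusters, p=p / p.sum())


# ---------------------------------------------------------------------------
# Synthetic per-cell value tables with planted summaries
# ---------------------------------------------------------------------------

def _shift_to_mean(values: np.ndarray, target_mean: float) -> np.ndarray:
    return values + (target_mean - values.mean())


def make_ratio_table(
    category_counts: Mapping[str, int],
    *,
    t_med: float = 1.15,
    t_high: float = 1.22,
    mean: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell segregation ratios with planted category counts and mean.

    ``category_counts`` maps ``symmetric`` / ``medium`` / ``high`` to counts.
    Symmetric values land in [1, t_med], medium in (t_med, t_high], high in
    (t_high, inf).  When ``mean`` is given the high-category values are
    shifted (staying above ``t_high``) so the exact arithmetic mean of the
    whole table equals it.
    """
    rng = np.random.default_rng(seed)
    n_sym = int(category_counts.get("symmetric", 0))
    n_med = int(category_counts.get("medium", 0))
    n_high = int(category_counts.get("high", 0))
    sym = rng.uniform(1.0, t_med, n_sym)
    med = rng.uniform(t_med + 1e-6, t_high, n_med)
    high = rng.uniform(t_high + 0.02, t_high + 0.5, n_high)
    if mean is not None:
        n = n_sym + n_med + n_high
        need = mean * n - sym.sum() - med.sum()
        if n_high == 0:
            raise ValueError("cannot plant a mean without high-category values")
        high = _shift_to_mean(high, need / n_high)
        if high.min() <= t_high:
            raise ValueError(
                f"target mean {mean} incompatible with category counts: "
                f"high values would cross {t_high}"
            )
    out = np.concatenate([sym, med, high])
    rng.shuffle(out)
    return out


def make_log2_table(n: int, mean: float, sd: float = 0.5, seed: int = 0) -> np.ndarray:
    """n log2 ratio values with an exact arithmetic mean (sd approximate)."""
    rng = np.random.default_rng(seed)
    return _shift_to_mean(rng.normal(mean, sd, n), mean)
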