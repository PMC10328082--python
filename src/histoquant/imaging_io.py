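"""Image and ROI input/output, and the shared spatial conventions.

Conventions
-----------
* Arrays are indexed ``(channel, z, y, x)``; all indices are 0-based and
  ``y`` increases downward (image convention).
* The pixel at integer index ``(y, x)`` occupies the unit square
  ``[x, x + 1) x [y, y + 1)`` in continuous coordinates; its center is at
  ``(x + 0.5, y + 0.5)``.  A pixel belongs to a polygon or ellipse ROI iff
  its center lies inside the geometry, which makes ROI pixel counts
  invariant under integer-pixel translations.
* Physical calibration (pixel size, z step, both in micrometers) is
  mandatory: downstream eligibility rules are physical distances, so a
  silent 1-um default would corrupt them.

Files
-----
Stacks are written as plain 16-bit multi-page TIFF with a JSON payload in
the ImageDescription tag carrying axes, calibration and channel names;
OME-TIFF and single-plane TIFFs from other tools are read via tifffile's
series axes.  ROIs travel in a JSON sidecar (schema: ``name``, ``type`` in
{polygon, ellipse, label}, geometry fields, ``z_range``) or as label-mask
TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import tifffile
from matplotlib.path import Path as _MplPath

__all__ = [
    "ImageStack",
    "Roi",
    "Polygon",
    "Ellipse",
    "LabelRef",
    "CalibrationError",
    "AxisOrderError",
    "EmptyRoiError",
    "read_stack",
    "write_stack",
    "roi_mask_2d",
    "roi_pixels",
    "load_rois",
    "save_rois",
]

_DESCRIPTION_KEY = "histoquant"


class CalibrationError(ValueError):
    """Pixel size / z step missing or invalid."""


class AxisOrderError(ValueError):
    """Axis order of a TIFF cannot be determined from its metadata."""


class EmptyRoiError(ValueError):
    """ROI geometry encloses no pixel center."""


@dataclass
class ImageStack:
    """A calibrated multi-channel z-stack.

    Parameters
    ----------
    data:
        Intensity array indexed ``(channel, z, y, x)``, non-negative, in
        arbitrary detector units.
    pixel_size_um:
        Physical edge length of one pixel in micrometers (> 0).
    z_step_um:
        Slice spacing in micrometers (> 0).
    channel_names:
        Ordered labels, one per channel.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4-D (channel, z, y, x); got shape {self.data.shape}"
            )
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise CalibrationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.z_step_um > 0):
            raise CalibrationError(f"z_step_um must be > 0, got {self.z_step_um}")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array of one named channel."""
        return self.data[self.channel_index(name)]


@dataclass(frozen=True)
class Polygon:
    """Polygon geometry; vertices are (x, y) continuous pixel coordinates."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse; center (x, y) and radii (rx, ry) in pixels."""

    center: tuple[float, float]
    radii: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.radii) <= 0:
            raise ValueError("ellipse radii must be > 0")


@dataclass(frozen=True)
class LabelRef:
    """Reference to one integer value in a label-mask image."""

    label: int


Geometry = Union[Polygon, Ellipse, LabelRef]


@dataclass
class Roi:
    """A named spatial selection with an inclusive z range.

    ``label_mask`` (a 2-D integer array) must be supplied when the geometry
    is a :class:`LabelRef`.
    """

    name: str
    geometry: Geometry
    z_range: tuple[int, int]
    label_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        z0, z1 = int(self.z_range[0]), int(self.z_range[1])
        if z0 < 0 or z1 < z0:
            raise ValueError(f"bad z_range {self.z_range}")
        self.z_range = (z0, z1)
        if isinstance(self.geometry, LabelRef) and self.label_mask is None:
            raise ValueError("LabelRef geometry requires a label_mask")

    def translated(self, dx: int, dy: int) -> "Roi":
        """Return a copy translated by integer pixel offsets (dx, dy)."""
        g = self.geometry
        if isinstance(g, Polygon):
            g2: Geometry = Polygon(tuple((x + dx, y + dy) for x, y in g.vertices))
        elif isinstance(g, Ellipse):
            g2 = Ellipse((g.center[0] + dx, g.center[1] + dy), g.radii)
        else:
            raise TypeError("cannot translate a label-mask ROI")
        return Roi(self.name, g2, self.z_range)


def _pixel_centers(shape_yx: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape_yx
    ys, xs = np.mgrid[0:h, 0:w]
    return xs + 0.5, ys + 0.5


def roi_mask_2d(roi: Roi, shape_yx: tuple[int, int]) -> np.ndarray:
    """Boolean (y, x) footprint of the ROI geometry on a frame of given shape."""
    g = roi.geometry
    if isinstance(g, LabelRef):
        mask = np.asarray(roi.label_mask) == g.label
        if mask.shape != tuple(shape_yx):
            raise ValueError(
                f"label mask shape {mask.shape} != frame shape {tuple(shape_yx)}"
            )
        return mask
    cx, cy = _pixel_centers(shape_yx)
    if isinstance(g, Ellipse):
        (ex, ey), (rx, ry) = g.center, g.radii
        return ((cx - ex) / rx) ** 2 + ((cy - ey) / ry) ** 2 <= 1.0
    # polygon: matplotlib point-in-polygon on pixel centers
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    inside = _MplPath(np.asarray(g.vertices)).contains_points(pts)
    return inside.reshape(shape_yx)


def roi_pixels(roi: Roi, stack: ImageStack) -> np.ndarray:
    """All (z, y, x) indices selected by the ROI, as an ``(n, 3)`` int array.

    Raises :class:`EmptyRoiError` if the geometry encloses no pixel center
    and ``ValueError`` if the z range exceeds the stack bounds.
    """
    z0, z1 = roi.z_range
    if z1 >= stack.n_slices:
        raise ValueError(
            f"roi z_range {roi.z_range} outside stack with {stack.n_slices} slices"
        )
    mask = roi_mask_2d(roi, stack.shape_yx)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise EmptyRoiError(f"ROI {roi.name!r} selects no pixels")
    zs = np.arange(z0, z1 + 1)
    out = np.empty((zs.size * ys.size, 3), dtype=np.intp)
    out[:, 0] = np.repeat(zs, ys.size)
    out[:, 1] = np.tile(ys, zs.size)
    out[:, 2] = np.tile(xs, zs.size)
    return out


# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a 16-bit TIFF with calibration in the description tag.

    ``read_stack(write_stack(s)) == s`` on data, calibration and channel
    names.  Raises ``ValueError`` when intensities exceed the 16-bit range
    (that signals a simulator clipping bug upstream).
    """
    path = Path(path)
    data = np.asarray(stack.data)
    if data.size and (float(data.max()) > 65535 or float(data.min()) < 0):
        raise ValueError("intensities outside [0, 65535]; upstream clipping failed")
    data16 = np.rint(data).astype(np.uint16)
    # top-level "shape" doubles as tifffile 'shaped' metadata so singleton
    # axes survive the read
    meta = {
        "shape": list(data16.shape),
        _DESCRIPTION_KEY: {
            "axes": "CZYX",
            "shape": list(data16.shape),
            "pixel_size_um": float(stack.pixel_size_um),
            "z_step_um": float(stack.z_step_um),
            "channel_names": list(stack.channel_names),
        },
    }
    tifffile.imwrite(
        path,
        data16,
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
        metadata=None,
    )
    return path


def _parse_description(desc: str | None) -> dict | None:
    if not desc:
        return None
    try:
        payload = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return None
    if isinstance(payload, dict) and _DESCRIPTION_KEY in payload:
        return payload[_DESCRIPTION_KEY]
    return None


def _normalize_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with a tifffile axes string to (C, Z, Y, X)."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if sorted(set(axes)) != sorted(axes):
        raise AxisOrderError(f"duplicate axes in {axes!r}")
    unknown = set(axes) - set("CZYX")
    if unknown:
        raise AxisOrderError(f"unsupported axes {unknown} in {axes!r}")
    for missing in "CZYX":
        if missing not in axes:
            arr = arr[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(arr, order)


def read_stack(
    path: str | Path,
    calibration: Mapping[str, object] | str | Path | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into an :class:`ImageStack`.

    Calibration (``pixel_size_um``, ``z_step_um`` and optionally
    ``channel_names``) comes from the file's own description payload when
    present; otherwise it must be supplied via ``calibration`` — either a
    mapping or the path of a JSON sidecar.  Missing calibration raises
    :class:`CalibrationError` rather than defaulting.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        file_axes = series.axes
        desc = _parse_description(tif.pages[0].description)

    sidecar: dict = {}
    if calibration is not None:
        if isinstance(calibration, (str, Path)):
            sidecar = json.loads(Path(calibration).read_text())
        else:
            sidecar = dict(calibration)

    meta = desc or {}
    axes = str(meta.get("axes") or sidecar.get("axes") or file_axes)
    # tifffile squeezes singleton axes; restore the full written shape
    if "shape" in meta and tuple(meta["shape"]) != arr.shape:
        arr = arr.reshape(meta["shape"])
    if arr.ndim != len(axes):
        raise AxisOrderError(
            f"axes {axes!r} do not match array of {arr.ndim} dimensions"
        )
    if arr.ndim > 2 and not (meta or sidecar.get("axes")) and set(axes) - set("YX") <= {"Q", "I"}:
        raise AxisOrderError(
            f"cannot resolve axis order {axes!r} of {path.name}; "
            "supply 'axes' via the calibration sidecar"
        )
    data = _normalize_axes(arr, axes)

    def _get(key: str):
        if key in meta:
            return meta[key]
        if key in sidecar:
            return sidecar[key]
        raise CalibrationError(
            f"{key} missing from metadata of {path.name}; pass a calibration sidecar"
        )

    pixel_size = float(_get("pixel_size_um"))
    z_step = float(_get("z_step_um"))
    if pixel_size <= 0 or z_step <= 0:
        raise CalibrationError(
            f"non-positive calibration in {path.name}: {pixel_size}, {z_step}"
        )
    names = meta.get("channel_names") or sidecar.get("channel_names")
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data, pixel_size, z_step, tuple(names))


# ---------------------------------------------------------------------------
# ROI sidecars
# ---------------------------------------------------------------------------

def _roi_to_dict(roi: Roi) -> dict:
    g = roi.geometry
    d: dict = {"name": roi.name, "z_range": list(roi.z_range)}
    if isinstance(g, Polygon):
        d["type"] = "polygon"
        d["vertices"] = [list(v) for v in g.vertices]
    elif isinstance(g, Ellipse):
        d["type"] = "ellipse"
        d["center"] = list(g.center)
        d["radii"] = list(g.radii)
    elif isinstance(g, LabelRef):
        d["type"] = "label"
        d["label"] = int(g.label)
    else:  # pragma: no cover
        raise TypeError(type(g))
    return d


def _roi_from_dict(d: Mapping, label_mask: np.ndarray | None = None) -> Roi:
    kind = d["type"]
    z_range = tuple(d["z_range"])
    if kind == "polygon":
        geom: Geometry = Polygon(tuple(tuple(v) for v in d["vertices"]))
    elif kind == "ellipse":
        geom = Ellipse(tuple(d["center"]), tuple(d["radii"]))
    elif kind == "label":
        geom = LabelRef(int(d["label"]))
    else:
        raise ValueError(f"unknown ROI type {kind!r}")
    return Roi(str(d["name"]), geom, z_range, label_mask=label_mask)


def save_rois(rois: Iterable[Roi], path: str | Path) -> Path:
    """Write ROIs to a JSON sidecar."""
    path = Path(path)
    payload = [_roi_to_dict(r) for r in rois]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_rois(
    path: str | Path, label_mask: np.ndarray | None = None
) -> list[Roi]:
    """Read ROIs from a JSON sidecar; ``label_mask`` backs any label ROIs."""
    payload = json.loads(Path(path).read_text())
    return [_roi_from_dict(d, label_mask=label_mask) for d in payload]
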