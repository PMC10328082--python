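"""Postmitotic-pair eligibility, Delta classification and inheritance ratios.

A candidate pair of neighboring cells is eligible when the centroids are
within 5 um, neither cell is more than 1.5x the diameter of the other,
both are EdU-negative, and both carry quantifiable old and new histone
totals.  Within an eligible pair, cell 1 is the Delta-high cell; the Delta
ratio is therefore >= 1 and the pair is Delta-asymmetric iff the ratio
exceeds 2 (a ratio of exactly 2 is assigned to the conservative symmetric
class).  Old/new inheritance is summarized as log2(cell1 / cell2), and
fold changes are geometric: ``2 ** |mean log2|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .quantify import CellMeasurement

__all__ = [
    "PairRecord",
    "PairRejection",
    "DELTA_ASYMMETRY_CUTOFF",
    "MAX_PAIR_DISTANCE_UM",
    "MAX_SIZE_RATIO",
    "pair_filter",
    "classify_pair_delta",
    "pair_log2_ratios",
    "fold_from_log2",
    "quadrant",
    "build_pair_record",
    "pair_summary",
]

MAX_PAIR_DISTANCE_UM = 5.0
MAX_SIZE_RATIO = 1.5
DELTA_ASYMMETRY_CUTOFF = 2.0
_REQUIRED_CHANNELS = ("old", "new")


@dataclass(frozen=True)
class PairRecord:
    """One eligible pair; ``cell1`` is the Delta-high cell."""

    cell1: CellMeasurement
    cell2: CellMeasurement
    delta_ratio: float
    delta_class: str
    old_log2: float
    new_log2: float
    quadrant: str

    @property
    def specimen(self) -> str | None:
        return self.cell1.specimen


@dataclass(frozen=True)
class PairRejection:
    cell_ids: tuple[str, str]
    reason: str


def _distance_um(a: CellMeasurement, b: CellMeasurement) -> float:
    (ax, ay), (bx, by) = a.centroid_um, b.centroid_um
    return float(np.hypot(ax - bx, ay - by))


def pair_filter(
    cells: Sequence[CellMeasurement],
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
    *,
    max_distance_um: float = MAX_PAIR_DISTANCE_UM,
    max_size_ratio: float = MAX_SIZE_RATIO,
    quantifiability_floor: float = 0.0,
    delta_channel: str = "DlnLacZ",
) -> tuple[list[tuple[CellMeasurement, CellMeasurement]], list[PairRejection]]:
    """Select eligible pairs and record a rejection reason per failed rule.

    ``candidate_pairs`` names neighbor candidates by cell id; when omitted,
    every cell is paired with its nearest neighbor within
    ``max_distance_um`` (each unordered pair considered once).  Rules, in
    the order reported: distance, size, EdU, quantifiability.  Cells must
    carry old and new totals and an EdU flag; missing ones raise.
    """
    by_id = {c.cell_id: c for c in cells}
    if candidate_pairs is None:
        candidate_pairs = _nearest_neighbor_pairs(cells, max_distance_um)

    eligible: list[tuple[CellMeasurement, CellMeasurement]] = []
    rejections: list[PairRejection] = []
    for id_a, id_b in candidate_pairs:
        a, b = by_id[id_a], by_id[id_b]
        for c in (a, b):
            for ch in _REQUIRED_CHANNELS:
                c.total(ch)  # raises KeyError if missing
            if c.edu_positive is None:
                raise ValueError(f"cell {c.cell_id!r} has no EdU flag")
        ids = (id_a, id_b)
        reasons: list[str] = []
        d = _distance_um(a, b)
        if d > max_distance_um:
            reasons.append(f"distance {d:.2f} um > {max_distance_um}")
        size_ratio = max(a.diameter_um, b.diameter_um) / min(a.diameter_um, b.diameter_um)
        if size_ratio > max_size_ratio:
            reasons.append(f"size ratio {size_ratio:.2f} > {max_size_ratio}")
        if a.edu_positive or b.edu_positive:
            reasons.append("EdU positive")
        if any(
            c.total(ch) <= quantifiability_floor
            for c in (a, b)
            for ch in _REQUIRED_CHANNELS
        ):
            reasons.append("histone totals below quantifiability floor")
        if reasons:
            rejections.append(PairRejection(ids, "; ".join(reasons)))
            continue
        a.total(delta_channel)
        b.total(delta_channel)
        eligible.append((a, b))
    return eligible, rejections


def _nearest_neighbor_pairs(
    cells: Sequence[CellMeasurement], max_distance_um: float
) -> list[tuple[str, str]]:
    seen: set[frozenset[str]] = set()
    out: list[tuple[str, str]] = []
    for c in cells:
        best, best_d = None, np.inf
        for other in cells:
            if other is c:
                continue
            d = _distance_um(c, other)
            if d < best_d:
                best, best_d = other, d
        if best is not None and best_d <= max_distance_um:
            key = frozenset((c.cell_id, best.cell_id))
            if key not in seen:
                seen.add(key)
                out.append((c.cell_id, best.cell_id))
    return out


def classify_pair_delta(dl1: float, dl2: float) -> tuple[float, str]:
    """Delta ratio (max/min) and its class: asymmetric iff ratio > 2."""
    if not (dl1 > 0 and dl2 > 0):
        raise ValueError(f"Delta totals must be positive, got ({dl1}, {dl2})")
    ratio = max(dl1, dl2) / min(dl1, dl2)
    cls = "asymmetric" if ratio > DELTA_ASYMMETRY_CUTOFF else "symmetric"
    return ratio, cls


def pair_log2_ratios(
    cell1: CellMeasurement, cell2: CellMeasurement
) -> tuple[float, float]:
    """log2(cell1/cell2) for the old and new channels (cell1 = Delta-high)."""
    vals = {}
    for ch in _REQUIRED_CHANNELS:
        v1, v2 = cell1.total(ch), cell2.total(ch)
        if not (v1 > 0 and v2 > 0):
            raise ValueError(
                f"non-positive {ch} total in pair ({cell1.cell_id}, {cell2.cell_id})"
            )
        vals[ch] = float(np.log2(v1 / v2))
    return vals["old"], vals["new"]


def fold_from_log2(mean_log2: float) -> float:
    """Geometric fold-change magnitude: ``2 ** |mean_log2|``."""
    if not np.isfinite(mean_log2):
        raise ValueError(f"mean_log2 must be finite, got {mean_log2}")
    return float(2.0 ** abs(mean_log2))


def quadrant(old_log2: float, new_log2: float) -> str:
    """Quadrant of (x=old_log2, y=new_log2): I (+,+), II (-,+), III (-,-),
    IV (+,-); 'origin' when both are exactly 0.  A value of exactly 0 on a
    single axis counts as positive."""
    if not (np.isfinite(old_log2) and np.isfinite(new_log2)):
        raise ValueError("log2 ratios must be finite")
    if old_log2 == 0 and new_log2 == 0:
        return "origin"
    if old_log2 >= 0:
        return "I" if new_log2 >= 0 else "IV"
    return "II" if new_log2 >= 0 else "III"


def build_pair_record(a: CellMeasurement, b: CellMeasurement,
                      delta_channel: str = "DlnLacZ") -> PairRecord:
    """Order the two cells by Delta level (ties broken by cell id for
    determinism) and compute all derived pair quantities."""
    dla, dlb = a.total(delta_channel), b.total(delta_channel)
    if dla > dlb or (dla == dlb and a.cell_id <= b.cell_id):
        c1, c2 = a, b
    else:
        c1, c2 = b, a
    delta_ratio, delta_class = classify_pair_delta(
        c1.total(delta_channel), c2.total(delta_channel)
    )
    old_log2, new_log2 = pair_log2_ratios(c1, c2)
    return PairRecord(
        cell1=c1,
        cell2=c2,
        delta_ratio=delta_ratio,
        delta_class=delta_class,
        old_log2=old_log2,
        new_log2=new_log2,
        quadrant=quadrant(old_log2, new_log2),
    )


def pair_summary(pairs: Sequence[PairRecord]) -> dict:
    """Per-class statistics with specimen-level averaging of proportions.

    Class proportions are computed per specimen and then averaged across
    specimens (mean +/- SEM of the per-specimen percentages), matching the
    per-midgut reporting convention; pooled counts are reported alongside
    for chi-square use.  Per-class mean +/- SEM of the log2 ratios are
    pooled over pairs.
    """
    if not pairs:
        raise ValueError("no pairs to summarize")
    specimens: dict[str, list[PairRecord]] = {}
    for p in pairs:
        specimens.setdefault(p.specimen or "_pooled", []).append(p)

    per_spec_pct = {"asymmetric": [], "symmetric": []}
    for recs in specimens.values():
        n = len(recs)
        n_asym = sum(1 for p in recs if p.delta_class == "asymmetric")
        per_spec_pct["asymmetric"].append(100.0 * n_asym / n)
        per_spec_pct["symmetric"].append(100.0 * (n - n_asym) / n)

    def _mean_sem(x: list[float]) -> tuple[float, float]:
        arr = np.asarray(x, dtype=np.float64)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return float(arr.mean()), sem

    out: dict = {
        "n_pairs": len(pairs),
        "n_specimens": len(specimens),
        "pooled_counts": {
            cls: sum(1 for p in pairs if p.delta_class == cls)
            for cls in ("asymmetric", "symmetric")
        },
        "class_percent": {},
        "log2": {},
    }
    for cls in ("asymmetric", "symmetric"):
        mean, sem = _mean_sem(per_spec_pct[cls])
        out["class_percent"][cls] = {"mean": mean, "sem": sem}
        recs = [p for p in pairs if p.delta_class == cls]
        if recs:
            old = np.array([p.old_log2 for p in recs])
            new = np.array([p.new_log2 for p in recs])
            out["log2"][cls] = {
                "n": len(recs),
                "old_mean": float(old.mean()),
                "old_sem": float(old.std(ddof=1) / np.sqrt(old.size)) if old.size > 1 else 0.0,
                "new_mean": float(new.mean()),
                "new_sem": float(new.std(ddof=1) / np.sqrt(new.size)) if new.size > 1 else 0.0,
            }
    return out
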