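"""Barrier-elicited field repetition: the BVC classification criterion.

A boundary cell firing along, say, the south wall is predicted — if it is a
BVC — to fire along the *north* side of a barrier inserted perpendicular to
its preferred direction, because positions just north of the barrier now also
have a proximal boundary to the south.  The criterion: firing at or above 40%
of the locational peak rate along 50% or more of the bins directly abutting
the predicted side of the barrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.ops import nearest_points

from .environment import Environment
from .ratemaps import RateMap

__all__ = [
    "FieldPeak",
    "PredictedSide",
    "CoverageResult",
    "ClassificationResult",
    "field_peak",
    "outer_portion",
    "predicted_side",
    "barrier_coverage",
    "boundary_off_coverage",
    "classify_bvc",
]

COVERAGE_RATE_FRACTION = 0.4  # of locational peak
COVERAGE_LENGTH_FRACTION = 50.0  # percent of abutting bins

_COMPASS = ["east", "northeast", "north", "northwest", "west", "southwest", "south", "southeast"]


def compass_label(angle: float) -> str:
    """Eight-way compass label for an allocentric angle (radians CCW from
    east)."""
    k = int(np.round(np.mod(angle, 2 * np.pi) / (np.pi / 4))) % 8
    return _COMPASS[k]


@dataclass(frozen=True)
class FieldPeak:
    """Location (bin centre) and rate of the maximal smoothed locational
    bin."""

    position: tuple[float, float]
    rate: float
    distance_to_centre: float


@dataclass(frozen=True)
class PredictedSide:
    """The barrier face where a second field is predicted.

    ``phi_pref`` is the inferred preferred allocentric direction (from the
    baseline field peak toward the nearest perimeter point); the predicted
    face is the one whose outward normal points the opposite way.
    """

    phi_pref: float
    face_normal: float
    label: str


@dataclass(frozen=True)
class CoverageResult:
    """Outcome of the coverage criterion along the predicted barrier face."""

    side: PredictedSide | float
    abutting: tuple[tuple[int, int], ...]
    threshold_rate: float
    n_abutting: int
    n_above: int
    coverage: float  # percent
    is_bvc: bool


@dataclass(frozen=True)
class ClassificationResult:
    eligible: bool
    is_bvc: bool
    reason: str
    peak: FieldPeak | None = None
    side: PredictedSide | None = None
    coverage: CoverageResult | None = None


def field_peak(rate_map: RateMap, env: Environment | None = None) -> FieldPeak:
    """Bin centre of the maximal (smoothed) rate over visited bins.

    Exact ties are broken by the lowest row-major bin index (x-major, the
    scan order of the rate array).
    """
    rate = np.where(rate_map.visited, rate_map.rate, np.nan)
    if not np.any(np.nan_to_num(rate, nan=0.0) > 0):
        raise ValueError("rate map has no visited bin with nonzero rate")
    i, j = np.unravel_index(np.nanargmax(rate), rate.shape)
    cx, cy = rate_map.bin_centres()
    pos = (float(cx[i]), float(cy[j]))
    return FieldPeak(pos, float(rate[i, j]), math.hypot(*pos))


def outer_portion(peak: FieldPeak, env: Environment, fraction: float = 0.75) -> bool:
    """True iff the peak lies in the outer portion of a circular environment:
    at or beyond ``fraction`` of the floor radius (boundary inclusive)."""
    if not env.is_circular:
        raise ValueError(f"outer_portion requires a circular environment, got {env.name!r}")
    return peak.distance_to_centre >= fraction * env.radius


def predicted_side(
    baseline_map: RateMap, env: Environment, field_fraction: float = 0.5
) -> PredictedSide:
    """Infer the preferred direction from the baseline field and return the
    barrier side where field repetition is predicted.

    The preferred direction points from the field toward the nearest
    perimeter point (a field along the south wall means the boundary is
    preferentially south of the animal); the predicted barrier face is the
    opposite one.  The field location is the rate-weighted centroid of bins
    at or above ``field_fraction`` of the peak, which is a far more stable
    direction estimate than the single peak bin when the field is an arc
    hugging a curved wall.
    """
    peak = field_peak(baseline_map, env)
    in_field = baseline_map.visited & (
        np.nan_to_num(baseline_map.rate, nan=0.0) >= field_fraction * peak.rate
    )
    cx, cy = baseline_map.bin_centres()
    w = np.where(in_field, baseline_map.rate, 0.0)
    p = Point(
        float((w * cx[:, None]).sum() / w.sum()),
        float((w * cy[None, :]).sum() / w.sum()),
    )
    q = nearest_points(env.floor.exterior, p)[0]
    dx, dy = q.x - p.x, q.y - p.y
    if math.hypot(dx, dy) < 1e-9:
        raise ValueError("field peak lies on the perimeter; direction ill-defined")
    if abs(p.x) < 1e-9 and abs(p.y) < 1e-9 and env.is_circular:
        raise ValueError("field peak at the exact centre; no nearest perimeter direction")
    phi = math.atan2(dy, dx)
    normal = phi + math.pi
    return PredictedSide(phi, normal, compass_label(normal))


def _abutting_bins(
    rate_map: RateMap, env: Environment, face_normal: float, abut_depth: float | None
) -> list[tuple[int, int]]:
    """Visited bins within one bin-width outward of the predicted 50 cm face,
    inside the barrier's along-axis extent."""
    if env.barrier is None:
        raise ValueError("environment contains no barrier")
    if abut_depth is None:
        abut_depth = rate_map.bin_size
    pa, pb = env.barrier.face(face_normal)
    u = np.array([math.cos(face_normal), math.sin(face_normal)])
    sign = 1.0 if float(u @ env.barrier.normal) >= 0 else -1.0
    out = sign * env.barrier.normal * abut_depth
    band = Polygon([tuple(pa), tuple(pb), tuple(pb + out), tuple(pa + out)])
    xe, ye = rate_map.x_edges, rate_map.y_edges
    xmin, ymin, xmax, ymax = band.bounds
    i0 = max(int(np.searchsorted(xe, xmin, "right")) - 1, 0)
    i1 = min(int(np.searchsorted(xe, xmax, "left")), len(xe) - 1)
    j0 = max(int(np.searchsorted(ye, ymin, "right")) - 1, 0)
    j1 = min(int(np.searchsorted(ye, ymax, "left")), len(ye) - 1)
    bins = []
    for i in range(i0, i1):
        for j in range(j0, j1):
            if not rate_map.visited[i, j]:
                continue
            cell = box(xe[i], ye[j], xe[i + 1], ye[j + 1])
            if cell.intersection(band).area > 1e-9:
                bins.append((i, j))
    return bins


def barrier_coverage(
    barrier_map: RateMap,
    env_with_barrier: Environment,
    side: PredictedSide | float,
    rate_fraction: float = COVERAGE_RATE_FRACTION,
    abut_depth: float | None = None,
) -> CoverageResult:
    """Coverage of the predicted barrier side by the second field.

    Coverage is the percentage of abutting bins whose (smoothed) rate is at
    least ``rate_fraction`` of the map's locational peak; at least 50%
    classifies the cell as a BVC.
    """
    face_normal = side.face_normal if isinstance(side, PredictedSide) else float(side)
    bins = _abutting_bins(barrier_map, env_with_barrier, face_normal, abut_depth)
    if not bins:
        raise ValueError("no visited bins abut the predicted barrier side")
    threshold = rate_fraction * barrier_map.peak_rate
    rates = np.array([barrier_map.rate[i, j] for i, j in bins])
    n_above = int(np.sum(rates >= threshold))
    coverage = 100.0 * n_above / len(bins)
    return CoverageResult(
        side, tuple(bins), threshold, len(bins), n_above, coverage,
        coverage >= COVERAGE_LENGTH_FRACTION,
    )


def boundary_off_coverage(
    baseline_map: RateMap | None,
    barrier_map: RateMap,
    env_with_barrier: Environment,
    side: PredictedSide | float,
    low_fraction: float = 0.4,
    abut_depth: float | None = None,
) -> CoverageResult:
    """Inverse criterion for boundary-off cells: the predicted side should
    show a zone of *low* firing.

    Coverage is the percentage of abutting bins whose rate is at or below
    ``low_fraction`` of the barrier map's median visited-bin rate; the flag is
    set at 50% or more.  The threshold form is this package's own
    operationalisation (the original description of boundary-off responses is
    qualitative); ``low_fraction`` is configurable.  ``baseline_map`` is
    accepted for report symmetry and not used by the statistic.
    """
    face_normal = side.face_normal if isinstance(side, PredictedSide) else float(side)
    bins = _abutting_bins(barrier_map, env_with_barrier, face_normal, abut_depth)
    if not bins:
        raise ValueError("no visited bins abut the predicted barrier side")
    median = float(np.nanmedian(barrier_map.rate[barrier_map.visited]))
    threshold = low_fraction * median
    rates = np.array([barrier_map.rate[i, j] for i, j in bins])
    n_low = int(np.sum(rates <= threshold))
    coverage = 100.0 * n_low / len(bins)
    return CoverageResult(
        side, tuple(bins), threshold, len(bins), n_low, coverage,
        coverage >= COVERAGE_LENGTH_FRACTION,
    )


def classify_bvc(
    baseline_map: RateMap,
    barrier_map: RateMap,
    env: Environment,
    env_with_barrier: Environment,
    outer_fraction: float = 0.75,
    wall_bin_widths: float = 2.0,
    min_selectivity: float = 3.0,
) -> ClassificationResult:
    """Full field-repetition decision for one cell.

    Eligibility first: the baseline field must sit at or near the perimeter —
    peak in the outer portion (circles) or within ``wall_bin_widths`` bin
    widths of a wall (other floors) — and the baseline map must be spatially
    selective (peak at least ``min_selectivity`` times the mean rate), which
    screens out cells with no locational structure.  Ineligible cells get a
    labelled "not eligible" outcome, not an exception.  Eligible cells are
    then scored with :func:`barrier_coverage` on the predicted side.
    """
    try:
        peak = field_peak(baseline_map, env)
    except ValueError as exc:
        return ClassificationResult(False, False, f"not eligible: {exc}")

    mean = baseline_map.mean_rate()
    if mean <= 0 or peak.rate / mean < min_selectivity:
        return ClassificationResult(
            False, False,
            "not eligible: baseline map lacks locational selectivity "
            f"(peak/mean {peak.rate / mean if mean > 0 else float('inf'):.2f} < {min_selectivity})",
            peak=peak,
        )
    if env.is_circular:
        near_perimeter = outer_portion(peak, env, outer_fraction)
    else:
        d = Point(peak.position).distance(env.floor.exterior)
        near_perimeter = d <= wall_bin_widths * baseline_map.bin_size
    if not near_perimeter:
        return ClassificationResult(
            False, False, "not eligible: baseline field peak not at/near the perimeter", peak=peak
        )
    try:
        side = predicted_side(baseline_map, env)
        cov = barrier_coverage(barrier_map, env_with_barrier, side)
    except ValueError as exc:
        return ClassificationResult(True, False, f"criterion not evaluable: {exc}", peak=peak)
    return ClassificationResult(
        True, cov.is_bvc,
        f"coverage {cov.coverage:.0f}% on the {side.label} side",
        peak=peak, side=side, coverage=cov,
    )
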