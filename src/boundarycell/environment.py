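"""Testing environments and geometric queries.

The environments used in boundary-cell experiments are flat floors bounded by
either vertical walls or drop-type edges (the rim of an elevated platform).
Both kinds of edge act as boundaries for a boundary vector cell, so they share
one representation: a list of line segments tagged ``wall`` or ``drop``.

Conventions (used everywhere in this package): origin at the environment
centre, x increasing east, y increasing north, angles in radians
counter-clockwise from east, distances in cm. Geometry is strictly 2-D; wall
height and platform elevation are recorded as metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box

__all__ = [
    "BoundaryElement",
    "Barrier",
    "Environment",
    "make_standard_environment",
    "insert_barrier",
    "boundary_distance",
    "ray_segment_distances",
    "UnknownEnvironmentError",
    "BarrierPlacementError",
    "OutsideFloorError",
]

#: number of chords used to polygonise circular floors
CIRCLE_SEGMENTS = 180

#: standard barrier dimensions, cm
BARRIER_LENGTH = 50.0
BARRIER_THICKNESS = 3.0

STANDARD_NAMES = ("walled_circle", "walled_square", "unwalled_circle", "together", "apart")


class UnknownEnvironmentError(ValueError):
    """Raised for an unrecognised standard-environment name."""


class BarrierPlacementError(ValueError):
    """Raised when a barrier does not fit inside the floor."""


class OutsideFloorError(ValueError):
    """Raised when a query position is not strictly inside the floor."""


@dataclass(frozen=True)
class BoundaryElement:
    """One boundary segment: a wall or a drop edge, from ``p0`` to ``p1`` (cm)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    kind: str  # "wall" | "drop"

    def __post_init__(self) -> None:
        if self.kind not in ("wall", "drop"):
            raise ValueError(f"kind must be 'wall' or 'drop', got {self.kind!r}")
        if math.dist(self.p0, self.p1) == 0.0:
            raise ValueError("degenerate boundary element: p0 == p1")

    @property
    def length(self) -> float:
        return math.dist(self.p0, self.p1)


@dataclass(frozen=True)
class Barrier:
    """An upright barrier inserted into a walled environment.

    The barrier is a ``length`` x ``thickness`` rectangle centred at ``centre``
    with its long axis at ``orientation`` radians CCW from east.  Its two long
    faces are the ones the field-repetition criterion is applied to; the short
    end faces are walls too but never a "predicted side".
    """

    centre: tuple[float, float]
    orientation: float
    length: float = BARRIER_LENGTH
    thickness: float = BARRIER_THICKNESS

    @property
    def axis(self) -> np.ndarray:
        return np.array([math.cos(self.orientation), math.sin(self.orientation)])

    @property
    def normal(self) -> np.ndarray:
        return np.array([-math.sin(self.orientation), math.cos(self.orientation)])

    def footprint(self) -> Polygon:
        c = np.asarray(self.centre, dtype=float)
        a = self.axis * (self.length / 2.0)
        n = self.normal * (self.thickness / 2.0)
        return Polygon([tuple(c + a + n), tuple(c - a + n), tuple(c - a - n), tuple(c + a - n)])

    def face(self, side_normal_angle: float) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the 50 cm face whose outward normal is closest to the
        given allocentric angle."""
        c = np.asarray(self.centre, dtype=float)
        a = self.axis * (self.length / 2.0)
        n = self.normal * (self.thickness / 2.0)
        u = np.array([math.cos(side_normal_angle), math.sin(side_normal_angle)])
        sign = 1.0 if float(u @ self.normal) >= 0 else -1.0
        return c - a + sign * n, c + a + sign * n

    def wall_elements(self) -> list[BoundaryElement]:
        pts = list(self.footprint().exterior.coords)[:-1]
        return [
            BoundaryElement(tuple(pts[i]), tuple(pts[(i + 1) % 4]), "wall")
            for i in range(4)
        ]


class Environment:
    """A floor region plus its boundary elements.

    Compared by identity (two environments are the same object or different),
    which lets rate-field normalisation constants be cached per environment.
    """

    def __init__(
        self,
        name: str,
        floor: Polygon,
        elements: list[BoundaryElement],
        barrier: Barrier | None = None,
        metadata: dict | None = None,
    ):
        for el in elements:
            if floor.buffer(1e-6).disjoint(Point(el.p0)) or floor.buffer(1e-6).disjoint(Point(el.p1)):
                raise ValueError(f"boundary element {el} lies outside the floor")
        self.name = name
        self.floor = floor
        self.elements = list(elements)
        self.barrier = barrier
        self.metadata = dict(metadata or {})
        self._refresh_segments()

    def _refresh_segments(self) -> None:
        self._p0 = np.array([el.p0 for el in self.elements], dtype=float)
        self._p1 = np.array([el.p1 for el in self.elements], dtype=float)

    # ------------------------------------------------------------------ #

    @property
    def segment_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary segments as (K,2) start/end arrays, barrier included."""
        return self._p0, self._p1

    @property
    def is_circular(self) -> bool:
        return bool(self.metadata.get("circular", False))

    @property
    def radius(self) -> float:
        """Nominal floor radius (cm) for circular environments."""
        if not self.is_circular:
            raise ValueError(f"environment {self.name!r} is not circular")
        return float(self.metadata["radius"])

    def circumradius(self) -> float:
        verts = np.asarray(self.floor.exterior.coords)
        return float(np.hypot(verts[:, 0], verts[:, 1]).max())

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) is strictly inside the floor and outside the
        barrier footprint."""
        inside = shapely.contains_xy(self.floor, x, y)
        if self.barrier is not None:
            inside = inside & ~shapely.contains_xy(
                self.barrier.footprint().buffer(1e-9), x, y
            )
        return inside

    def free_floor(self) -> Polygon:
        """Floor minus the barrier footprint."""
        if self.barrier is None:
            return self.floor
        return self.floor.difference(self.barrier.footprint())

    def __repr__(self) -> str:  # pragma: no cover
        b = ", barrier" if self.barrier else ""
        return f"Environment({self.name!r}, {len(self.elements)} elements{b})"


# ---------------------------------------------------------------------- #
# standard environments


def _disk(radius: float, kind: str, name: str, meta: dict) -> Environment:
    theta = np.linspace(0.0, 2 * np.pi, CIRCLE_SEGMENTS, endpoint=False)
    verts = np.c_[radius * np.cos(theta), radius * np.sin(theta)]
    floor = Polygon([tuple(v) for v in verts])
    elements = [
        BoundaryElement(tuple(verts[i]), tuple(verts[(i + 1) % len(verts)]), kind)
        for i in range(len(verts))
    ]
    meta = dict(meta, circular=True, radius=radius)
    return Environment(name, floor, elements, metadata=meta)


def _rect(w: float, h: float, kind: str, name: str, meta: dict) -> Environment:
    floor = box(-w / 2, -h / 2, w / 2, h / 2)
    c = [(-w / 2, -h / 2), (w / 2, -h / 2), (w / 2, h / 2), (-w / 2, h / 2)]
    elements = [BoundaryElement(c[i], c[(i + 1) % 4], kind) for i in range(4)]
    return Environment(name, floor, elements, metadata=meta)


def make_standard_environment(name: str) -> Environment:
    """Build one of the standard testing environments.

    ``walled_circle``
        150 cm diameter floor with 50 cm high walls.
    ``walled_square``
        100 x 100 cm floor with 50 cm high walls.
    ``unwalled_circle``
        155 cm diameter elevated platform; the rim is a drop-type boundary.
    ``together``
        three 50 x 50 cm platforms juxtaposed into a 150 x 50 cm rectangle
        (drop perimeter).
    ``apart``
        the three platforms separated by two traversable 10 cm gaps.  The
        floor is the full 170 x 50 cm bounding rectangle (rats cross the
        gaps unaided) and every platform edge — including the four interior
        edges facing the gaps — is a drop element.
    """
    if name == "walled_circle":
        return _disk(75.0, "wall", name, {"wall_height_cm": 50.0})
    if name == "walled_square":
        return _rect(100.0, 100.0, "wall", name, {"wall_height_cm": 50.0})
    if name == "unwalled_circle":
        return _disk(77.5, "drop", name, {"elevation_cm": 30.0})
    if name == "together":
        return _rect(150.0, 50.0, "drop", name, {"elevation_cm": 50.0})
    if name == "apart":
        floor = box(-85.0, -25.0, 85.0, 25.0)
        elements: list[BoundaryElement] = []
        for cx in (-60.0, 0.0, 60.0):
            c = [
                (cx - 25.0, -25.0),
                (cx + 25.0, -25.0),
                (cx + 25.0, 25.0),
                (cx - 25.0, 25.0),
            ]
            elements += [BoundaryElement(c[i], c[(i + 1) % 4], "drop") for i in range(4)]
        return Environment(name, floor, elements, metadata={"elevation_cm": 50.0})
    raise UnknownEnvironmentError(
        f"unknown environment {name!r}; expected one of {STANDARD_NAMES}"
    )


def insert_barrier(
    env: Environment,
    centre: tuple[float, float] = (0.0, 0.0),
    orientation: float = 0.0,
    length: float = BARRIER_LENGTH,
    thickness: float = BARRIER_THICKNESS,
) -> Environment:
    """Return a copy of ``env`` with an upright barrier added.

    The barrier contributes four wall elements (two long faces, two end
    faces); the floor region is unchanged but the barrier footprint is
    excluded from valid positions.  Raises :class:`BarrierPlacementError` if
    the barrier touches the floor perimeter or an existing barrier.
    """
    if env.barrier is not None:
        raise BarrierPlacementError("environment already contains a barrier")
    barrier = Barrier(tuple(centre), float(orientation), length, thickness)
    fp = barrier.footprint()
    if not env.floor.buffer(-1e-9).contains(fp):
        raise BarrierPlacementError(
            f"barrier at {centre} (orientation {orientation:.3f} rad) intersects the floor perimeter"
        )
    out = Environment(
        env.name + "+barrier",
        env.floor,
        env.elements + barrier.wall_elements(),
        barrier=barrier,
        metadata=env.metadata,
    )
    return out


# ---------------------------------------------------------------------- #
# ray casting


try:  # compiled kernel; the numpy path below is the reference implementation
    from numba import njit

    @njit(fastmath=True, cache=False)
    def _ray_kernel(ox, oy, dx, dy, p0x, p0y, ex, ey, out):  # pragma: no cover
        for i in range(ox.shape[0]):
            for m in range(dx.shape[0]):
                best = np.inf
                for k in range(ex.shape[0]):
                    den = dx[m] * ey[k] - dy[m] * ex[k]
                    if abs(den) < 1e-12:
                        continue
                    wx = p0x[k] - ox[i]
                    wy = p0y[k] - oy[i]
                    t = (wx * ey[k] - wy * ex[k]) / den
                    if t <= 1e-9 or t >= best:
                        continue
                    s = (wx * dy[m] - wy * dx[m]) / den
                    if -1e-9 <= s <= 1.0 + 1e-9:
                        best = t
                out[i, m] = best

except ImportError:  # pragma: no cover
    _ray_kernel = None


def ray_segment_distances(
    origins: np.ndarray,
    angles: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Distance from each origin along each ray direction to the nearest
    segment, vectorised.

    Parameters
    ----------
    origins : (N, 2) ray start points.
    angles : (M,) allocentric ray directions, radians.
    p0, p1 : (K, 2) segment endpoints.
    chunk : origins processed per block to bound memory.

    Returns
    -------
    (N, M) array of distances; ``inf`` where a ray hits no segment.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    if _ray_kernel is not None:
        out = np.empty((origins.shape[0], angles.shape[0]))
        _ray_kernel(
            np.ascontiguousarray(origins[:, 0]),
            np.ascontiguousarray(origins[:, 1]),
            np.cos(angles),
            np.sin(angles),
            np.ascontiguousarray(p0[:, 0]),
            np.ascontiguousarray(p0[:, 1]),
            np.ascontiguousarray(p1[:, 0] - p0[:, 0]),
            np.ascontiguousarray(p1[:, 1] - p0[:, 1]),
            out,
        )
        return out
    dx = np.cos(angles)
    dy = np.sin(angles)  # (M,)
    ex = (p1[:, 0] - p0[:, 0]).astype(np.float64)
    ey = (p1[:, 1] - p0[:, 1]).astype(np.float64)  # (K,)
    # solve o + t*d = p0 + s*e via 2-D cross products:
    #   t = cross(p0 - o, e) / cross(d, e),  s = cross(p0 - o, d) / cross(d, e)
    denom = dx[:, None] * ey[None, :] - dy[:, None] * ex[None, :]  # (M,K)
    with np.errstate(divide="ignore"):
        inv_denom = np.where(np.abs(denom) > 1e-12, 1.0 / denom, np.nan)
    # origin-independent pieces
    a_we = p0[:, 0] * ey - p0[:, 1] * ex  # (K,)  cross(p0, e)
    b_wd = p0[None, :, 0] * dy[:, None] - p0[None, :, 1] * dx[:, None]  # (M,K)  cross(p0, d)
    out = np.empty((origins.shape[0], angles.shape[0]))
    for lo in range(0, origins.shape[0], chunk):
        ox = origins[lo : lo + chunk, 0][:, None, None]
        oy = origins[lo : lo + chunk, 1][:, None, None]
        we = a_we[None, None, :] - ox * ey[None, None, :] + oy * ex[None, None, :]
        t = we * inv_denom[None, :, :]
        s = (b_wd[None, :, :] - ox * dy[:, None][None, :, :] + oy * dx[:, None][None, :, :]) * inv_denom[None, :, :]
        t[~((t > 1e-9) & (s >= -1e-9) & (s <= 1 + 1e-9))] = np.inf  # NaNs compare False
        out[lo : lo + chunk] = t.min(axis=2)
    return out


def boundary_distance(env: Environment, position, direction: float) -> float:
    """Distance from ``position`` along the allocentric ``direction`` ray to
    the first boundary element (wall or drop), in cm.

    Returns ``inf`` if the ray escapes without hitting any element (possible
    only in open configurations such as the gap mouths of ``apart``).
    Raises :class:`OutsideFloorError` for positions not strictly inside the
    floor (or inside a barrier footprint).
    """
    position = np.asarray(position, dtype=float)
    if not bool(env.contains(position[0], position[1])):
        raise OutsideFloorError(f"position {tuple(position)} is not inside the floor")
    p0, p1 = env.segment_arrays
    d = ray_segment_distances(position[None, :], np.array([direction]), p0, p1)
    return float(d[0, 0])
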