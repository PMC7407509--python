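"""Parametric plan-view channel geometries on a rotating disk.

The devices modeled here are planar microchannels of constant depth ``H``
(extruded 2D outlines) placed on a spinning compact disk.  Two families are
provided:

* a contraction-expansion array separator: a narrow channel that repeatedly
  opens into one-sided expansion chambers and ends in a bifurcation with a
  target (large-cell) and a waste (small-cell) outlet;
* a serpentine micromixer with optional square obstacles, fed by two inlets
  (cell suspension and lysis buffer) and ending in one outlet.

All coordinates are SI meters.  Each geometry lives in a local frame with
``x`` the down-channel (radially outward) axis and ``y`` the lateral axis;
:func:`place_on_disk` fixes the mapping to disk coordinates, with the disk
center at the origin and the disk in the x-y plane.

Geometries are unions of axis-aligned rectangles minus obstacle rectangles,
which keeps containment, lateral-gap and meshing queries exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelSection",
    "Rect",
    "Port",
    "ContractionExpansionSpec",
    "SerpentineMixerSpec",
    "ChannelGeometry",
    "Mesh",
    "GeometryError",
    "hydraulic_diameter",
    "build_contraction_expansion_channel",
    "build_serpentine_mixer",
    "build_straight_channel",
    "place_on_disk",
    "generate_mesh",
]

UM = 1e-6


class GeometryError(ValueError):
    """Raised for invalid geometric specifications or failed construction."""


def hydraulic_diameter(width: float, height: float) -> float:
    """Hydraulic diameter ``2WH/(W+H)`` of a rectangular channel.

    Parameters
    ----------
    width, height : float
        Cross-section dimensions in meters; both must be positive.
    """
    if width <= 0 or height <= 0:
        raise GeometryError(
            f"channel dimensions must be positive, got W={width!r}, H={height!r}"
        )
    return 2.0 * width * height / (width + height)


@dataclass(frozen=True)
class ChannelSection:
    """A straight rectangular channel segment.

    ``width`` is the in-plane (lateral) dimension, ``height`` the extruded
    depth, ``length`` the down-channel extent.  ``orientation`` is the unit
    down-channel axis in the local plane.
    """

    width: float
    height: float
    length: float
    orientation: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.length) <= 0:
            raise GeometryError(
                "ChannelSection dimensions must be positive: "
                f"W={self.width}, H={self.height}, L={self.length}"
            )
        nx, ny = self.orientation
        norm = math.hypot(nx, ny)
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            object.__setattr__(self, "orientation", (nx / norm, ny / norm))

    @property
    def aspect_ratio(self) -> float:
        """Aspect ratio AR = W/H, the index into the lift-coefficient table."""
        return self.width / self.height

    @property
    def hydraulic_diameter(self) -> float:
        return hydraulic_diameter(self.width, self.height)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] x [y0, y1] in local plane coordinates."""

    x0: float
    x1: float
    y0: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise GeometryError(f"degenerate rectangle {self}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)
        )

    def contains_strict(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x > self.x0) & (x < self.x1) & (y > self.y0) & (y < self.y1)

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))


@dataclass(frozen=True)
class Port:
    """An inlet or outlet facet on the geometry boundary.

    ``axis`` is the axis normal to the port plane ('x' or 'y'), ``position``
    the plane coordinate, ``span`` the extent along the other axis and
    ``outward`` the sign of the outward normal along ``axis``.
    """

    label: str
    kind: str  # "inlet" | "outlet"
    axis: str
    position: float
    span: tuple[float, float]
    outward: int

    @property
    def width(self) -> float:
        return self.span[1] - self.span[0]

    @property
    def center(self) -> tuple[float, float]:
        mid = 0.5 * (self.span[0] + self.span[1])
        if self.axis == "x":
            return (self.position, mid)
        return (mid, self.position)


@dataclass(frozen=True)
class ContractionExpansionSpec:
    """Parametric contraction-expansion array separator.

    Defaults follow typical contraction-expansion-array sorters: 50 um wide
    contractions opening into 250 um one-sided expansion chambers, depth
    50 um, eight repeat units, placed with the inlet 3 cm from the disk
    center.  The bifurcation split coordinate defaults to the collector
    midline.
    """

    contraction: ChannelSection = ChannelSection(50 * UM, 50 * UM, 200 * UM)
    expansion: ChannelSection = ChannelSection(250 * UM, 50 * UM, 400 * UM)
    n_units: int = 8
    inlet: ChannelSection = ChannelSection(50 * UM, 50 * UM, 200 * UM)
    outlet_lower: ChannelSection = ChannelSection(50 * UM, 50 * UM, 300 * UM)
    outlet_upper: ChannelSection = ChannelSection(50 * UM, 50 * UM, 300 * UM)
    collector_length: float = 200 * UM
    septum: float = 5 * UM
    split_y: float | None = None  # None -> collector midline
    radial_offset: float = 0.03

    def __post_init__(self) -> None:
        if self.expansion.width <= self.contraction.width:
            raise GeometryError("expansion width must exceed contraction width")
        if self.n_units < 1:
            raise GeometryError("need at least one contraction-expansion unit")
        if self.radial_offset <= 0:
            raise GeometryError("radial offset must be positive")
        heights = {
            self.contraction.height,
            self.expansion.height,
            self.inlet.height,
            self.outlet_lower.height,
            self.outlet_upper.height,
        }
        if len(heights) != 1:
            raise GeometryError("all separator sections must share one depth H")


@dataclass(frozen=True)
class SerpentineMixerSpec:
    """Parametric serpentine micromixer with optional square obstacles.

    The channel zig-zags through ``n_turns`` 90-degree corners (default 6,
    i.e. three down-channel legs joined by two risers) for a total
    centerline length of about 2.5 mm.  Obstacles are 40 um squares attached
    alternately to the two side walls; ``obstacle_stations`` lists
    (centerline arc length, side) pairs, side +1 meaning the left wall
    (larger lateral coordinate looking down-channel).
    """

    cross_section: ChannelSection = ChannelSection(100 * UM, 50 * UM, 2500 * UM)
    n_turns: int = 6
    obstacle_edge: float = 40 * UM
    obstacles_enabled: bool = True
    obstacle_stations: tuple[tuple[float, int], ...] | None = None
    leg_pitch: float = 300 * UM
    merge_length: float = 300 * UM
    radial_offset: float = 0.043

    def __post_init__(self) -> None:
        if self.obstacle_edge >= self.cross_section.width:
            raise GeometryError("obstacle edge must be smaller than channel width")
        if self.n_turns < 0 or self.n_turns % 2:
            raise GeometryError("n_turns must be a nonnegative even number")
        if self.radial_offset <= 0:
            raise GeometryError("radial offset must be positive")

    @property
    def n_legs(self) -> int:
        return self.n_turns // 2 + 1


@dataclass
class Placement:
    """World-frame placement of a geometry on the disk."""

    radial_offset: float
    azimuth: float = 0.0


@dataclass
class ChannelGeometry:
    """A planar channel as a union of fluid rectangles minus obstacles.

    Provides the containment, lateral-gap, nearest-wall and disk-placement
    queries the flow solver and particle tracker rely on.  ``centerline`` is
    a polyline (down-channel path) used to parameterize stations by arc
    length; ``y_ref`` is the lateral coordinate mapped onto the placement
    radius.
    """

    kind: str
    fluid_rects: list[Rect]
    obstacle_rects: list[Rect]
    height: float
    ports: dict[str, Port]
    centerline: np.ndarray
    y_ref: float
    placement: Placement | None = None
    split_y: float | None = None
    spec: object | None = None

    # -- basic queries ----------------------------------------------------

    @property
    def bounding_box(self) -> Rect:
        xs0 = min(r.x0 for r in self.fluid_rects)
        xs1 = max(r.x1 for r in self.fluid_rects)
        ys0 = min(r.y0 for r in self.fluid_rects)
        ys1 = max(r.y1 for r in self.fluid_rects)
        return Rect(xs0, xs1, ys0, ys1)

    @property
    def volume(self) -> float:
        """Analytic fluid volume (rectangles are non-overlapping by construction)."""
        area = sum(r.area for r in self.fluid_rects)
        area -= sum(r.area for r in self.obstacle_rects)
        return area * self.height

    @property
    def inlets(self) -> list[Port]:
        return [p for p in self.ports.values() if p.kind == "inlet"]

    @property
    def outlets(self) -> list[Port]:
        return [p for p in self.ports.values() if p.kind == "outlet"]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point-in-fluid test (boundary counts as inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = pts[:, 0], pts[:, 1]
        inside = np.zeros(len(pts), dtype=bool)
        for r in self.fluid_rects:
            inside |= r.contains(x, y)
        for r in self.obstacle_rects:
            inside &= ~r.contains_strict(x, y)
        if np.ndim(points) == 1:
            return inside[0]
        return inside

    def lateral_gap(self, x: float, y: float) -> tuple[float, float]:
        """Return the lateral fluid interval (y_lo, y_hi) containing (x, y).

        Merges the y-intervals of all fluid rectangles covering station
        ``x`` and subtracts obstacles, then picks the interval containing
        ``y``.  Raises :class:`GeometryError` outside the fluid.
        """
        intervals = sorted(
            (r.y0, r.y1) for r in self.fluid_rects if r.x0 <= x <= r.x1
        )
        if not intervals:
            raise GeometryError(f"station x={x} outside geometry")
        merged: list[list[float]] = [list(intervals[0])]
        for lo, hi in intervals[1:]:
            if lo <= merged[-1][1] + 1e-15:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        pieces: list[tuple[float, float]] = [tuple(m) for m in merged]
        for ob in self.obstacle_rects:
            if ob.x0 < x < ob.x1:
                nxt: list[tuple[float, float]] = []
                for lo, hi in pieces:
                    if ob.y1 <= lo or ob.y0 >= hi:
                        nxt.append((lo, hi))
                        continue
                    if ob.y0 > lo:
                        nxt.append((lo, ob.y0))
                    if ob.y1 < hi:
                        nxt.append((ob.y1, hi))
                pieces = nxt
        for lo, hi in pieces:
            if lo <= y <= hi:
                return (lo, hi)
        raise GeometryError(f"point ({x}, {y}) not inside fluid at its station")

    def wall_distance(self, point: Sequence[float]) -> tuple[float, np.ndarray]:
        """Distance to the nearest lateral wall or obstacle face, with the
        inward unit normal.

        The returned distance, normalized by the local lateral gap, is the
        nondimensional wall coordinate s in (0, 1) used by the lift model.
        """
        x, y = float(point[0]), float(point[1])
        lo, hi = self.lateral_gap(x, y)
        d_lo, d_hi = y - lo, hi - y
        if d_lo <= d_hi:
            dist, normal = d_lo, np.array([0.0, 1.0])
        else:
            dist, normal = d_hi, np.array([0.0, -1.0])
        for ob in self.obstacle_rects:
            if ob.y0 <= y <= ob.y1:
                if x <= ob.x0 and ob.x0 - x < dist:
                    dist, normal = ob.x0 - x, np.array([-1.0, 0.0])
                elif x >= ob.x1 and x - ob.x1 < dist:
                    dist, normal = x - ob.x1, np.array([1.0, 0.0])
        return dist, normal

    def wall_coordinate(self, x: float, y: float) -> tuple[float, float]:
        """Nondimensional lateral wall distance s (from the y_lo wall) and gap."""
        lo, hi = self.lateral_gap(x, y)
        gap = hi - lo
        return (y - lo) / gap, gap

    # -- placement --------------------------------------------------------

    def disk_position(self, points: np.ndarray) -> np.ndarray:
        """Disk-center position vectors for local points.

        The local frame is channel-aligned: local +x is radially outward,
        local +y the azimuthal direction of disk spin-axis cross radial.
        The inlet centerline (x = 0, y = y_ref) sits at the placement
        radius.  Channel curvature over the ~mm device extent is neglected.
        """
        if self.placement is None:
            raise GeometryError("geometry has not been placed on the disk")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty_like(pts)
        out[:, 0] = self.placement.radial_offset + pts[:, 0]
        out[:, 1] = pts[:, 1] - self.y_ref
        if np.ndim(points) == 1:
            return out[0]
        return out

    def to_world(self, points: np.ndarray) -> np.ndarray:
        """Rotate disk positions by the placement azimuth into world x-y."""
        disk = np.atleast_2d(self.disk_position(points))
        a = self.placement.azimuth
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        out = disk @ rot.T
        if np.ndim(points) == 1:
            return out[0]
        return out

    # -- stations ---------------------------------------------------------

    @property
    def arclength(self) -> np.ndarray:
        seg = np.diff(self.centerline, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])

    def station(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Centerline point and unit tangent at arc length ``s``."""
        arc = self.arclength
        if not 0.0 <= s <= arc[-1] + 1e-12:
            raise GeometryError(f"station s={s} outside [0, {arc[-1]}]")
        s = min(s, arc[-1])
        i = int(np.searchsorted(arc, s, side="right") - 1)
        i = min(i, len(arc) - 2)
        seg = self.centerline[i + 1] - self.centerline[i]
        seg_len = np.hypot(*seg)
        t = seg / seg_len
        point = self.centerline[i] + (s - arc[i]) * t
        return point, t

    def station_samples(self, s: float, n: int) -> np.ndarray:
        """``n`` area-uniform sample points across the cross-section at
        arc length ``s`` (the station is clipped to the fluid)."""
        point, t = self.station(s)
        normal = np.array([-t[1], t[0]])
        if abs(normal[0]) > abs(normal[1]):  # station cut along x
            lo, hi = self._axial_gap(point[1], point[0])
            frac = (np.arange(n) + 0.5) / n
            xs = lo + frac * (hi - lo)
            return np.column_stack([xs, np.full(n, point[1])])
        lo, hi = self.lateral_gap(point[0], point[1])
        frac = (np.arange(n) + 0.5) / n
        ys = lo + frac * (hi - lo)
        return np.column_stack([np.full(n, point[0]), ys])

    def _axial_gap(self, y: float, x: float) -> tuple[float, float]:
        intervals = sorted(
            (r.x0, r.x1) for r in self.fluid_rects if r.y0 <= y <= r.y1
        )
        merged: list[list[float]] = [list(intervals[0])]
        for lo, hi in intervals[1:]:
            if lo <= merged[-1][1] + 1e-15:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            if lo <= x <= hi:
                return (lo, hi)
        raise GeometryError(f"point ({x}, {y}) not inside fluid")


# -- builders -------------------------------------------------------------


def build_contraction_expansion_channel(
    spec: ContractionExpansionSpec | None = None,
) -> ChannelGeometry:
    """Build the separator: inlet, ``n_units`` contraction-expansion units
    with one-sided expansion chambers, a collector and a bifurcation into a
    lower (target, large-cell) and an upper (waste, small-cell) outlet.

    The straight reference wall runs along y = 0; expansion chambers bulge
    toward +y, the side toward which the Coriolis-driven secondary flow
    sweeps unfocused small cells.
    """
    spec = spec or ContractionExpansionSpec()
    wc, lc = spec.contraction.width, spec.contraction.length
    we, le = spec.expansion.width, spec.expansion.length
    H = spec.contraction.height

    rects: list[Rect] = []
    x = 0.0
    rects.append(Rect(x, x + spec.inlet.length, 0.0, spec.inlet.width))
    x += spec.inlet.length
    for _ in range(spec.n_units):
        rects.append(Rect(x, x + lc, 0.0, wc))
        x += lc
        rects.append(Rect(x, x + le, 0.0, we))
        x += le
    w_lo = spec.outlet_lower.width
    w_up = spec.outlet_upper.width
    coll_w = w_lo + spec.septum + w_up
    rects.append(Rect(x, x + spec.collector_length, 0.0, coll_w))
    x += spec.collector_length
    branch_len = max(spec.outlet_lower.length, spec.outlet_upper.length)
    rects.append(Rect(x, x + branch_len, 0.0, w_lo))
    rects.append(Rect(x, x + branch_len, w_lo + spec.septum, coll_w))
    x_end = x + branch_len

    ports = {
        "inlet": Port("inlet", "inlet", "x", 0.0, (0.0, spec.inlet.width), -1),
        "outlet_lower": Port(
            "outlet_lower", "outlet", "x", x_end, (0.0, w_lo), +1
        ),
        "outlet_upper": Port(
            "outlet_upper", "outlet", "x", x_end, (w_lo + spec.septum, coll_w), +1
        ),
    }
    centerline = np.array([[0.0, wc / 2], [x_end, wc / 2]])
    split = spec.split_y if spec.split_y is not None else coll_w / 2
    return ChannelGeometry(
        kind="separator",
        fluid_rects=rects,
        obstacle_rects=[],
        height=H,
        ports=ports,
        centerline=centerline,
        y_ref=spec.inlet.width / 2,
        split_y=split,
        spec=spec,
        placement=Placement(spec.radial_offset),
    )


def build_serpentine_mixer(spec: SerpentineMixerSpec | None = None) -> ChannelGeometry:
    """Build the serpentine mixer: two side-by-side inlets merging at x = 0,
    legs joined by risers, one outlet, and (optionally) square obstacles
    carved from the interior attached alternately to the side walls."""
    spec = spec or SerpentineMixerSpec()
    w = spec.cross_section.width
    H = spec.cross_section.height
    n = spec.n_legs
    total = spec.cross_section.length
    pitch = spec.leg_pitch

    # The two inlets feed a radial merge channel (along +x) so the
    # centrifugal head drives both streams in symmetrically; the merged
    # stream then zig-zags through legs along y (azimuthal) at radial
    # stations x_i = (Lm - w/2) + i*pitch, joined by radially outward
    # risers, so every stage advances outward.  Risers sit at lateral
    # levels yL = w/2 (near side) and yR (far side); yR is chosen so the
    # centerline arc length equals the requested total:
    #   total = (Lm - w/2) + (n-1)(yR - w/2) + yR + (n-1) pitch
    Lm = spec.merge_length
    if Lm <= 1.5 * w:
        raise GeometryError("merge_length must exceed 1.5 channel widths")
    yL = w / 2
    if n >= 2:
        yR = (total - (Lm - w / 2) + (n - 1) * (w / 2) - (n - 1) * pitch) / n
    else:
        yR = total - (Lm - w / 2)
    if yR - yL <= 2 * w:
        raise GeometryError("total length too short for the requested turn count")
    y_top = yR + w / 2
    x0_leg = Lm - w / 2  # first leg centerline (radial station)

    rects: list[Rect] = [Rect(0.0, Lm - w, 0.0, w)]  # merge channel
    pts: list[list[float]] = [[0.0, w / 2], [x0_leg, w / 2]]
    for i in range(n):
        x_c = x0_leg + i * pitch
        rects.append(Rect(x_c - w / 2, x_c + w / 2, 0.0, y_top))
        going_up = i % 2 == 0
        if i < n - 1:
            y_riser = yR if going_up else yL
            pts.append([x_c, y_riser])
            pts.append([x_c + pitch, y_riser])
            rects.append(
                Rect(x_c + w / 2, x_c + pitch - w / 2,
                     y_riser - w / 2, y_riser + w / 2)
            )
        else:
            pts.append([x_c, y_top if going_up else 0.0])

    centerline = np.array(pts)
    outlet_x = x0_leg + (n - 1) * pitch
    if (n - 1) % 2 == 0:
        out_pos, out_sign = y_top, +1
    else:
        out_pos, out_sign = 0.0, -1

    ports = {
        "inlet_sample": Port("inlet_sample", "inlet", "x", 0.0, (0.0, w / 2), -1),
        "inlet_buffer": Port("inlet_buffer", "inlet", "x", 0.0, (w / 2, w), -1),
        "outlet": Port(
            "outlet", "outlet", "y", out_pos,
            (outlet_x - w / 2, outlet_x + w / 2), out_sign,
        ),
    }

    geo_tmp = ChannelGeometry(
        kind="mixer", fluid_rects=rects, obstacle_rects=[], height=H,
        ports=ports, centerline=centerline, y_ref=y_top / 2,
    )
    obstacles: list[Rect] = []
    if spec.obstacles_enabled:
        stations = (
            spec.obstacle_stations
            if spec.obstacle_stations is not None
            else _default_obstacle_stations(geo_tmp, n, pitch)
        )
        e = spec.obstacle_edge
        for s, side in stations:
            point, t = geo_tmp.station(s)
            normal = np.array([-t[1], t[0]])
            if abs(normal[1]) > 0.5:  # leg along x: lateral axis is y
                lo, hi = geo_tmp.lateral_gap(point[0], point[1])
                yb = (hi - e, hi) if side * normal[1] > 0 else (lo, lo + e)
                ob = Rect(point[0] - e / 2, point[0] + e / 2, yb[0], yb[1])
            else:  # riser along y: lateral axis is x
                lo, hi = geo_tmp._axial_gap(point[1], point[0])
                xb = (hi - e, hi) if side * normal[0] > 0 else (lo, lo + e)
                ob = Rect(xb[0], xb[1], point[1] - e / 2, point[1] + e / 2)
            corners = np.array(
                [[ob.x0, ob.y0], [ob.x1, ob.y0], [ob.x0, ob.y1], [ob.x1, ob.y1]]
            )
            if not geo_tmp.contains(corners).all():
                raise GeometryError(
                    f"obstacle at station s={s:.3e} overlaps the channel wall"
                )
            obstacles.append(ob)

    return ChannelGeometry(
        kind="mixer",
        fluid_rects=rects,
        obstacle_rects=obstacles,
        height=H,
        ports=ports,
        centerline=centerline,
        y_ref=y_top / 2,
        spec=spec,
        placement=Placement(spec.radial_offset),
    )


def _default_obstacle_stations(
    geo: ChannelGeometry, n_legs: int, pitch: float
) -> tuple[tuple[float, int], ...]:
    """Three obstacles per serpentine leg at 25/50/75% of the leg arc,
    attached to alternating walls, clear of the corners and of the outlet
    face (so no obstacle wake straddles the outlet cross-section)."""
    arc = geo.arclength
    stations: list[tuple[float, int]] = []
    side = 1
    for leg in range(n_legs):
        k = 2 * leg + 1  # segment 0 is the merge channel; legs are odd
        s0, s1 = arc[k], arc[k + 1]
        for frac in (0.25, 0.5, 0.75):
            stations.append((s0 + frac * (s1 - s0), side))
            side = -side
    return tuple(stations)


def build_straight_channel(
    section: ChannelSection, radial_offset: float = 0.03
) -> ChannelGeometry:
    """A single straight duct with one inlet and one outlet (oracle geometry)."""
    r = Rect(0.0, section.length, 0.0, section.width)
    ports = {
        "inlet": Port("inlet", "inlet", "x", 0.0, (0.0, section.width), -1),
        "outlet": Port(
            "outlet", "outlet", "x", section.length, (0.0, section.width), +1
        ),
    }
    centerline = np.array(
        [[0.0, section.width / 2], [section.length, section.width / 2]]
    )
    return ChannelGeometry(
        kind="duct",
        fluid_rects=[r],
        obstacle_rects=[],
        height=section.height,
        ports=ports,
        centerline=centerline,
        y_ref=section.width / 2,
        spec=section,
        placement=Placement(radial_offset),
    )


def place_on_disk(
    geometry: ChannelGeometry, radial_offset: float, azimuth: float = 0.0
) -> ChannelGeometry:
    """Return a copy of ``geometry`` placed with its inlet centerline at
    ``radial_offset`` from the disk center, rotated by ``azimuth``."""
    if radial_offset <= 0:
        raise GeometryError("radial offset must be positive")
    return replace(geometry, placement=Placement(radial_offset, azimuth))


# -- meshing --------------------------------------------------------------


@dataclass
class Mesh:
    """Uniform structured grid over the geometry bounding box with a fluid
    mask, presented with generic node/cell connectivity and tagged boundary
    facets (wall / obstacle / port labels).

    Cell (i, j) covers [x0 + i dx, x0 + (i+1) dx] x [y0 + j dx, ...]; the
    mask is indexed ``fluid[j, i]``.  Facets are (i, j, side, tag) with side
    in {W, E, S, N}.
    """

    geometry: ChannelGeometry
    dx: float
    origin: tuple[float, float]
    nx: int
    ny: int
    fluid: np.ndarray
    facets: list[tuple[int, int, str, str]]

    @property
    def n_cells(self) -> int:
        return int(self.fluid.sum())

    @property
    def cell_centers(self) -> np.ndarray:
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.dx
        ys = y0 + (np.arange(self.ny) + 0.5) * self.dx
        X, Y = np.meshgrid(xs, ys)
        return np.column_stack([X[self.fluid], Y[self.fluid]])

    @property
    def volume(self) -> float:
        return self.n_cells * self.dx**2 * self.geometry.height

    @property
    def points(self) -> np.ndarray:
        """Node coordinates of fluid cells (shared nodes deduplicated)."""
        return self._nodes_cells()[0]

    @property
    def cells(self) -> np.ndarray:
        """Quad connectivity (n_cells, 4) into :attr:`points`."""
        return self._nodes_cells()[1]

    def _nodes_cells(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        jj, ii = np.nonzero(self.fluid)
        node_id: dict[tuple[int, int], int] = {}
        pts: list[tuple[float, float]] = []

        def nid(i: int, j: int) -> int:
            key = (i, j)
            if key not in node_id:
                node_id[key] = len(pts)
                pts.append((x0 + i * self.dx, y0 + j * self.dx))
            return node_id[key]

        quads = np.empty((len(ii), 4), dtype=int)
        for k, (i, j) in enumerate(zip(ii, jj)):
            quads[k] = (nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1))
        return np.asarray(pts), quads

    def facet_tags(self) -> set[str]:
        return {t for *_ij, t in self.facets}


def generate_mesh(geometry: ChannelGeometry, target_edge: float = 5e-6) -> Mesh:
    """Mesh the geometry with a uniform grid of spacing ``target_edge``.

    Geometry coordinates are expected to be (near-)commensurate with the
    grid; port faces snap to the nearest grid line.  Boundary facets are
    tagged 'wall', 'obstacle' or with the adjacent port's label.
    """
    bb = geometry.bounding_box
    min_feature = min(
        min(r.x1 - r.x0, r.y1 - r.y0) for r in geometry.fluid_rects
    )
    if target_edge >= min_feature:
        raise GeometryError(
            f"target_edge {target_edge} must resolve the smallest feature "
            f"({min_feature})"
        )
    dx = target_edge
    nx = max(1, round((bb.x1 - bb.x0) / dx))
    ny = max(1, round((bb.y1 - bb.y0) / dx))
    x0, y0 = bb.x0, bb.y0
    xs = x0 + (np.arange(nx) + 0.5) * dx
    ys = y0 + (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    fluid = geometry.contains(pts).reshape(ny, nx)
    if not fluid.any():
        raise GeometryError("meshing produced no fluid cells; check geometry")

    in_obstacle = np.zeros((ny, nx), dtype=bool)
    for ob in geometry.obstacle_rects:
        in_obstacle |= ob.contains(X, Y)

    def port_at(xf: float, yc: float, axis: str) -> str | None:
        for p in geometry.ports.values():
            if p.axis != axis:
                continue
            if abs(p.position - xf) < 0.51 * dx and p.span[0] - 1e-12 <= yc <= p.span[1] + 1e-12:
                return p.label
        return None

    facets: list[tuple[int, int, str, str]] = []
    sides = {
        "W": (-1, 0), "E": (1, 0), "S": (0, -1), "N": (0, 1),
    }
    jj, ii = np.nonzero(fluid)
    for i, j in zip(ii, jj):
        for side, (di, dj) in sides.items():
            i2, j2 = i + di, j + dj
            outside = not (0 <= i2 < nx and 0 <= j2 < ny) or not fluid[j2, i2]
            if not outside:
                continue
            if side in ("W", "E"):
                xf = x0 + (i + (side == "E")) * dx
                yc = y0 + (j + 0.5) * dx
                label = port_at(xf, yc, "x")
            else:
                yf = y0 + (j + (side == "N")) * dx
                xc = x0 + (i + 0.5) * dx
                label = port_at(yf, xc, "y")
            if label is None:
                solid_is_obstacle = (
                    0 <= i2 < nx and 0 <= j2 < ny and in_obstacle[j2, i2]
                )
                label = "obstacle" if solid_is_obstacle else "wall"
            facets.append((i, j, side, label))

    return Mesh(
        geometry=geometry, dx=dx, origin=(x0, y0), nx=nx, ny=ny,
        fluid=fluid, facets=facets,
    )
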