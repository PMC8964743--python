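"""Wide-Bezier parametric foot geometry: design variables -> geometry -> frame mesh.

A single-part energy-storage-and-return foot is described by three wide
Bezier curves over six control circles C1..C6: a cubic keel C1->C4, a linear
forefoot C4->C5 and a linear heel C4->C6.  A wide Bezier curve uses control
*circles*: the circle centers are the Bezier control points of the
centerline and the circle radii are Bernstein-interpolated along the curve
to give the local half-thickness.  The boundary is the centerline offset by
the half-thickness along the local normal.

Of the 18 scalars (x, y, diameter for six circles), 11 are free design
variables; the rest are fixed by the user's body (foot length, prosthesis
build height) or anchored conventions:

* C1 (the ankle / shank attachment) sits at the local origin,
* C5 (toe) and C6 (heel) abscissae are set by the foot length with the
  ankle at a configurable fraction (default 25%) of foot length from the
  heel, and
* C4, C5, C6 rest on the ground line ``y = -h_ank``
  (center height ``-h_ank + d/2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json
import re

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .gait import UserCharacteristics

__all__ = [
    "ControlCircle",
    "FootDesign",
    "FootGeometry",
    "SegmentGeometry",
    "FrameMesh",
    "DesignBounds",
    "IntersectionReport",
    "INDEPENDENT_VAR_NAMES",
    "complete_design",
    "evaluate_geometry",
    "check_self_intersection",
    "mesh_geometry",
    "export_outline",
    "read_outline",
    "default_bounds",
]


class GeometryError(ValueError):
    """The requested design does not define a valid physical geometry."""


@dataclass(frozen=True)
class ControlCircle:
    x: float  # m
    y: float  # m
    diameter: float  # m, > 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.diameter) and self.diameter > 0):
            raise GeometryError("control circle diameter must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


#: the 11 free design variables, in canonical order
INDEPENDENT_VAR_NAMES = (
    "C1.d", "C2.x", "C2.y", "C2.d", "C3.x", "C3.y", "C3.d",
    "C4.x", "C4.d", "C5.d", "C6.d",
)


@dataclass(frozen=True)
class FootDesign:
    """Six control circles plus the user-derived build height and foot length."""

    circles: tuple[ControlCircle, ...]  # C1..C6
    h_ank: float  # m, ankle origin height above ground
    L_foot: float  # m
    ankle_fraction: float = 0.25  # ankle station from heel / L_foot

    def __post_init__(self) -> None:
        if len(self.circles) != 6:
            raise GeometryError("a foot design has exactly six control circles")
        c1 = self.circles[0]
        if abs(c1.x) > 1e-12 or abs(c1.y) > 1e-12:
            raise GeometryError("C1 center must be the local origin")

    @property
    def independent_vars(self) -> np.ndarray:
        """The 11 free values in :data:`INDEPENDENT_VAR_NAMES` order."""
        c = self.circles
        return np.array([
            c[0].diameter, c[1].x, c[1].y, c[1].diameter,
            c[2].x, c[2].y, c[2].diameter,
            c[3].x, c[3].diameter, c[4].diameter, c[5].diameter,
        ])

    @property
    def toe_x(self) -> float:
        return (1.0 - self.ankle_fraction) * self.L_foot

    @property
    def heel_x(self) -> float:
        return -self.ankle_fraction * self.L_foot

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "units": "m",
            "h_ank_m": self.h_ank,
            "L_foot_m": self.L_foot,
            "ankle_fraction": self.ankle_fraction,
            "circles": [
                {"x_m": c.x, "y_m": c.y, "diameter_m": c.diameter}
                for c in self.circles
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "FootDesign":
        data = json.loads(Path(path).read_text())
        circles = tuple(
            ControlCircle(c["x_m"], c["y_m"], c["diameter_m"]) for c in data["circles"]
        )
        return cls(circles=circles, h_ank=data["h_ank_m"], L_foot=data["L_foot_m"],
                   ankle_fraction=data.get("ankle_fraction", 0.25))


def complete_design(independent_vars, user: UserCharacteristics,
                    ankle_fraction: float = 0.25) -> FootDesign:
    """Fill the 7 dependent scalars from the 11 free values and the user's body.

    Dependent values: C1 center at the origin; C5.x/C6.x at the toe and heel
    extremities fixed by the foot length; C4.y/C5.y/C6.y resting on the
    ground line ``y = -h_ank``.
    """
    v = np.asarray(independent_vars, dtype=float)
    if v.shape != (11,) or not np.all(np.isfinite(v)):
        raise GeometryError("expected 11 finite independent variables")
    (c1d, c2x, c2y, c2d, c3x, c3y, c3d, c4x, c4d, c5d, c6d) = v
    if min(c1d, c2d, c3d, c4d, c5d, c6d) <= 0:
        raise GeometryError("all control circle diameters must be positive")
    h = user.build_height_h_ank
    L = user.foot_length
    circles = (
        ControlCircle(0.0, 0.0, c1d),
        ControlCircle(c2x, c2y, c2d),
        ControlCircle(c3x, c3y, c3d),
        ControlCircle(c4x, -h + c4d / 2.0, c4d),
        ControlCircle((1.0 - ankle_fraction) * L, -h + c5d / 2.0, c5d),
        ControlCircle(-ankle_fraction * L, -h + c6d / 2.0, c6d),
    )
    return FootDesign(circles=circles, h_ank=h, L_foot=L, ankle_fraction=ankle_fraction)


@dataclass(frozen=True)
class DesignBounds:
    """Elementwise bounds on the 11 independent design variables."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (11,) or hi.shape != (11,):
            raise GeometryError("bounds must cover the 11 independent variables")
        if not np.all(lo < hi):
            raise GeometryError("lower bounds must be strictly below upper bounds")

    def contains(self, vars11) -> bool:
        v = np.asarray(vars11, dtype=float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    def violation(self, vars11) -> float:
        """Total out-of-bounds distance (0 when inside)."""
        v = np.asarray(vars11, dtype=float)
        return float(np.sum(np.clip(self.lower - v, 0, None))
                     + np.sum(np.clip(v - self.upper, 0, None)))


def default_bounds(user: UserCharacteristics) -> DesignBounds:
    """Bounds keeping the structure within roughly a biological-foot envelope.

    The envelope is a box of ``L_foot`` by ``h_ank + 2 cm``; thicknesses are
    bounded to stay manufacturable and meshable.
    """
    h = user.build_height_h_ank
    L = user.foot_length
    d_lo, d_hi = 0.006, min(0.045, h)
    lower = np.array([
        d_lo,               # C1.d
        -0.15 * L, -h,      # C2.x, C2.y
        d_lo,               # C2.d
        0.05 * L, -h,       # C3.x, C3.y
        d_lo,               # C3.d
        0.15 * L,           # C4.x
        d_lo, d_lo, d_lo,   # C4.d, C5.d, C6.d
    ])
    upper = np.array([
        d_hi,
        0.35 * L, 0.02,
        d_hi,
        0.60 * L, 0.02,
        d_hi,
        0.60 * L,
        d_hi, d_hi, d_hi,
    ])
    return DesignBounds(lower, upper)


# ---------------------------------------------------------------------------
# geometry evaluation


@dataclass(frozen=True)
class SegmentGeometry:
    """One sampled wide-Bezier segment: centerline, unit tangents, half-thickness."""

    name: str
    points: np.ndarray  # (n, 2) m
    tangents: np.ndarray  # (n, 2) unit
    half_thickness: np.ndarray  # (n,) m, > 0
    arc_s: np.ndarray  # (n,) cumulative arc length, m

    @property
    def length(self) -> float:
        return float(self.arc_s[-1])

    def normals(self) -> np.ndarray:
        """Unit left normals (tangent rotated +90 deg)."""
        t = self.tangents
        return np.column_stack([-t[:, 1], t[:, 0]])

    def offset(self, side: float) -> np.ndarray:
        """Boundary polyline at ``centerline + side * half_thickness * normal``."""
        return self.points + side * self.half_thickness[:, None] * self.normals()


@dataclass(frozen=True)
class FootGeometry:
    """The three sampled segments (keel, forefoot, heel), joined at C4."""

    keel: SegmentGeometry
    forefoot: SegmentGeometry
    heel: SegmentGeometry
    design: FootDesign

    @property
    def segments(self) -> tuple[SegmentGeometry, ...]:
        return (self.keel, self.forefoot, self.heel)


def _bezier(control: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a Bezier curve of arbitrary degree at parameters t (de Casteljau)."""
    pts = np.repeat(control[None, :, :], t.size, axis=0)  # (T, n, 2)
    tt = t[:, None, None]
    while pts.shape[1] > 1:
        pts = (1 - tt) * pts[:, :-1, :] + tt * pts[:, 1:, :]
    return pts[:, 0, :]


def _bezier_deriv(control: np.ndarray, t: np.ndarray) -> np.ndarray:
    n = control.shape[0] - 1
    dcontrol = n * np.diff(control, axis=0)
    return _bezier(dcontrol, t)


def _bernstein_scalar(values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Bernstein interpolation of scalars (radii) along the curve parameter."""
    return _bezier(np.column_stack([values, np.zeros_like(values)]), t)[:, 0]


def _sample_segment(name: str, centers: np.ndarray, radii: np.ndarray,
                    n: int) -> SegmentGeometry:
    if n < 2:
        raise GeometryError("need at least 2 samples per segment")
    for a, b in zip(centers[:-1], centers[1:]):
        if np.hypot(*(b - a)) < 1e-9:
            raise GeometryError(f"degenerate segment {name!r}: coincident adjacent centers")
    t = np.linspace(0.0, 1.0, n)
    pts = _bezier(centers, t)
    d = _bezier_deriv(centers, t)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise GeometryError(f"degenerate segment {name!r}: vanishing tangent")
    tangents = d / norms[:, None]
    half = _bernstein_scalar(radii, t)
    if np.any(half <= 0):
        raise GeometryError(f"segment {name!r} has non-positive thickness")
    seglen = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    return SegmentGeometry(name=name, points=pts, tangents=tangents,
                           half_thickness=half, arc_s=arc)


def evaluate_geometry(design: FootDesign, samples_per_segment: int = 80) -> FootGeometry:
    """Sample the three wide-Bezier segments of ``design``.

    The keel is a cubic Bezier over the C1..C4 centers with cubic-Bernstein
    interpolated radii; forefoot (C4->C5) and heel (C4->C6) are linear.
    """
    c = design.circles
    keel = _sample_segment(
        "keel",
        np.array([ci.center for ci in c[:4]]),
        np.array([ci.radius for ci in c[:4]]),
        samples_per_segment,
    )
    forefoot = _sample_segment(
        "forefoot",
        np.array([c[3].center, c[4].center]),
        np.array([c[3].radius, c[4].radius]),
        samples_per_segment,
    )
    heel = _sample_segment(
        "heel",
        np.array([c[3].center, c[5].center]),
        np.array([c[3].radius, c[5].radius]),
        samples_per_segment,
    )
    return FootGeometry(keel=keel, forefoot=forefoot, heel=heel, design=design)


# ---------------------------------------------------------------------------
# self-intersection


@dataclass(frozen=True)
class IntersectionReport:
    intersects: bool
    pair: tuple[str, str] | None = None

    def __bool__(self) -> bool:
        return self.intersects


def _segment_polygon(seg: SegmentGeometry) -> Polygon:
    left = seg.offset(+1.0)
    right = seg.offset(-1.0)
    return Polygon(np.vstack([left, right[::-1]]))


def check_self_intersection(geom: FootGeometry) -> IntersectionReport:
    """Detect non-physical designs whose thick segments fold onto themselves
    or cross each other away from the shared C4 junction.

    Checks the offset boundary polylines (centerline +/- half-thickness
    along the normal).  A violation is (a) a segment whose own left/right
    offsets cross or whose offset polyline self-crosses (over-thick tight
    bend), or (b) boundaries of two different segments crossing outside the
    junction neighborhood where all three segments legitimately merge into
    the C4 node (shallow-angle merges there are a single solid part).
    """
    offsets: dict[str, tuple[LineString, LineString]] = {}
    lengths: dict[str, float] = {}
    for seg in geom.segments:
        left = LineString(seg.offset(+1.0))
        right = LineString(seg.offset(-1.0))
        if not left.is_simple or not right.is_simple:
            return IntersectionReport(True, (seg.name, seg.name))
        if left.intersects(right):
            return IntersectionReport(True, (seg.name, seg.name))
        offsets[seg.name] = (left, right)
        lengths[seg.name] = seg.length
    c4 = Point(*geom.design.circles[3].center)
    r4 = geom.design.circles[3].radius
    names = list(offsets)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            benign = max(4.0 * r4, 0.2 * min(lengths[names[i]], lengths[names[j]]))
            for a in offsets[names[i]]:
                for b in offsets[names[j]]:
                    inter = a.intersection(b)
                    if inter.is_empty:
                        continue
                    pts = getattr(inter, "geoms", [inter])
                    for p in pts:
                        (x, y) = (p.x, p.y) if p.geom_type == "Point" \
                            else p.representative_point().coords[0]
                        if c4.distance(Point(x, y)) > benign:
                            return IntersectionReport(True, (names[i], names[j]))
    return IntersectionReport(False, None)


# ---------------------------------------------------------------------------
# meshing


@dataclass(frozen=True)
class SoleMap:
    """Ground-contact description: sole nodes ordered heel tip -> toe tip."""

    node_ids: np.ndarray  # (m,) indices into mesh nodes
    bottom: np.ndarray  # (m, 2) undeformed bottom-fiber points
    tangent_angle: np.ndarray  # (m,) undeformed sole tangent angle, rad (heel->toe)
    offset_vec: np.ndarray  # (m, 2) centerline-node -> bottom-fiber vector
    heel_tip_index: int  # position (in sole order) of the heel extremity
    toe_tip_index: int

    def station_node(self, x_foot: float) -> int:
        """Mesh node whose undeformed bottom point is nearest ``x_foot``."""
        k = int(np.argmin(np.abs(self.bottom[:, 0] - x_foot)))
        return int(self.node_ids[k])

    def sole_index_of(self, node_id: int) -> int:
        where = np.nonzero(self.node_ids == node_id)[0]
        if where.size == 0:
            raise GeometryError(f"node {node_id} is not on the sole")
        return int(where[0])


@dataclass(frozen=True)
class FrameMesh:
    """Discretized foot: nodes, 2-node frame elements and section properties."""

    nodes: np.ndarray  # (N, 2) m
    elements: np.ndarray  # (E, 2) node indices
    thickness: np.ndarray  # (E,) m, in-plane depth
    width: float  # m, out-of-plane extrusion
    area: np.ndarray  # (E,) m^2
    inertia: np.ndarray  # (E,) m^4
    attachment_node: int
    sole: SoleMap
    node_segment: np.ndarray  # (N,) 0 keel, 1 forefoot, 2 heel (C4 node -> 0)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_lengths(self) -> np.ndarray:
        d = self.nodes[self.elements[:, 1]] - self.nodes[self.elements[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])


def _resample_by_arc(seg: SegmentGeometry, n_nodes: int):
    """Equal-arc-length node positions plus interpolated properties."""
    s = np.linspace(0.0, seg.length, n_nodes)
    x = np.interp(s, seg.arc_s, seg.points[:, 0])
    y = np.interp(s, seg.arc_s, seg.points[:, 1])
    tx = np.interp(s, seg.arc_s, seg.tangents[:, 0])
    ty = np.interp(s, seg.arc_s, seg.tangents[:, 1])
    tt = np.column_stack([tx, ty])
    tt /= np.linalg.norm(tt, axis=1)[:, None]
    half = np.interp(s, seg.arc_s, seg.half_thickness)
    return np.column_stack([x, y]), tt, half


def mesh_geometry(geom: FootGeometry, n_elements: int = 300,
                  width: float = 0.060) -> FrameMesh:
    """Mesh the foot geometry into plane-frame elements.

    Elements are allocated to the three segments proportionally to arc
    length (at least one each); per-element thickness is twice the mean
    half-thickness over its span; ``area = width * t`` and
    ``I = width * t^3 / 12``.  The shank attachment node is at C1 (keel
    start); the C4 junction node is shared by all three segments.
    """
    if n_elements < 3:
        raise GeometryError("need at least 3 elements (one per segment)")
    if width <= 0:
        raise GeometryError("width must be positive")
    segs = geom.segments
    lengths = np.array([s.length for s in segs])
    counts = np.maximum(1, np.round(n_elements * lengths / lengths.sum()).astype(int))
    while counts.sum() > n_elements:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_elements:
        counts[np.argmin(counts)] += 1

    nodes: list[np.ndarray] = []
    node_seg: list[int] = []
    elements: list[tuple[int, int]] = []
    thick: list[float] = []
    seg_nodes: dict[str, np.ndarray] = {}
    seg_half: dict[str, np.ndarray] = {}
    seg_tan: dict[str, np.ndarray] = {}

    def add_chain(pts, half, first_id=None, seg_id=0):
        ids = np.empty(pts.shape[0], dtype=int)
        start = 0
        if first_id is not None:
            ids[0] = first_id
            start = 1
        for k in range(start, pts.shape[0]):
            ids[k] = len(nodes)
            nodes.append(pts[k])
            node_seg.append(seg_id)
        for k in range(pts.shape[0] - 1):
            elements.append((int(ids[k]), int(ids[k + 1])))
            thick.append(float(half[k] + half[k + 1]))  # 2 * mean half-thickness
        return ids

    # keel: node 0 = C1 (attachment), last = C4 junction
    kp, kt, kh = _resample_by_arc(segs[0], counts[0] + 1)
    keel_ids = add_chain(kp, kh, first_id=None, seg_id=0)
    junction = int(keel_ids[-1])
    seg_nodes["keel"], seg_half["keel"], seg_tan["keel"] = keel_ids, kh, kt

    fp, ft, fh = _resample_by_arc(segs[1], counts[1] + 1)
    fore_ids = add_chain(fp, fh, first_id=junction, seg_id=1)
    seg_nodes["forefoot"], seg_half["forefoot"], seg_tan["forefoot"] = fore_ids, fh, ft

    hp, ht, hh = _resample_by_arc(segs[2], counts[2] + 1)
    heel_ids = add_chain(hp, hh, first_id=junction, seg_id=2)
    seg_nodes["heel"], seg_half["heel"], seg_tan["heel"] = heel_ids, hh, ht

    nodes_arr = np.array(nodes)
    elements_arr = np.array(elements, dtype=int)
    t_arr = np.array(thick)
    area = width * t_arr
    inertia = width * t_arr**3 / 12.0

    # sole: heel chain reversed (tip -> C4) then forefoot chain (C4 -> toe)
    def bottom_of(ids, pts, half, tan):
        normals = np.column_stack([-tan[:, 1], tan[:, 0]])
        # downward-pointing offset: flip normals with positive y component
        flip = np.where(normals[:, 1] > 0, -1.0, 1.0)
        off = normals * flip[:, None] * half[:, None]
        return pts + off, off

    hb, hoff = bottom_of(heel_ids, hp, hh, ht)
    fb, foff = bottom_of(fore_ids, fp, fh, ft)
    sole_ids = np.concatenate([heel_ids[::-1], fore_ids[1:]])
    sole_bottom = np.vstack([hb[::-1], fb[1:]])
    sole_off = np.vstack([hoff[::-1], foff[1:]])
    d = np.gradient(sole_bottom, axis=0)
    tangent_angle = np.arctan2(d[:, 1], d[:, 0])
    sole = SoleMap(node_ids=sole_ids, bottom=sole_bottom,
                   tangent_angle=tangent_angle, offset_vec=sole_off,
                   heel_tip_index=0, toe_tip_index=len(sole_ids) - 1)

    mesh = FrameMesh(nodes=nodes_arr, elements=elements_arr, thickness=t_arr,
                     width=width, area=area, inertia=inertia,
                     attachment_node=0, sole=sole,
                     node_segment=np.array(node_seg, dtype=int))
    total = mesh.element_lengths().sum()
    if abs(total - lengths.sum()) > 1e-3 * lengths.sum():
        raise GeometryError("meshed arc length deviates from geometry by > 0.1%")
    return mesh


# ---------------------------------------------------------------------------
# outline export


def outline_polygon(geom: FootGeometry) -> np.ndarray:
    """Closed outer boundary of the foot (union of the three thick segments)."""
    from shapely.ops import unary_union

    union = unary_union([_segment_polygon(s) for s in geom.segments])
    if union.geom_type != "Polygon":
        raise GeometryError("foot boundary is not a single closed region")
    xy = np.asarray(union.exterior.coords)
    return xy


def export_outline(geom: FootGeometry, fmt: str, path) -> Path:
    """Write the closed outer boundary as an SVG path or DXF polyline, in mm.

    Refuses self-intersecting geometry (it would not be manufacturable).
    """
    report = check_self_intersection(geom)
    if report.intersects:
        raise GeometryError(f"self-intersecting geometry: {report.pair}")
    xy_mm = outline_polygon(geom) * 1000.0
    path = Path(path)
    if fmt == "svg":
        pts = " L ".join(f"{x:.6f} {-y:.6f}" for x, y in xy_mm)  # SVG y is down
        xs, ys = xy_mm[:, 0], -xy_mm[:, 1]
        pad = 5.0
        vb = (xs.min() - pad, ys.min() - pad,
              xs.max() - xs.min() + 2 * pad, ys.max() - ys.min() + 2 * pad)
        svg = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'viewBox="{vb[0]:.3f} {vb[1]:.3f} {vb[2]:.3f} {vb[3]:.3f}" '
            f'width="{vb[2]:.3f}mm" height="{vb[3]:.3f}mm">\n'
            f'<path d="M {pts} Z" fill="none" stroke="black" stroke-width="0.2"/>\n'
            "</svg>\n"
        )
        path.write_text(svg)
    elif fmt == "dxf":
        lines = ["0", "SECTION", "2", "ENTITIES", "0", "LWPOLYLINE",
                 "8", "0", "90", str(len(xy_mm)), "70", "1"]
        for x, y in xy_mm:
            lines += ["10", f"{x:.6f}", "20", f"{y:.6f}"]
        lines += ["0", "ENDSEC", "0", "EOF", ""]
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown outline format {fmt!r} (use 'svg' or 'dxf')")
    return path


def read_outline(path) -> np.ndarray:
    """Re-import an exported outline (mm) as an (n, 2) vertex array."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".svg" or text.lstrip().startswith("<?xml"):
        m = re.search(r'd="M ([^"]+?) Z"', text)
        if not m:
            raise ValueError("no path found in SVG")
        nums = np.array(m.group(1).replace("L", " ").split(), dtype=float)
        xy = nums.reshape(-1, 2)
        xy[:, 1] *= -1.0
        return xy
    tokens = text.split("\n")
    xs, ys = [], []
    it = iter(range(len(tokens)))
    for i in it:
        if tokens[i].strip() == "10":
            xs.append(float(tokens[i + 1]))
        elif tokens[i].strip() == "20":
            ys.append(float(tokens[i + 1]))
    if not xs:
        raise ValueError("no polyline vertices found in DXF")
    return np.column_stack([xs, ys])
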