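"""Parametric umbilical-cord geometry.

The cord is modelled as one straight umbilical vein (UV) on the cord axis and
two umbilical arteries (UAs) wound helically around it, a quarter-turn apart
in phase by default (pi radians, i.e. diametrically opposite). The helix
radius is fixed by construction: the arterial centreline sits at

    R_h = r_UV + r_UA + clearance

so that the two tube surfaces keep the prescribed clearance everywhere. The
module provides analytic metrics (arc lengths, lateral wall areas, the
umbilical coiling index) and triangulated tube surfaces swept along the
centrelines with a rotation-minimizing frame, exportable as STL or legacy-VTK
polydata for external 3D CFD.

Coordinate convention: the cord axis is x, with x = 0 at the fetal end and
x = cord_length at the placental end. "Counterclockwise" winding is as seen
from the fetal end looking toward the placenta; the choice only flips the sign
of the helix angle and has no effect on any scalar output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.spatial.distance import cdist

from .units import parse_length

__all__ = [
    "CordSpec",
    "VesselCenterline",
    "CordGeometry",
    "TubeSurfaceMesh",
    "GeometryError",
    "MeshingError",
    "build_cord_geometry",
    "build_straight_centerline",
    "arc_length",
    "helix_arc_length",
    "lateral_tube_area",
    "wall_area",
    "compute_uci",
    "check_clearance",
    "sweep_tube_mesh",
    "export_mesh",
    "read_mesh",
    "export_centerline_csv",
]


class GeometryError(ValueError):
    """Raised when a geometric configuration is physically inconsistent."""


class MeshingError(RuntimeError):
    """Raised when a swept tube surface would self-intersect or is degenerate."""


class CordSpec(BaseModel):
    """Parametric description of the cord.

    Defaults are a term (38-40 week) cord: 60 cm long, UV diameter 8.3 mm, UA
    diameter 4.2 mm, one arterial coil per 5 cm (12 coils, coiling index
    0.2 coils/cm), and a 0.2 mm surface gap between vein and arteries standing
    in for the Wharton's-jelly separation.
    """

    cord_length: float = 0.6
    uv_diameter: float = 0.0083
    ua_diameter: float = 0.0042
    coil_pitch: float = 0.05
    clearance: float = 0.0002
    n_arteries: int = 2
    phase_offset: float = math.pi
    handedness: Literal["clockwise", "counterclockwise"] = "counterclockwise"

    @model_validator(mode="before")
    @classmethod
    def _coerce_units(cls, data):
        if isinstance(data, dict):
            for key in ("cord_length", "uv_diameter", "ua_diameter",
                        "coil_pitch", "clearance"):
                if key in data and data[key] is not None:
                    data[key] = parse_length(data[key])
        return data

    @model_validator(mode="after")
    def _validate(self):
        for name in ("cord_length", "uv_diameter", "ua_diameter", "coil_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clearance < 0:
            raise ValueError("clearance must be non-negative")
        if self.coil_pitch > self.cord_length:
            raise ValueError("coil_pitch must not exceed cord_length")
        if self.n_arteries not in (1, 2):
            raise ValueError("n_arteries must be 1 or 2")
        return self

    @property
    def helix_radius(self) -> float:
        """Arterial centreline radius r_UV + r_UA + clearance (m)."""
        return self.uv_diameter / 2 + self.ua_diameter / 2 + self.clearance

    @property
    def n_coils(self) -> float:
        return self.cord_length / self.coil_pitch


@dataclass
class VesselCenterline:
    """Discretized centreline of one vessel.

    ``points`` is ordered with the first point at axial coordinate x = 0 (the
    fetal end of the cord axis); ``arclength_per_point`` is the cumulative
    polyline length, zero at the first point.
    """

    vessel_id: str
    points: np.ndarray
    arclength_per_point: np.ndarray
    tube_radius: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        self.arclength_per_point = np.asarray(self.arclength_per_point, float)
        if np.any(np.diff(self.arclength_per_point) <= 0):
            raise ValueError("arclength must be strictly increasing")


@dataclass
class CordGeometry:
    """Realized cord geometry with analytic metrics attached."""

    spec: CordSpec
    centerlines: dict[str, VesselCenterline]
    helix_radius: float
    arc_lengths: dict[str, float]
    wall_areas: dict[str, float] = field(default_factory=dict)
    uci: float = 0.0
    n_coils: float = 0.0

    def centerline(self, vessel_id: str) -> VesselCenterline:
        try:
            return self.centerlines[vessel_id]
        except KeyError:
            raise KeyError(
                f"unknown vessel {vessel_id!r}; have {sorted(self.centerlines)}"
            ) from None

    def diameter(self, vessel_id: str) -> float:
        return 2.0 * self.centerline(vessel_id).tube_radius


@dataclass
class TubeSurfaceMesh:
    """Triangulated tube surface for one vessel."""

    vertices: np.ndarray
    triangles: np.ndarray
    vessel_id: str
    closed: bool

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def surface_area(self) -> float:
        v = self.vertices
        t = self.triangles
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * float(np.linalg.norm(np.cross(a, b), axis=1).sum())

    def is_watertight(self) -> bool:
        """True when every undirected edge is shared by exactly two triangles."""
        t = self.triangles
        edges = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def build_straight_centerline(
    vessel_id: str, length: float, tube_radius: float, n_points: int = 121
) -> VesselCenterline:
    """Straight centreline along the cord axis from x = 0 to x = length."""
    x = np.linspace(0.0, length, n_points)
    pts = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    return VesselCenterline(vessel_id, pts, x.copy(), tube_radius)


def _helix_points(
    spec: CordSpec, phase: float, points_per_coil: int, radius: float
) -> np.ndarray:
    n_turns = spec.n_coils
    n_pts = max(2, int(round(points_per_coil * n_turns)) + 1)
    theta = np.linspace(0.0, 2.0 * math.pi * n_turns, n_pts)
    sign = 1.0 if spec.handedness == "counterclockwise" else -1.0
    r = radius
    x = theta * spec.coil_pitch / (2.0 * math.pi)
    y = r * np.cos(sign * theta + phase)
    z = r * np.sin(sign * theta + phase)
    return np.column_stack([x, y, z])


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def build_cord_geometry(
    spec: CordSpec,
    points_per_coil: int = 64,
    helix_radius: float | None = None,
) -> CordGeometry:
    """Build the UV + UA centrelines and attach analytic metrics.

    Parameters
    ----------
    spec:
        Validated cord parameters.
    points_per_coil:
        Centreline sampling density per full arterial turn (>= 8). The default
        64 keeps the polyline arc-length error below 0.1 % of the closed form.
    helix_radius:
        Override for the arterial centreline radius. The default (None) uses
        the clearance construction r_UV + r_UA + clearance; forcing a smaller
        radius yields interpenetrating tubes that ``check_clearance`` rejects.
    """
    if points_per_coil < 8:
        raise ValueError("points_per_coil must be >= 8")
    r_helix = spec.helix_radius if helix_radius is None else float(helix_radius)

    centerlines: dict[str, VesselCenterline] = {}
    n_axial = max(2, int(round(points_per_coil * spec.n_coils)) + 1)
    centerlines["UV"] = build_straight_centerline(
        "UV", spec.cord_length, spec.uv_diameter / 2, n_points=n_axial
    )
    for i in range(spec.n_arteries):
        phase = i * spec.phase_offset
        pts = _helix_points(spec, phase, points_per_coil, r_helix)
        cl = VesselCenterline(
            f"UA{i + 1}", pts, _cumulative_arclength(pts), spec.ua_diameter / 2
        )
        centerlines[cl.vessel_id] = cl

    geom = CordGeometry(
        spec=spec,
        centerlines=centerlines,
        helix_radius=r_helix,
        arc_lengths={vid: arc_length(cl) for vid, cl in centerlines.items()},
        n_coils=spec.n_coils,
    )
    geom.wall_areas = {
        vid: wall_area(geom, vid, convention="straight_length")
        for vid in centerlines
    }
    geom.uci = compute_uci(geom)
    return geom


def arc_length(centerline: VesselCenterline) -> float:
    """Total polyline length of a centreline (m)."""
    if len(centerline.points) < 2:
        raise ValueError("centerline needs at least 2 points")
    return float(centerline.arclength_per_point[-1])


def helix_arc_length(n_coils: float, helix_radius: float, pitch: float) -> float:
    """Closed-form helix length: n_coils * sqrt((2*pi*R_h)^2 + pitch^2)."""
    return n_coils * math.hypot(2.0 * math.pi * helix_radius, pitch)


def lateral_tube_area(diameter: float, length: float) -> float:
    """Lateral (side-wall) area of a circular tube, pi * D * L (m^2)."""
    if diameter <= 0 or length <= 0:
        raise ValueError("diameter and length must be positive")
    return math.pi * diameter * length


def wall_area(
    geometry: CordGeometry,
    vessel_id: str,
    convention: Literal["straight_length", "arc_length"] = "straight_length",
) -> float:
    """Lateral wall area of a vessel, pi * D * L.

    ``straight_length`` (default) uses the cord length for L regardless of
    coiling — the convention the baseline heat-flux denominators are built on
    (0.0156 m^2 for the UV, 0.00791 m^2 per UA). ``arc_length`` uses the true
    helical centreline length instead, ~29 % larger for the baseline artery.
    """
    cl = geometry.centerline(vessel_id)
    if convention == "straight_length":
        length = geometry.spec.cord_length
    elif convention == "arc_length":
        length = geometry.arc_lengths[vessel_id]
    else:
        raise ValueError(f"unknown wall-area convention {convention!r}")
    return lateral_tube_area(2.0 * cl.tube_radius, length)


def compute_uci(geometry: CordGeometry) -> float:
    """Umbilical coiling index in coils/cm.

    Counts full turns from the winding angle of the first arterial centreline
    (unwrapped atan2 of the transverse coordinates) and divides by the cord
    length in centimetres. Falls back to 0 for a cord with no arteries.
    """
    ua = geometry.centerlines.get("UA1")
    if ua is None:
        return 0.0
    theta = np.unwrap(np.arctan2(ua.points[:, 2], ua.points[:, 1]))
    turns = abs(theta[-1] - theta[0]) / (2.0 * math.pi)
    return float(turns / (geometry.spec.cord_length * 100.0))


def check_clearance(geometry: CordGeometry, fine_factor: int = 4) -> dict[str, float]:
    """Minimum surface-to-surface gaps between the cord vessels.

    Returns a dict with keys like ``"UV-UA1"`` and ``"UA1-UA2"`` giving the
    minimum gap (m) between the corresponding tube surfaces, estimated from
    centreline samples. For the vein/artery pair this equals the spec
    clearance by construction. A negative vein/artery gap (interpenetrating
    tubes, e.g. a forced sub-physical helix radius) raises GeometryError.
    """
    spec = geometry.spec
    gaps: dict[str, float] = {}
    r_uv = geometry.centerline("UV").tube_radius
    ua_ids = [vid for vid in geometry.centerlines if vid.startswith("UA")]
    for vid in ua_ids:
        ua = geometry.centerline(vid)
        # UV surface is a cylinder about the x axis: the gap is the radial
        # distance of the arterial centreline minus both tube radii.
        radial = np.hypot(ua.points[:, 1], ua.points[:, 2])
        gap = float(radial.min() - r_uv - ua.tube_radius)
        gaps[f"UV-{vid}"] = gap
        if gap < -1e-12:
            raise GeometryError(
                f"UV and {vid} tube surfaces intersect (gap {gap:.3e} m)"
            )
    if len(ua_ids) == 2:
        a = geometry.centerline(ua_ids[0])
        b = geometry.centerline(ua_ids[1])
        pa, pb = a.points, b.points
        if fine_factor > 1:  # refine by linear interpolation along each polyline
            pa = _refine_polyline(pa, fine_factor)
            pb = _refine_polyline(pb, fine_factor)
        d = cdist(pa, pb).min()
        gaps[f"{ua_ids[0]}-{ua_ids[1]}"] = float(d - a.tube_radius - b.tube_radius)
    return gaps


def _refine_polyline(points: np.ndarray, factor: int) -> np.ndarray:
    t = np.arange(len(points), dtype=float)
    tf = np.linspace(0.0, t[-1], (len(points) - 1) * factor + 1)
    return np.column_stack(
        [np.interp(tf, t, points[:, k]) for k in range(3)]
    )


def _rotation_minimizing_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Double-reflection rotation-minimizing frame along a polyline.

    Returns (normals, binormals), each (N, 3), orthonormal to the local
    tangent at every point, with no spurious twist.
    """
    n = len(points)
    tangents = np.zeros_like(points)
    tangents[1:-1] = points[2:] - points[:-2]
    tangents[0] = points[1] - points[0]
    tangents[-1] = points[-1] - points[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    normals = np.zeros_like(points)
    # seed normal: any unit vector orthogonal to the first tangent
    t0 = tangents[0]
    seed = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(seed, t0)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    r = seed - np.dot(seed, t0) * t0
    normals[0] = r / np.linalg.norm(r)

    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 == 0.0:
            normals[i + 1] = normals[i]
            continue
        r_l = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        t_l = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - t_l
        c2 = np.dot(v2, v2)
        if c2 == 0.0:
            normals[i + 1] = r_l
        else:
            normals[i + 1] = r_l - (2.0 / c2) * np.dot(v2, r_l) * v2
        normals[i + 1] /= np.linalg.norm(normals[i + 1])

    binormals = np.cross(tangents, normals)
    return normals, binormals


def _max_curvature(points: np.ndarray) -> float:
    """Discrete curvature upper estimate via circumscribed circles of triples."""
    p0, p1, p2 = points[:-2], points[1:-1], points[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    cross = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    return float(np.max(kappa)) if len(kappa) else 0.0


def sweep_tube_mesh(
    centerline: VesselCenterline,
    circumferential_segments: int = 64,
    cap_ends: bool = True,
) -> TubeSurfaceMesh:
    """Sweep a triangulated tube of the centreline's radius along it.

    Cross-section circles are placed in a rotation-minimizing frame, so helical
    centrelines produce untwisted tubes. Raises MeshingError when the tube
    radius exceeds the local radius of curvature (the sweep would
    self-intersect on the inner side of the bend).
    """
    if circumferential_segments < 3:
        raise ValueError("circumferential_segments must be >= 3")
    pts = centerline.points
    if len(pts) < 2:
        raise MeshingError("centerline too short to sweep")
    radius = centerline.tube_radius
    kappa = _max_curvature(pts)
    if kappa > 0 and radius >= 1.0 / kappa:
        raise MeshingError(
            f"tube radius {radius:.4g} m exceeds minimum curvature radius "
            f"{1.0 / kappa:.4g} m; swept surface would self-intersect"
        )

    normals, binormals = _rotation_minimizing_frames(pts)
    phi = np.linspace(0.0, 2.0 * math.pi, circumferential_segments, endpoint=False)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    # rings[i, j] = point i + r*(cos*n_i + sin*b_i)
    rings = (
        pts[:, None, :]
        + radius * (cos_p[None, :, None] * normals[:, None, :]
                    + sin_p[None, :, None] * binormals[:, None, :])
    )
    n_rings, n_seg = rings.shape[0], circumferential_segments
    vertices = rings.reshape(-1, 3)

    tri = []
    for i in range(n_rings - 1):
        base0 = i * n_seg
        base1 = (i + 1) * n_seg
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            tri.append([base0 + j, base1 + j, base1 + jn])
            tri.append([base0 + j, base1 + jn, base0 + jn])

    if cap_ends:
        c0 = len(vertices)
        c1 = c0 + 1
        vertices = np.vstack([vertices, pts[0], pts[-1]])
        last = (n_rings - 1) * n_seg
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            tri.append([c0, jn, j])                     # start cap
            tri.append([c1, last + j, last + jn])       # end cap
    triangles = np.asarray(tri, dtype=np.int64)
    return TubeSurfaceMesh(
        vertices=np.asarray(vertices, float),
        triangles=triangles,
        vessel_id=centerline.vessel_id,
        closed=cap_ends,
    )


# ---------------------------------------------------------------------------
# mesh I/O


def export_mesh(mesh: TubeSurfaceMesh, path, fmt: str | None = None) -> None:
    """Write a surface mesh as STL (binary) or legacy-VTK ASCII polydata.

    The format is inferred from the file suffix when ``fmt`` is None.
    """
    import os

    if mesh.n_triangles == 0 or mesh.n_vertices == 0:
        raise ValueError("refusing to export an empty mesh")
    path = os.fspath(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt == "stl":
        import trimesh

        tm = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.triangles, process=False
        )
        tm.export(path)
    elif fmt == "vtk":
        _write_vtk_polydata(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use stl or vtk)")


def _write_vtk_polydata(mesh: TubeSurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cordflow tube surface {mesh.vessel_id}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        n = mesh.n_triangles
        fh.write(f"POLYGONS {n} {4 * n}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh(path, fmt: str | None = None) -> TubeSurfaceMesh:
    """Read back an STL or legacy-VTK polydata file written by export_mesh."""
    import os

    path = os.fspath(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt == "stl":
        import trimesh

        tm = trimesh.load(path, process=False)
        return TubeSurfaceMesh(
            vertices=np.asarray(tm.vertices, float),
            triangles=np.asarray(tm.faces, np.int64),
            vessel_id="",
            closed=bool(tm.is_watertight),
        )
    if fmt == "vtk":
        return _read_vtk_polydata(path)
    raise ValueError(f"unsupported mesh format {fmt!r}")


def _read_vtk_polydata(path: str) -> TubeSurfaceMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    verts: list[list[float]] = []
    tris: list[list[int]] = []
    i = 0
    while i < len(lines):
        tok = lines[i].split()
        if tok[:1] == ["POINTS"]:
            n = int(tok[1])
            for j in range(n):
                verts.append([float(v) for v in lines[i + 1 + j].split()])
            i += n
        elif tok[:1] == ["POLYGONS"]:
            n = int(tok[1])
            for j in range(n):
                row = [int(v) for v in lines[i + 1 + j].split()]
                tris.append(row[1:])
            i += n
        i += 1
    return TubeSurfaceMesh(
        vertices=np.asarray(verts, float),
        triangles=np.asarray(tris, np.int64),
        vessel_id="",
        closed=False,
    )


def export_centerline_csv(centerline: VesselCenterline, path) -> None:
    """Write a centreline as CSV columns x, y, z, arclength (all metres)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "x_m": centerline.points[:, 0],
            "y_m": centerline.points[:, 1],
            "z_m": centerline.points[:, 2],
            "arclength_m": centerline.arclength_per_point,
        }
    )
    df.to_csv(path, index=False)
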