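"""Parametric patellofemoral joint geometry.

The trochlear groove is modelled as a rounded V-profile revolved about the
femoral flexion axis (x = lateral, y = anterior, z = proximal, origin on the
axis); the patellar articular surface is a matching two-facet wedge with a
rounded median ridge, slightly less curved than the groove (1 degree wedge
opening, +2 mm sagittal radius) so that a small approach produces a large,
centre-weighted contact patch.  The patella is transported along the condylar
track by rotating its frame about the flexion axis at a fixed
patellar-to-knee flexion ratio.

Units are mm and degrees throughout.  All study kinematic inputs (ligament
length-flexion profiles) come from measured tables, not from this geometry;
the geometry supplies contact surfaces, force directions and moment arms
only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Patellar track: the patella flexes at a fraction of knee flexion while it
# glides along the condylar arc; 0.7 is a standard in vivo tracking ratio.
TRACK_RATIO = 0.7
# Angular station of the patella centre on the condylar arc at 0 deg knee
# flexion, measured from the +y (anterior) axis toward +z (proximal).
TRACK_OFFSET_DEG = -15.0
REFERENCE_FLEXION = 40.0
STUDY_ANGLES = (0.0, 30.0, 60.0, 90.0, 120.0)

_GROOVE_BLEND = 3.0     # mm half-width of the rounded sulcus / median ridge
_WEDGE_MISMATCH = 1.0   # deg: patellar facets this much shallower than groove
_SAG_MISMATCH = 2.0     # mm: patellar sagittal radius exceeds condylar radius
_CENTER_OFFSET = 8.0    # mm: patella body centroid anterior of its cartilage


class GeometryError(ValueError):
    """Invalid joint parameter or pose request."""


@dataclass(frozen=True)
class JointParams:
    """Parameters of the synthetic PFJ geometry family.

    ``wiberg_ratio`` is the medial fraction of the patellar articular width
    (Wiberg type II ~ 0.4); ``sulcus_angle`` is the trochlear groove opening
    angle in degrees.
    """

    sulcus_angle: float = 138.0
    groove_depth: float = 5.5
    condyle_radius: float = 32.0
    patella_width: float = 42.0
    patella_height: float = 32.0
    wiberg_ratio: float = 0.4
    cartilage_thickness_femur: float = 3.0
    cartilage_thickness_patella: float = 3.0
    mesh_resolution: int = 5000

    def __post_init__(self) -> None:
        positive = (
            "groove_depth", "condyle_radius", "patella_width",
            "patella_height", "cartilage_thickness_femur",
            "cartilage_thickness_patella",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 90.0 < self.sulcus_angle < 180.0:
            raise GeometryError(
                f"sulcus_angle must lie in (90, 180) degrees, got {self.sulcus_angle}")
        if not 0.0 < self.wiberg_ratio < 1.0:
            raise GeometryError(
                f"wiberg_ratio must lie in (0, 1), got {self.wiberg_ratio}")
        if self.mesh_resolution < 8:
            raise GeometryError(
                f"mesh_resolution must be >= 8 faces, got {self.mesh_resolution}")

    @property
    def wall_angle_deg(self) -> float:
        """Inclination of each groove wall from the mediolateral axis."""
        return (180.0 - self.sulcus_angle) / 2.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform (rotation matrix + translation), mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=1e-12)
                and np.allclose(self.translation, 0.0, atol=1e-12))


def rotation_about_x(angle_deg: float) -> RigidTransform:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return RigidTransform(rotation=np.array([
        [1.0, 0.0, 0.0],
        [0.0, c, -s],
        [0.0, s, c],
    ]))


@dataclass(frozen=True)
class TriMesh:
    """Minimal triangle surface (open boundary, consistently oriented)."""

    vertices: np.ndarray  # (nv, 3) mm
    faces: np.ndarray     # (nf, 3) int

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    @property
    def face_normals(self) -> np.ndarray:
        v = self.vertices[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def edge_lengths(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return np.concatenate([
            np.linalg.norm(v[:, 1] - v[:, 0], axis=1),
            np.linalg.norm(v[:, 2] - v[:, 1], axis=1),
            np.linalg.norm(v[:, 0] - v[:, 2], axis=1),
        ])

    def transformed(self, t: RigidTransform) -> "TriMesh":
        return TriMesh(vertices=t.apply(self.vertices), faces=self.faces)


@dataclass(frozen=True)
class Anchor:
    """Named insertion point, fixed either to the femur or to the patella."""

    name: str
    point: np.ndarray  # home-frame coordinates (femur frame, reference pose)
    frame: str         # "femur" | "patella"

    def __post_init__(self) -> None:
        if self.frame not in ("femur", "patella"):
            raise GeometryError(f"anchor frame must be femur|patella, got {self.frame}")


def _wedge_profile(x: np.ndarray, ridge_x: float, wall_deg: float,
                   depth: float, blend: float) -> np.ndarray:
    """Radial rise of a rounded-V profile above its floor, as f(|x - ridge|)."""
    t = np.tan(np.deg2rad(wall_deg))
    d = np.abs(np.asarray(x, dtype=float) - ridge_x)
    rise = np.where(d < blend, d * d * t / (2.0 * blend), (d - blend / 2.0) * t)
    return np.minimum(rise, depth)


class FemoralSurface:
    """Trochlear cartilage outer surface: rounded-V profile of revolution.

    Radius profile about the flexion axis: R(x) = Rc + wedge(x), the groove
    floor at x = 0 and walls rising toward the condylar crests.  Provides an
    exact smooth signed-distance (penetration) query used by the contact
    solver; the triangulated mesh is for export and pressure reporting only.
    """

    def __init__(self, params: JointParams):
        self.params = params
        self._tan = np.tan(np.deg2rad(params.wall_angle_deg))
        self._blend = _GROOVE_BLEND
        self._cap = params.groove_depth

    def radius(self, x: np.ndarray) -> np.ndarray:
        return self.params.condyle_radius + _wedge_profile(
            x, 0.0, self.params.wall_angle_deg, self._cap, self._blend)

    def slope(self, x: np.ndarray) -> np.ndarray:
        """dR/dx of the profile (signed)."""
        x = np.asarray(x, dtype=float)
        d = np.abs(x)
        s = np.where(d < self._blend, d * self._tan / self._blend, self._tan)
        # plateau beyond the cap
        cap_d = self._cap / self._tan + self._blend / 2.0
        s = np.where(d >= cap_d, 0.0, s)
        return np.sign(x) * s

    def penetration(self, points: np.ndarray):
        """Signed penetration depth and outward normals for query points.

        Positive depth means the point lies radially inside the cartilage
        surface.  Distance is measured along the local surface normal of the
        revolved profile (slope-corrected radial distance; exact for this
        surface family up to local curvature).
        """
        p = np.asarray(points, dtype=float)
        x = p[:, 0]
        rho = np.hypot(p[:, 1], p[:, 2])
        rho_safe = np.maximum(rho, 1e-9)
        gap = rho - self.radius(x)
        s = self.slope(x)
        denom = np.sqrt(1.0 + s * s)
        depth = -gap / denom
        # outward normal of the revolved surface at the foot point
        n = np.empty_like(p)
        n[:, 0] = -s / denom
        n[:, 1] = (p[:, 1] / rho_safe) / denom
        n[:, 2] = (p[:, 2] / rho_safe) / denom
        return depth, n


@dataclass(frozen=True)
class PosedJoint:
    """A joint posed at a flexion angle.

    Meshes are stored in their home frames (femur frame for the femoral
    cartilage; the patella frame coincides with the femur frame at the
    reference pose).  ``patella_pose`` maps patella-frame points into the
    femur frame; ``base_transform`` maps the femur frame into the world (for
    frame-invariance checks and export).
    """

    params: JointParams
    flexion_angle: float
    femoral_cartilage_mesh: TriMesh
    patellar_cartilage_mesh: TriMesh
    patella_pose: RigidTransform
    anchors: dict
    femoral_surface: FemoralSurface
    patella_center: np.ndarray  # home-frame patella body centroid
    base_transform: RigidTransform = field(default_factory=RigidTransform)

    def anchor_world(self, name: str, extra_patella: RigidTransform | None = None) -> np.ndarray:
        """Anchor position in the world frame under the current pose.

        ``extra_patella`` optionally composes a further patella displacement
        (applied in the femur frame after ``patella_pose``).
        """
        a = self.anchors[name]
        p = a.point
        if a.frame == "patella":
            p = self.patella_pose.apply(p[None])[0]
            if extra_patella is not None:
                p = extra_patella.apply(p[None])[0]
        return self.base_transform.apply(p[None])[0]

    def patellar_centroids_femur_frame(self, extra: RigidTransform | None = None) -> np.ndarray:
        pts = self.patella_pose.apply(self.patellar_cartilage_mesh.face_centroids)
        if extra is not None:
            pts = extra.apply(pts)
        return pts

    def transformed(self, t: RigidTransform) -> "PosedJoint":
        return dataclasses.replace(self, base_transform=t.compose(self.base_transform))


def _grid_mesh(xs: np.ndarray, phis: np.ndarray, rho_fn) -> TriMesh:
    """Revolved-coordinate grid surface: rho = rho_fn(x, phi)."""
    X, P = np.meshgrid(xs, phis, indexing="ij")
    R = rho_fn(X, P)
    verts = np.stack([X, R * np.cos(P), R * np.sin(P)], axis=-1).reshape(-1, 3)
    nx, np_ = X.shape
    faces = []
    for i in range(nx - 1):
        for j in range(np_ - 1):
            a = i * np_ + j
            b = a + 1
            c = a + np_
            d = c + 1
            faces.append((a, c, b))
            faces.append((b, c, d))
    return TriMesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64))


def _grid_counts(target_faces: int) -> int:
    # square grid with 2*(n-1)^2 faces >= target
    return int(np.ceil(np.sqrt(target_faces / 2.0))) + 1


def patellar_profile_rise(params: JointParams, x: np.ndarray) -> np.ndarray:
    """Cross-section rise of the patellar wedge (facets shallower than groove).

    The median ridge seats in the sulcus (x = 0); the Wiberg ratio shapes the
    facet extents (medial facet narrower), not the ridge position.  The
    facets are one degree steeper than the groove walls so that the
    undisplaced surfaces touch at the ridge and clear everywhere else,
    giving a centre-weighted near-congruent contact patch under approach.
    """
    return _wedge_profile(
        x, 0.0, params.wall_angle_deg + _WEDGE_MISMATCH,
        np.inf, _GROOVE_BLEND)


def patellar_facet_extent(params: JointParams) -> tuple[float, float]:
    """(medial, lateral) facet widths in mm; medial fraction = wiberg_ratio."""
    return (params.wiberg_ratio * params.patella_width,
            (1.0 - params.wiberg_ratio) * params.patella_width)


def sagittal_gap(params: JointParams, arc_mm: np.ndarray) -> np.ndarray:
    """Radial clearance from sagittal-curvature mismatch at arc distance s."""
    rc = params.condyle_radius
    kappa = _SAG_MISMATCH / (rc * (rc + _SAG_MISMATCH))
    return 0.5 * kappa * np.asarray(arc_mm, dtype=float) ** 2


def track_angle_deg(flexion_angle: float) -> float:
    return TRACK_OFFSET_DEG + TRACK_RATIO * flexion_angle


def build_joint(params: JointParams | None = None) -> PosedJoint:
    """Construct the joint at the 40 deg reference flexion, zero displacement.

    The patellar cartilage mesh is generated congruent to the groove at the
    reference station (up to the wedge/sagittal mismatches) and stored in the
    patella frame, which coincides with the femur frame at reference.
    """
    params = params or JointParams()
    surf = FemoralSurface(params)
    phi_ref = np.deg2rad(track_angle_deg(REFERENCE_FLEXION))
    rc = params.condyle_radius

    n = _grid_counts(params.mesh_resolution)
    # femoral surface mesh: spans the groove and the patellar travel range
    half_w = params.patella_width / 2.0 + 4.0
    fem_phis = np.deg2rad(np.linspace(-30.0, 100.0, n))
    fem_xs = np.linspace(-half_w, half_w, n)
    fem_mesh = _grid_mesh(fem_xs, fem_phis,
                          lambda X, P: surf.radius(X) + 0.0 * P)

    # patellar articular surface in the femur frame at reference pose
    w_med, w_lat = patellar_facet_extent(params)
    arc_half = params.patella_height / 2.0
    dphi = arc_half / rc
    pat_xs = np.linspace(-w_med, w_lat, n)
    pat_phis = phi_ref + np.linspace(-dphi, dphi, n)

    groove_floor = rc  # groove floor radius at x=0

    def pat_rho(X, P):
        return (groove_floor + patellar_profile_rise(params, X)
                + sagittal_gap(params, (P - phi_ref) * rc))

    pat_mesh = _grid_mesh(pat_xs, pat_phis, pat_rho)

    center = np.array([
        0.0,
        (rc + _CENTER_OFFSET) * np.cos(phi_ref),
        (rc + _CENTER_OFFSET) * np.sin(phi_ref),
    ])

    anchors = _default_anchors(params, center)
    return PosedJoint(
        params=params,
        flexion_angle=REFERENCE_FLEXION,
        femoral_cartilage_mesh=fem_mesh,
        patellar_cartilage_mesh=pat_mesh,
        patella_pose=RigidTransform(),
        anchors=anchors,
        femoral_surface=surf,
        patella_center=center,
    )


def _default_anchors(params: JointParams, center: np.ndarray) -> dict:
    """Anatomically motivated insertion points (femur frame, reference pose).

    The MPFL femoral point sits near the flexion axis at the medial
    epicondyle (near-isometry); the AMT pulley lies proximal-posterior to it
    at the adductor tubercle; MQTFL attaches to the medial third of the
    quadriceps tendon above the superior pole.
    """
    med = -(params.patella_width / 2.0 + 19.0)   # medial epicondyle x
    lat = params.patella_width / 2.0 + 19.0
    c = center
    pts = {
        # femur-fixed
        "mpfl_femoral": (np.array([med, -5.0, 0.0]), "femur"),
        "amt_pulley": (np.array([med + 2.0, -8.0, 12.0]), "femur"),
        "lr_femoral": (np.array([lat, -5.0, 2.0]), "femur"),
        "qt_origin_vm": (np.array([-29.0, 2.0, 55.0]), "femur"),
        "qt_origin_vi": (np.array([0.0, 8.0, 70.0]), "femur"),
        "qt_origin_rf": (np.array([0.0, 18.0, 68.0]), "femur"),
        "qt_origin_vl": (np.array([27.0, 6.0, 64.0]), "femur"),
        "pt_tibial_med": (np.array([3.0, 22.0, -52.0]), "femur"),
        "pt_tibial_lat": (np.array([9.0, 22.0, -52.0]), "femur"),
        # patella-fixed (coordinates at the reference pose)
        "mpfl_patellar_sup": (c + np.array([-16.0, -4.0, 8.0]), "patella"),
        "mpfl_patellar_inf": (c + np.array([-16.0, -4.0, 1.0]), "patella"),
        "mqtfl_qt_point": (c + np.array([-5.0, -2.0, 14.0]), "patella"),
        "lr_patellar": (c + np.array([18.0, -4.0, 0.0]), "patella"),
        "qt_patellar_vm": (c + np.array([-6.0, 0.0, 13.0]), "patella"),
        "qt_patellar_vi": (c + np.array([-2.0, 0.0, 13.0]), "patella"),
        "qt_patellar_rf": (c + np.array([2.0, 0.0, 13.0]), "patella"),
        "qt_patellar_vl": (c + np.array([6.0, 0.0, 13.0]), "patella"),
        "pt_patellar_med": (c + np.array([-4.0, 0.0, -13.0]), "patella"),
        "pt_patellar_lat": (c + np.array([4.0, 0.0, -13.0]), "patella"),
    }
    return {k: Anchor(k, p, fr) for k, (p, fr) in pts.items()}


def pose_at_flexion(joint: PosedJoint, angle: float) -> PosedJoint:
    """Transport the patella along the condylar track to ``angle`` degrees.

    The patella frame rotates about the femoral flexion axis by the track
    increment; femur-fixed anchors are untouched.
    """
    if not 0.0 <= angle <= 120.0:
        raise GeometryError(f"flexion angle must lie in [0, 120], got {angle}")
    dphi = track_angle_deg(angle) - track_angle_deg(REFERENCE_FLEXION)
    return dataclasses.replace(
        joint,
        flexion_angle=float(angle),
        patella_pose=rotation_about_x(dphi),
    )


def sample_cohort(params: JointParams, n: int, cv: float, seed: int) -> list[JointParams]:
    """Seeded cohort of joint-parameter variants (stand-in for a scanned
    sample of knees): each length/angle parameter drawn from a normal
    distribution with coefficient of variation ``cv``, truncated to the
    family's valid ranges."""
    if n < 1:
        raise GeometryError(f"cohort size must be >= 1, got {n}")
    if not 0.0 <= cv <= 0.2:
        raise GeometryError(f"cv must lie in [0, 0.2], got {cv}")
    rng = np.random.default_rng(seed)
    bounds = {
        "sulcus_angle": (90.001, 179.999),
        "groove_depth": (0.5, np.inf),
        "condyle_radius": (5.0, np.inf),
        "patella_width": (5.0, np.inf),
        "patella_height": (5.0, np.inf),
        "wiberg_ratio": (0.05, 0.95),
        "cartilage_thickness_femur": (0.5, np.inf),
        "cartilage_thickness_patella": (0.5, np.inf),
    }
    out = []
    for _ in range(n):
        kwargs = {}
        for name, (lo, hi) in bounds.items():
            mu = getattr(params, name)
            val = float(rng.normal(mu, cv * abs(mu))) if cv > 0 else float(mu)
            kwargs[name] = min(max(val, lo), hi)
        kwargs["mesh_resolution"] = params.mesh_resolution
        out.append(JointParams(**kwargs))
    return out


def export_anchors_json(joint: PosedJoint, path: str | Path) -> None:
    data = {
        name: {"point": [float(v) for v in joint.anchor_world(name)],
               "frame": a.frame}
        for name, a in joint.anchors.items()
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def export_obj(mesh: TriMesh, path: str | Path) -> None:
    import trimesh as _tm

    tm = _tm.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_text(tm.export(file_type="obj"))
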