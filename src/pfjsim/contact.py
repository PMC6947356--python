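"""Cartilage contact and quasi-static patellar equilibrium.

Contact uses an elastic-foundation (Winkler) formulation: the two 3 mm
cartilage layers between rigid bones act as a bed of independent compressive
springs in series, p = M * delta / (t_f + t_p), with the confined-layer
modulus M = E (1 - nu) / ((1 + nu)(1 - 2 nu)).  Penetration is the signed
normal distance from patellar face centroids to the parametric femoral
surface.  Tangential traction is regularized Coulomb friction (tanh
smoothing), bounded by mu * p.

Equilibrium: the rigid patella's pose increments (translations restricted to
a caller-chosen free basis, all three rotations) are solved by a damped
Newton iteration on the generalized residual wrench, with the ligament
pretension ramped in increments and warm-started poses between steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import PosedJoint, RigidTransform, TriMesh

logger = logging.getLogger(__name__)

_ROT_SCALE = 20.0  # mm lever arm used to nondimensionalize rotation DOFs


class ContactError(ValueError):
    """Invalid contact parameter or degenerate configuration."""


@dataclass(frozen=True)
class ContactParams:
    """Cartilage layer and solver parameters (MPa, mm)."""

    E_cartilage: float = 10.0
    poisson: float = 0.45
    total_thickness: float = 6.0
    friction_mu: float = 0.02
    approach_depth: float = 0.3
    regularization_velocity: float = 0.01
    tol_force: float = 1e-4      # N
    tol_torque: float = 1e-3     # N*mm
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson < 0.5:
            raise ContactError(f"poisson must lie in [0, 0.5), got {self.poisson}")
        for name in ("E_cartilage", "total_thickness"):
            if not getattr(self, name) > 0:
                raise ContactError(f"{name} must be > 0")
        if self.friction_mu < 0:
            raise ContactError("friction_mu must be >= 0")
        if self.approach_depth < 0:
            raise ContactError("approach_depth must be >= 0")

    @property
    def foundation_stiffness(self) -> float:
        """M / t in MPa per mm of penetration."""
        return foundation_modulus(self.E_cartilage, self.poisson) / self.total_thickness


def foundation_modulus(E: float, nu: float) -> float:
    """Confined (oedometric) modulus M = E(1-nu)/((1+nu)(1-2nu)) in MPa."""
    if not 0.0 <= nu < 0.5:
        raise ContactError(f"poisson ratio must lie in [0, 0.5), got {nu}")
    if E <= 0:
        raise ContactError(f"elastic modulus must be positive, got {E}")
    return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))


def contact_pressure(penetration, M: float, total_thickness: float):
    """Foundation law p = M * max(delta, 0) / t, elementwise (MPa)."""
    if total_thickness <= 0:
        raise ContactError("total_thickness must be positive")
    return np.maximum(np.asarray(penetration, dtype=float), 0.0) * M / total_thickness


@dataclass(frozen=True)
class PressureField:
    """Per-face contact pressures on the patellar cartilage mesh."""

    mesh: TriMesh
    pressure: np.ndarray  # (nf,) MPa, >= 0
    area: np.ndarray      # (nf,) mm^2
    flexion_angle: float

    def max(self) -> float:
        return max_pressure(self)


def max_pressure(field: PressureField) -> float:
    if field.pressure.size == 0:
        raise ContactError("empty pressure field")
    return float(field.pressure.max())


def relative_pressure(after: PressureField, baseline: PressureField) -> PressureField:
    """Baseline-subtracted field: per-face max(p_after - p_baseline, 0)."""
    if after.pressure.shape != baseline.pressure.shape or \
            after.flexion_angle != baseline.flexion_angle:
        raise ContactError("pressure fields are on different meshes or angles")
    return PressureField(
        mesh=after.mesh,
        pressure=np.maximum(after.pressure - baseline.pressure, 0.0),
        area=after.area,
        flexion_angle=after.flexion_angle,
    )


@dataclass
class SpringHandle:
    """Femur-frame view of a tension-only element for the solver.

    ``attach_home`` is the patella-fixed anchor at the solve's start pose;
    ``slack`` is the zero-force length at full pretension ramp.
    """

    name: str
    fixed_point: np.ndarray
    attach_home: np.ndarray
    K: float
    slack: float
    delta_L: float = 0.0
    ref: object = None

    def force_vector(self, extra: RigidTransform, ramp: float):
        attach = extra.apply(self.attach_home[None])[0]
        d = self.fixed_point - attach
        L = float(np.linalg.norm(d))
        slack_eff = self.slack + (1.0 - ramp) * max(self.delta_L, 0.0)
        F = self.K * max(L - slack_eff, 0.0)
        return (F / L) * d, attach, F


@dataclass
class ContactSystem:
    """Discretized patella + foundation + springs, posed in the femur frame."""

    surface: object               # exposes penetration(points) -> (depth, normals)
    centroids: np.ndarray         # (nf, 3) patellar face centroids at q = 0
    areas: np.ndarray             # (nf,)
    center: np.ndarray            # rotation center / torque reference
    springs: list
    foundation_stiffness: float   # M / t, MPa per mm
    mu: float = 0.0
    v_reg: float = 0.01
    friction_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.areas <= 0):
            raise ContactError("mesh has zero-area faces")

    def pressures(self, extra: RigidTransform) -> np.ndarray:
        pts = extra.apply(self.centroids)
        depth, _ = self.surface.penetration(pts)
        return contact_pressure(depth, self.foundation_stiffness, 1.0)

    def wrench(self, extra: RigidTransform, ramp: float = 1.0):
        """Total (force, torque about ``center``) on the patella, plus the
        per-face pressures and per-spring tensions."""
        pts = extra.apply(self.centroids)
        depth, normals = self.surface.penetration(pts)
        p = contact_pressure(depth, self.foundation_stiffness, 1.0)
        f_faces = (p * self.areas)[:, None] * normals
        if self.mu > 0.0:
            ref = self.centroids if self.friction_ref is None else self.friction_ref
            slip = pts - ref
            slip_t = slip - (np.einsum("ij,ij->i", slip, normals))[:, None] * normals
            mag = np.linalg.norm(slip_t, axis=1)
            scale = np.where(mag > 0, np.tanh(mag / self.v_reg) / np.maximum(mag, 1e-30), 0.0)
            f_faces -= (self.mu * p * self.areas * scale)[:, None] * slip_t
        force = f_faces.sum(axis=0)
        torque = np.cross(pts - self.center, f_faces).sum(axis=0)
        tensions = {}
        for s in self.springs:
            fv, attach, F = s.force_vector(extra, ramp)
            force = force + fv
            torque = torque + np.cross(attach - self.center, fv)
            tensions[s.name] = F
        return force, torque, p, tensions


def _rodrigues(w: np.ndarray) -> np.ndarray:
    theta = float(np.linalg.norm(w))
    if theta < 1e-14:
        return np.eye(3)
    k = w / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def _extra_from_q(q: np.ndarray, trans_basis: np.ndarray, center: np.ndarray) -> RigidTransform:
    k = trans_basis.shape[0]
    u = q[:k] @ trans_basis
    w = q[k:] / _ROT_SCALE
    R = _rodrigues(w)
    return RigidTransform(rotation=R, translation=u + center - R @ center)


def solve_system(system: ContactSystem, params: ContactParams,
                 trans_basis: np.ndarray, ramp_schedule,
                 q0: np.ndarray | None = None):
    """Damped-Newton equilibrium solve over the ramp schedule.

    ``trans_basis`` is a (k, 3) orthonormal set of free translation
    directions (k in 0..3); all three rotations are always free.  Returns
    (q, extra, converged, residual_norms) at the final ramp value.
    """
    k = trans_basis.shape[0]
    n = k + 3
    q = np.zeros(n) if q0 is None else np.array(q0, dtype=float)

    def residual(qv: np.ndarray, ramp: float) -> np.ndarray:
        extra = _extra_from_q(qv, trans_basis, system.center)
        force, torque, _, _ = system.wrench(extra, ramp)
        return np.concatenate([trans_basis @ force, torque / _ROT_SCALE])

    def norms(qv: np.ndarray, ramp: float):
        extra = _extra_from_q(qv, trans_basis, system.center)
        force, torque, _, _ = system.wrench(extra, ramp)
        fn = float(np.linalg.norm(trans_basis @ force)) if k else 0.0
        return fn, float(np.linalg.norm(torque))

    converged = True
    for ramp in ramp_schedule:
        ok = False
        for it in range(params.max_iterations):
            r = residual(q, ramp)
            fn, tn = norms(q, ramp)
            if fn < params.tol_force and tn < params.tol_torque:
                ok = True
                break
            # forward-difference Jacobian
            J = np.empty((n, n))
            h = 1e-6
            for j in range(n):
                qp = q.copy()
                qp[j] += h
                J[:, j] = (residual(qp, ramp) - r) / h
            # truncated-SVD solve: unresisted directions (e.g. tangential
            # motion of a frictionless flat patch) make J numerically
            # singular and a raw solve returns garbage steps
            dq = np.linalg.lstsq(J, -r, rcond=1e-9)[0]
            # trust region: physical increments are sub-mm; a capped step
            # keeps one-sided contact/slack kinks from launching the pose
            step = float(np.max(np.abs(dq)))
            if step > 0.25:
                dq *= 0.25 / step
            # backtracking line search on the residual norm
            base = float(np.linalg.norm(r))
            alpha = 1.0
            while alpha > 1e-6:
                rn = float(np.linalg.norm(residual(q + alpha * dq, ramp)))
                if rn < base * (1.0 - 1e-4 * alpha) or rn < 1e-12:
                    break
                alpha *= 0.5
            if alpha <= 1e-6:
                # flat or kinked landscape: accept a tiny step and continue
                alpha = 1e-6
            q = q + alpha * dq
            logger.debug("ramp %.3f it %d |F|=%.3e |T|=%.3e alpha=%.2g",
                         ramp, it, fn, tn, alpha)
        if not ok:
            fn, tn = norms(q, ramp)
            ok = fn < params.tol_force and tn < params.tol_torque
        converged = converged and ok
    extra = _extra_from_q(q, trans_basis, system.center)
    return q, extra, converged, norms(q, list(ramp_schedule)[-1])


@dataclass
class EquilibriumSolution:
    """Solved patella pose with element forces and the contact field."""

    patella_pose: RigidTransform
    extra: RigidTransform              # displacement from the posed state
    element_forces: dict
    pressure_field: PressureField
    residual_wrench: tuple
    converged: bool
    load_steps: int
    elements: list = field(default_factory=list)
    free_basis: np.ndarray | None = None
    friction_ref: np.ndarray | None = None
    #: held/rotation reference point; must be reused by follow-on solves
    #: because the held-DOF reaction makes torque reference-dependent
    constraint_center: np.ndarray | None = None


def _approach_normal(joint: PosedJoint) -> np.ndarray:
    """Outward radial direction at the posed patella centre."""
    c = joint.patella_pose.apply(joint.patella_center[None])[0]
    n = np.array([0.0, c[1], c[2]])
    return n / np.linalg.norm(n)


def _free_translation_basis(held_dir: np.ndarray | None) -> np.ndarray:
    if held_dir is None:
        return np.eye(3)
    n = held_dir / np.linalg.norm(held_dir)
    # two orthonormal vectors spanning the plane normal to n
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    b1 = a - (a @ n) * n
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(n, b1)
    return np.vstack([b1, b2])


def _springs_from_elements(joint: PosedJoint, elements,
                           start_extra: RigidTransform) -> list:
    springs = []
    for el in elements:
        fa = joint.anchors[el.femur_anchor]
        pa = joint.anchors[el.patella_anchor]
        if fa.frame != "femur" or pa.frame != "patella":
            raise ContactError(
                f"element {el.name}: expected femur-fixed + patella-fixed anchors")
        attach = start_extra.apply(joint.patella_pose.apply(pa.point[None]))[0]
        springs.append(SpringHandle(
            name=el.name, fixed_point=fa.point.copy(), attach_home=attach,
            K=el.stiffness_K,
            slack=el.slack_length if el.slack_length is not None
            else float(np.linalg.norm(attach - fa.point)),
            delta_L=el.delta_L, ref=el))
    return springs


def _make_system(joint: PosedJoint, elements, params: ContactParams,
                 start_extra: RigidTransform,
                 friction_ref: np.ndarray | None) -> ContactSystem:
    centroids = start_extra.apply(
        joint.patella_pose.apply(joint.patellar_cartilage_mesh.face_centroids))
    areas = joint.patellar_cartilage_mesh.face_areas
    center = start_extra.apply(
        joint.patella_pose.apply(joint.patella_center[None]))[0]
    return ContactSystem(
        surface=joint.femoral_surface,
        centroids=centroids,
        areas=areas,
        center=center,
        springs=_springs_from_elements(joint, elements, start_extra),
        foundation_stiffness=params.foundation_stiffness,
        mu=params.friction_mu,
        v_reg=params.regularization_velocity,
        friction_ref=friction_ref if friction_ref is not None else centroids,
    )


def contact_wrench(joint: PosedJoint, params: ContactParams,
                   extra: RigidTransform | None = None):
    """Contact-only wrench (force N, torque N*mm about the patella centre)
    and the pressure field at the joint's current pose."""
    extra = extra or RigidTransform()
    system = _make_system(joint, [], params, extra, None)
    force, torque, p, _ = system.wrench(RigidTransform(), ramp=1.0)
    fld = PressureField(mesh=joint.patellar_cartilage_mesh, pressure=p,
                        area=system.areas, flexion_angle=joint.flexion_angle)
    return force, torque, fld


def baseline_state(joint: PosedJoint, params: ContactParams,
                   tether_elements=None) -> EquilibriumSolution:
    """Seat the patella: advance it radially by ``approach_depth`` (held
    thereafter), zero the QT/PT tether tensions at the approached pose, and
    equilibrate the remaining five DOFs under contact + tethers only."""
    from .ligaments import build_tethers

    n_hat = _approach_normal(joint)
    approach = RigidTransform(translation=-params.approach_depth * n_hat)
    elements = build_tethers(joint) if tether_elements is None else tether_elements
    for el in elements:
        el.set_slack_from_pose(joint, approach)
    system = _make_system(joint, elements, params, approach, None)
    if params.approach_depth > 0:
        depth, _ = joint.femoral_surface.penetration(system.centroids)
        if not np.any(depth > 0):
            raise ContactError(
                "no cartilage contact at the prescribed approach depth")
    basis = _free_translation_basis(n_hat)
    q, extra_eq, converged, res = solve_system(system, params, basis, [1.0])
    total_extra = extra_eq.compose(approach)
    _, _, p, tensions = system.wrench(extra_eq, ramp=1.0)
    fld = PressureField(mesh=joint.patellar_cartilage_mesh, pressure=p,
                        area=system.areas, flexion_angle=joint.flexion_angle)
    return EquilibriumSolution(
        patella_pose=total_extra.compose(joint.patella_pose),
        extra=total_extra,
        element_forces=tensions,
        pressure_field=fld,
        residual_wrench=res,
        converged=converged,
        load_steps=1,
        elements=elements,
        free_basis=basis,
        friction_ref=system.friction_ref,
        constraint_center=system.center,
    )


def solve_equilibrium(joint: PosedJoint, elements, params: ContactParams,
                      n_steps: int = 10,
                      baseline: EquilibriumSolution | None = None) -> EquilibriumSolution:
    """Ramp the ligament pretension in ``n_steps`` increments from the
    baseline state and solve the patella's equilibrium at each step.

    Tether (QT/PT) slack lengths are inherited from the baseline so that an
    element set without MPFL/LR reproduces the baseline exactly.  Element
    forces are re-evaluated at the final pose, so stiff grafts relax as the
    patella displaces.
    """
    if n_steps < 1:
        raise ContactError("n_steps must be >= 1")
    baseline = baseline if baseline is not None else baseline_state(joint, params)
    base_slacks = {el.name: el.slack_length for el in baseline.elements}
    for el in elements:
        if el.role in ("qt", "pt") and el.name in base_slacks:
            el.slack_length = base_slacks[el.name]
    system = _make_system(joint, elements, params, baseline.extra,
                          baseline.friction_ref)
    if baseline.constraint_center is not None:
        system.center = baseline.constraint_center
    basis = baseline.free_basis if baseline.free_basis is not None \
        else _free_translation_basis(_approach_normal(joint))
    schedule = [(i + 1) / n_steps for i in range(n_steps)]
    q, extra_eq, converged, res = solve_system(system, params, basis, schedule)
    if not converged:
        logger.info("equilibrium not converged: |F|=%.3e N |T|=%.3e N*mm", *res)
    total_extra = extra_eq.compose(baseline.extra)
    _, _, p, tensions = system.wrench(extra_eq, ramp=1.0)
    fld = PressureField(mesh=joint.patellar_cartilage_mesh, pressure=p,
                        area=system.areas, flexion_angle=joint.flexion_angle)
    return EquilibriumSolution(
        patella_pose=total_extra.compose(joint.patella_pose),
        extra=total_extra,
        element_forces=tensions,
        pressure_field=fld,
        residual_wrench=res,
        converged=converged,
        load_steps=n_steps,
        elements=list(elements),
        free_basis=basis,
        friction_ref=baseline.friction_ref,
        constraint_center=system.center,
    )


class FlatFoundation:
    """Analytic flat foundation occupying z <= 0 (outward normal +z).

    Test/oracle surface: penetration of a point is -z.
    """

    def penetration(self, points: np.ndarray):
        p = np.asarray(points, dtype=float)
        depth = -p[:, 2]
        normals = np.zeros_like(p)
        normals[:, 2] = 1.0
        return depth, normals
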