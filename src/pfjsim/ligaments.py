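"""Ligament and tendon elements of the PFJ model.

Houses the measured tissue stiffness table and the flexion-indexed
attachment-distance profiles for the native MPFL and the three
reconstruction techniques, the tension-only axial mechanics, the pretension
protocol F = dL x K about the 40-degree reference flexion, and the shared
cross-sectional-area calibration that closes sigma = F / A (the source
tables report stiffnesses and stresses but no graft cross-section).

Bundle bookkeeping: the native MPFL is a fan-shaped ligament whose measured
stiffness describes the whole structure, so its two bundles share K and A
(half each); a reconstruction graft is a tendon strand whose measured
stiffness describes the strand, so each limb of a looped graft carries the
full K and full A.  Either way the per-bundle stress under pretension equals
dL x K / A.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import PosedJoint, REFERENCE_FLEXION, RigidTransform

TECHNIQUES = ("intact", "static_anatomic", "amt_pulley", "mqtfl")
GRAFTS = ("native", "semitendinosus", "gracilis", "tibialis_posterior_allograft")

#: Technique -> grafts tested in the source study.
ALLOWED_PAIRS = {
    "intact": ("native",),
    "static_anatomic": ("semitendinosus", "gracilis"),
    "amt_pulley": ("semitendinosus", "gracilis"),
    "mqtfl": ("semitendinosus", "tibialis_posterior_allograft"),
}

#: Intact-knee 0-degree calibration row: pretension elongation (mm), native
#: ligament stiffness (N/mm) and the reported maximum ligament stress (MPa).
INTACT_CALIBRATION = {"delta_L": 2.5, "K": 12.0, "sigma": 8.85}

_QT_NAMES = ("vm", "vi", "rf", "vl")
_TETHER_AREA = 30.0  # mm^2, nominal; tether stresses are never reported


class LigamentError(ValueError):
    """Invalid ligament specification or query."""


def load_tissue_table() -> pd.DataFrame:
    """Measured stiffness (N/mm) and Poisson ratio per tissue.

    The Poisson ratio is recorded for fidelity but unused: axial tension-only
    elements do not consume it.
    """
    with importlib.resources.files("pfjsim.data").joinpath(
            "material_properties.csv").open() as fh:
        return pd.read_csv(fh).set_index("name")


def load_length_profiles() -> dict[str, "LengthProfile"]:
    with importlib.resources.files("pfjsim.data").joinpath(
            "length_profiles.csv").open() as fh:
        df = pd.read_csv(fh)
    out = {}
    for bundle, grp in df.groupby("bundle"):
        out[bundle] = LengthProfile(
            technique_bundle=bundle,
            lengths={float(a): float(l) for a, l in
                     zip(grp["flexion_deg"], grp["length_mm"])},
            markers={float(a): str(m) for a, m in
                     zip(grp["flexion_deg"], grp["tension"])},
        )
    return out


@dataclass(frozen=True)
class LengthProfile:
    """Attachment-to-attachment distance (mm) indexed by flexion angle.

    ``markers`` record the source table's per-angle tension state ("+" under
    tension, "*" slack, "ref" at the reference angle).  The markers are not
    fully consistent with the length differences (the AMT inferior bundle is
    marked "+" at 0/30 deg though shorter than at reference, and "*" at
    60/90 deg though longer); where they disagree, the slack state follows
    whichever rule predicts no tension.
    """

    technique_bundle: str
    lengths: dict
    reference_angle: float = REFERENCE_FLEXION
    markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_angle not in self.lengths:
            raise LigamentError(
                f"profile {self.technique_bundle} lacks the reference angle "
                f"{self.reference_angle}")
        if any(v <= 0 for v in self.lengths.values()):
            raise LigamentError("profile lengths must be positive")


def nominal_elongation(profile: LengthProfile, angle: float) -> float:
    """Signed elongation L(angle) - L(reference); negative means slack."""
    if angle not in profile.lengths:
        raise LigamentError(
            f"angle {angle} not tabulated for profile {profile.technique_bundle}")
    return profile.lengths[angle] - profile.lengths[profile.reference_angle]


def effective_elongation(profile: LengthProfile, angle: float) -> float:
    """Pretension elongation honouring the table's slack markers.

    At angles the source marks slack ("*") the element is installed with a
    slack margin of |dL| regardless of the sign of the tabulated length
    difference; at "+"-marked angles the signed dL is used as is (a negative
    dL still clamps to zero pretension downstream)."""
    dl = nominal_elongation(profile, angle)
    if profile.markers.get(angle) == "*":
        return -abs(dl)
    return dl


def pretension_force(delta_L: float, K: float) -> float:
    """Pretension dL x K, clamped at zero for slack (negative dL)."""
    if K <= 0:
        raise LigamentError(f"stiffness must be positive, got {K}")
    return max(delta_L, 0.0) * K


def element_axial_force(current_length: float, slack_length: float, K: float) -> float:
    """Tension-only linear spring: K x max(L - L_slack, 0)."""
    if current_length <= 0 or slack_length <= 0:
        raise LigamentError("lengths must be positive")
    return K * max(current_length - slack_length, 0.0)


def axial_stress(force: float, area: float) -> float:
    """Engineering axial stress F / A in MPa (N and mm^2)."""
    if area <= 0:
        raise LigamentError(f"cross-section area must be positive, got {area}")
    return force / area


def calibrate_area(intact_row: dict | None = None) -> float:
    """Shared ligament cross-section (mm^2) from the intact 0-degree row.

    A = dL x K / sigma, applied to all MPFL-type and retinaculum elements.
    """
    row = dict(INTACT_CALIBRATION if intact_row is None else intact_row)
    if row["sigma"] <= 0:
        raise LigamentError(f"sigma must be positive, got {row['sigma']}")
    return row["delta_L"] * row["K"] / row["sigma"]


@dataclass(frozen=True)
class ReconstructionSpec:
    """Which fixation technique and graft a simulation case uses."""

    technique: str = "intact"
    graft: str = "native"

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise LigamentError(f"unknown technique {self.technique!r}")
        if self.graft not in GRAFTS:
            raise LigamentError(f"unknown graft {self.graft!r}")
        if self.graft not in ALLOWED_PAIRS[self.technique]:
            raise LigamentError(
                f"graft {self.graft!r} was not tested with technique "
                f"{self.technique!r} (allowed: {ALLOWED_PAIRS[self.technique]})")

    @property
    def label(self) -> str:
        return f"{self.technique}_{self.graft}"


def graft_stiffness(spec: ReconstructionSpec, tissues: pd.DataFrame) -> float:
    if spec.technique == "intact":
        return float(tissues.loc["native_mpfl", "stiffness_K"])
    if spec.technique == "mqtfl" and spec.graft == "tibialis_posterior_allograft":
        return float(tissues.loc["tibialis_posterior_allograft", "stiffness_K"])
    return float(tissues.loc[spec.graft, "stiffness_K"])


@dataclass
class LigamentElement:
    """A straight tension-only elastic element between two anchors.

    ``delta_L`` is the pretension elongation taken from the measured length
    profiles (zero for the QT/PT tethers); ``slack_length`` is resolved
    against the joint geometry so that the tension at the pose where it is
    set equals pretension_force(delta_L, K).
    """

    name: str
    femur_anchor: str
    patella_anchor: str
    stiffness_K: float
    cross_section_A: float
    delta_L: float = 0.0
    slack_length: float | None = None
    role: str = "mpfl"  # mpfl | lr | qt | pt
    tension_only: bool = True

    def current_length(self, joint: PosedJoint,
                       extra: RigidTransform | None = None) -> float:
        a = joint.anchor_world(self.femur_anchor, extra_patella=extra)
        b = joint.anchor_world(self.patella_anchor, extra_patella=extra)
        return float(np.linalg.norm(b - a))

    def set_slack_from_pose(self, joint: PosedJoint,
                            extra: RigidTransform | None = None) -> None:
        self.slack_length = self.current_length(joint, extra) - self.delta_L

    def force(self, joint: PosedJoint, extra: RigidTransform | None = None,
              ramp: float = 1.0) -> float:
        """Axial tension at the given patella displacement.

        ``ramp`` in (0, 1] scales the pretension elongation (incremental
        loading); the slack length must already be resolved.
        """
        if self.slack_length is None:
            raise LigamentError(f"element {self.name}: slack length not set")
        slack = self.slack_length + (1.0 - ramp) * max(self.delta_L, 0.0)
        return element_axial_force(self.current_length(joint, extra), slack,
                                   self.stiffness_K)

    def stress(self, force: float) -> float:
        return axial_stress(force, self.cross_section_A)


def _lr_profile_key(technique: str) -> str:
    # The retinaculum's elongation follows the active medial structure's
    # profile (the source protocol ties LR length to the MPFL length); for
    # the AMT technique the tensioned superior bundle is used.
    return {"intact": "anatomic", "static_anatomic": "anatomic",
            "amt_pulley": "amt_superior", "mqtfl": "mqtfl"}[technique]


def build_elements(spec: ReconstructionSpec, joint: PosedJoint,
                   tissues: pd.DataFrame | None = None,
                   profiles: dict | None = None,
                   cross_section: float | None = None,
                   angle: float | None = None,
                   extra_pose: RigidTransform | None = None) -> list[LigamentElement]:
    """Assemble the element set for a technique at the joint's flexion angle.

    Pretension elongations are read from the measured profiles at ``angle``
    (defaults to the joint's flexion angle); slack lengths are resolved at
    the joint's current pose (optionally offset by ``extra_pose``, e.g. the
    baseline-approach pose) so that each element's initial tension equals its
    pretension force.  QT/PT tethers carry zero pretension.
    """
    tissues = load_tissue_table() if tissues is None else tissues
    profiles = load_length_profiles() if profiles is None else profiles
    A = calibrate_area() if cross_section is None else cross_section
    ang = joint.flexion_angle if angle is None else angle

    K = graft_stiffness(spec, tissues)
    elements: list[LigamentElement] = []

    def dl(bundle: str) -> float:
        return effective_elongation(profiles[bundle], ang)

    if spec.technique in ("intact", "static_anatomic"):
        # two bundles, anatomic femoral point to two patellar points
        per_bundle_K = K / 2.0 if spec.technique == "intact" else K
        per_bundle_A = A / 2.0 if spec.technique == "intact" else A
        for pat in ("mpfl_patellar_sup", "mpfl_patellar_inf"):
            elements.append(LigamentElement(
                name=f"mpfl_{pat.rsplit('_', 1)[-1]}",
                femur_anchor="mpfl_femoral", patella_anchor=pat,
                stiffness_K=per_bundle_K, cross_section_A=per_bundle_A,
                delta_L=dl("anatomic"), role="mpfl"))
    elif spec.technique == "amt_pulley":
        for bundle, pat in (("amt_superior", "mpfl_patellar_sup"),
                            ("amt_inferior", "mpfl_patellar_inf")):
            elements.append(LigamentElement(
                name=bundle, femur_anchor="amt_pulley", patella_anchor=pat,
                stiffness_K=K, cross_section_A=A,
                delta_L=dl(bundle), role="mpfl"))
    else:  # mqtfl
        elements.append(LigamentElement(
            name="mqtfl", femur_anchor="mpfl_femoral",
            patella_anchor="mqtfl_qt_point",
            stiffness_K=K, cross_section_A=A,
            delta_L=dl("mqtfl"), role="mpfl"))

    elements.append(LigamentElement(
        name="lateral_retinaculum", femur_anchor="lr_femoral",
        patella_anchor="lr_patellar",
        stiffness_K=float(tissues.loc["lateral_retinaculum", "stiffness_K"]),
        cross_section_A=A,
        delta_L=dl(_lr_profile_key(spec.technique)), role="lr"))

    elements.extend(build_tethers(joint, tissues))

    for el in elements:
        el.set_slack_from_pose(joint, extra_pose)
    return elements


def build_tethers(joint: PosedJoint, tissues: pd.DataFrame | None = None,
                  extra_pose: RigidTransform | None = None) -> list[LigamentElement]:
    """QT (x4) and PT (x2) tension-only tethers with zero pretension."""
    tissues = load_tissue_table() if tissues is None else tissues
    elements = []
    qt_K = float(tissues.loc["quadriceps_tendon", "stiffness_K"])
    for nm in _QT_NAMES:
        elements.append(LigamentElement(
            name=f"qt_{nm}", femur_anchor=f"qt_origin_{nm}",
            patella_anchor=f"qt_patellar_{nm}",
            stiffness_K=qt_K, cross_section_A=_TETHER_AREA, role="qt"))
    pt_K = float(tissues.loc["patellar_tendon", "stiffness_K"])
    for side in ("med", "lat"):
        elements.append(LigamentElement(
            name=f"pt_{side}", femur_anchor=f"pt_tibial_{side}",
            patella_anchor=f"pt_patellar_{side}",
            stiffness_K=pt_K, cross_section_A=_TETHER_AREA, role="pt"))
    for el in elements:
        el.set_slack_from_pose(joint, extra_pose)
    return elements


def scaled_elements(elements: list[LigamentElement], mpfl_scale: float) -> list[LigamentElement]:
    """Copy of the element set with MPFL stiffnesses scaled (sensitivity aid)."""
    return [replace(el, stiffness_K=el.stiffness_K * mpfl_scale)
            if el.role == "mpfl" else replace(el) for el in elements]
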