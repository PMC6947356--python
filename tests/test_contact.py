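"""Elastic-foundation contact and the quasi-static equilibrium solver."""

import numpy as np
import pytest

from pfjsim.contact import (ContactError, ContactParams, ContactSystem,
                            FlatFoundation, PressureField, SpringHandle,
                            baseline_state, contact_pressure, contact_wrench,
                            foundation_modulus, max_pressure,
                            relative_pressure, solve_equilibrium, solve_system)
from pfjsim.geometry import (JointParams, RigidTransform, build_joint,
                             pose_at_flexion, rotation_about_x)
from pfjsim.ligaments import ReconstructionSpec, build_elements


class TestFoundationLaw:
    def test_confined_modulus_value(self):
        assert foundation_modulus(10.0, 0.45) == pytest.approx(37.931, abs=1e-3)

    def test_zero_poisson_limit(self):
        assert foundation_modulus(10.0, 0.0) == 10.0

    def test_modulus_grows_toward_incompressible_limit(self):
        nus = np.linspace(0.0, 0.499, 40)
        ms = [foundation_modulus(10.0, nu) for nu in nus]
        assert np.all(np.diff(ms) > 0)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ContactError):
            foundation_modulus(10.0, 0.5)

    def test_pressure_law(self):
        M = foundation_modulus(10.0, 0.45)
        assert contact_pressure(0.0, M, 6.0) == 0.0
        assert contact_pressure(-0.2, M, 6.0) == 0.0
        assert contact_pressure(0.6, M, 6.0) == pytest.approx(3.793, abs=1e-3)
        # linear in penetration
        assert contact_pressure(0.4, M, 6.0) == pytest.approx(
            2 * contact_pressure(0.2, M, 6.0))


class TestContactWrench:
    def test_separated_surfaces_give_zero_wrench(self, default_joint):
        params = ContactParams()
        lifted = RigidTransform(translation=np.array([0.0, 5.0, 2.0]))
        force, torque, field = contact_wrench(default_joint, params, extra=lifted)
        assert np.allclose(force, 0.0)
        assert np.allclose(torque, 0.0)
        assert field.pressure.max() == 0.0

    def test_uniform_flat_patch_matches_closed_form(self, flat_patch):
        cent, areas = flat_patch
        params = ContactParams(friction_mu=0.0)
        pushed = cent.copy()
        pushed[:, 2] -= 0.1  # uniform 0.1 mm penetration over 100 mm^2
        system = ContactSystem(FlatFoundation(), pushed, areas, np.zeros(3),
                               [], params.foundation_stiffness, mu=0.0)
        force, _, p, _ = system.wrench(RigidTransform())
        expected = foundation_modulus(10.0, 0.45) / 6.0 * 0.1 * 100.0
        assert force[2] == pytest.approx(expected, rel=1e-12)
        assert np.allclose(p, p[0])

    def test_symmetric_joint_has_no_mediolateral_force(self):
        joint = build_joint(JointParams(wiberg_ratio=0.5, mesh_resolution=2000))
        params = ContactParams(friction_mu=0.0)
        c = joint.patella_pose.apply(joint.patella_center[None])[0]
        n = np.array([0.0, c[1], c[2]])
        n /= np.linalg.norm(n)
        approach = RigidTransform(translation=-0.3 * n)
        force, _, _ = contact_wrench(joint, params, extra=approach)
        assert abs(force[0]) < 1e-6
        assert np.linalg.norm(force) > 1.0  # but contact is engaged

    def test_zero_area_faces_rejected(self, flat_patch):
        cent, areas = flat_patch
        bad = areas.copy()
        bad[0] = 0.0
        with pytest.raises(ContactError):
            ContactSystem(FlatFoundation(), cent, bad, np.zeros(3), [],
                          1.0)


class TestSeriesSpringOracle:
    @pytest.mark.parametrize("K,dL", [
        (100.0, 0.5), (10.0, 1.0), (513.0, 0.3), (2.0, 2.5), (1350.0, 0.05),
        (50.0, 1.5),
    ])
    def test_single_spring_against_flat_foundation(self, flat_patch, K, dL):
        """1-DOF pull-in matches F = K*k_c/(K+k_c)*dL to 1e-6 relative."""
        cent, areas = flat_patch
        params = ContactParams(friction_mu=0.0)
        k_c = params.foundation_stiffness * areas.sum()
        spring = SpringHandle("s", np.array([0.0, 0.0, -50.0]),
                              np.array([0.0, 0.0, 0.0]), K, 50.0 - dL,
                              delta_L=dL)
        system = ContactSystem(FlatFoundation(), cent, areas, np.zeros(3),
                               [spring], params.foundation_stiffness, mu=0.0)
        _, extra, converged, _ = solve_system(
            system, params, np.eye(3), [0.25, 0.5, 0.75, 1.0])
        assert converged
        _, _, _, tensions = system.wrench(extra, 1.0)
        expected = K * k_c / (K + k_c) * dL
        assert tensions["s"] == pytest.approx(expected, rel=1e-6)

    def test_stiffer_spring_does_not_reduce_contact(self, flat_patch):
        cent, areas = flat_patch
        params = ContactParams(friction_mu=0.0)
        forces, depths = [], []
        for K in (25.0, 50.0, 100.0, 200.0):
            spring = SpringHandle("s", np.array([0.0, 0.0, -50.0]),
                                  np.array([0.0, 0.0, 0.0]), K, 50.0 - 0.4,
                                  delta_L=0.4)
            system = ContactSystem(FlatFoundation(), cent, areas, np.zeros(3),
                                   [spring], params.foundation_stiffness, mu=0.0)
            _, extra, converged, _ = solve_system(system, params, np.eye(3), [1.0])
            assert converged
            _, _, p, _ = system.wrench(extra, 1.0)
            forces.append((p * areas).sum())
            depths.append(-extra.translation[2])
        assert np.all(np.diff(forces) > 0)
        assert np.all(np.diff(depths) > 0)


class TestBaseline:
    def test_zero_approach_gives_zero_field(self, default_joint):
        params = ContactParams(approach_depth=0.0)
        sol = baseline_state(pose_at_flexion(default_joint, 0.0), params)
        assert sol.pressure_field.pressure.max() == 0.0

    def test_default_approach_engages_contact(self, default_runner):
        base = default_runner.baseline(0.0)
        assert base.converged
        assert base.pressure_field.pressure.max() > 0.5

    def test_complementarity(self, default_runner):
        """Faces carry pressure only where they interpenetrate."""
        base = default_runner.baseline(0.0)
        pts = base.extra.apply(default_runner.posed(0.0).patella_pose.apply(
            base.pressure_field.mesh.face_centroids))
        depth, _ = default_runner.joint.femoral_surface.penetration(pts)
        p = base.pressure_field.pressure
        assert np.all(p[depth <= 0.0] == 0.0)
        assert np.all(p >= 0.0)
        k = default_runner.contact.foundation_stiffness
        assert np.allclose(p, np.maximum(depth, 0.0) * k, atol=1e-12)

    def test_residuals_below_tolerance(self, default_runner):
        for angle in (0.0, 30.0, 90.0):
            base = default_runner.baseline(angle)
            fn, tn = base.residual_wrench
            assert base.converged
            assert fn < default_runner.contact.tol_force
            assert tn < default_runner.contact.tol_torque


class TestSolveEquilibrium:
    def test_tethers_only_reproduces_baseline(self, default_runner):
        from pfjsim.ligaments import build_tethers
        ja = default_runner.posed(0.0)
        base = default_runner.baseline(0.0)
        tethers = build_tethers(ja, default_runner.tissues,
                                extra_pose=base.extra)
        sol = solve_equilibrium(ja, tethers, default_runner.contact,
                                baseline=base)
        assert np.allclose(sol.extra.translation, base.extra.translation,
                           atol=1e-9)
        assert np.allclose(sol.pressure_field.pressure,
                           base.pressure_field.pressure, atol=1e-12)

    def test_reference_angle_has_zero_pretension(self, default_runner):
        ja = default_runner.posed(40.0)
        base = baseline_state(ja, default_runner.contact)
        els = build_elements(ReconstructionSpec("mqtfl", "semitendinosus"), ja,
                             tissues=default_runner.tissues,
                             profiles=default_runner.profiles,
                             cross_section=default_runner.cross_section,
                             extra_pose=base.extra)
        sol = solve_equilibrium(ja, els, default_runner.contact, baseline=base)
        assert sol.element_forces["mqtfl"] == pytest.approx(0.0, abs=1e-9)
        rel = relative_pressure(sol.pressure_field, base.pressure_field)
        assert rel.pressure.max() == pytest.approx(0.0, abs=1e-9)

    def test_frame_invariance(self, default_runner):
        """A rigid world transform of the whole joint leaves pressures and
        element forces unchanged."""
        spec = ReconstructionSpec("static_anatomic", "gracilis")
        res0, art0 = default_runner.run(spec, 0.0, return_artifacts=True)
        T = rotation_about_x(17.0).compose(
            RigidTransform(translation=np.array([5.0, -3.0, 11.0])))
        moved = default_runner.posed(0.0).transformed(T)
        base = baseline_state(moved, default_runner.contact)
        els = build_elements(spec, moved, tissues=default_runner.tissues,
                             profiles=default_runner.profiles,
                             cross_section=default_runner.cross_section,
                             extra_pose=base.extra)
        sol = solve_equilibrium(moved, els, default_runner.contact,
                                baseline=base)
        assert sol.pressure_field.pressure.max() == pytest.approx(
            art0["solution"].pressure_field.pressure.max(), rel=1e-9)
        for name, f in art0["solution"].element_forces.items():
            assert sol.element_forces[name] == pytest.approx(f, abs=1e-7)

    def test_friction_is_a_small_effect(self, default_runner):
        """At mu = 0.02 the relative-pressure peak differs from the
        frictionless solve by under 5 percent."""
        from pfjsim.config import Config
        from pfjsim.study import _CaseRunner
        cfg = Config()
        cfg.contact.friction_mu = 0.0
        frictionless = _CaseRunner(cfg)
        spec = ReconstructionSpec("static_anatomic", "semitendinosus")
        with_mu = default_runner.run(spec, 0.0).max_relative_pressure
        without = frictionless.run(spec, 0.0).max_relative_pressure
        assert abs(with_mu - without) / without < 0.05


class TestPressureFields:
    def _field(self, values, angle=0.0):
        from pfjsim.geometry import TriMesh
        n = len(values)
        verts = np.zeros((n + 2, 3))
        verts[:, 0] = np.arange(n + 2)
        faces = np.array([[i, i + 1, i + 2] for i in range(n)])
        return PressureField(TriMesh(verts, faces), np.asarray(values, float),
                             np.ones(n), angle)

    def test_relative_pressure_of_identical_fields_is_zero(self):
        f = self._field([1.0, 2.0, 0.5])
        rel = relative_pressure(f, f)
        assert np.all(rel.pressure == 0.0)

    def test_zero_baseline_passes_through(self):
        f = self._field([1.0, 2.0, 0.5])
        z = self._field([0.0, 0.0, 0.0])
        assert np.array_equal(relative_pressure(f, z).pressure, f.pressure)

    def test_relative_max_bounded_by_after_max(self):
        a = self._field([1.0, 3.0, 0.5])
        b = self._field([0.2, 1.0, 0.9])
        assert max_pressure(relative_pressure(a, b)) <= max_pressure(a)

    def test_mismatched_fields_rejected(self):
        with pytest.raises(ContactError):
            relative_pressure(self._field([1.0, 2.0]), self._field([1.0]))
        with pytest.raises(ContactError):
            relative_pressure(self._field([1.0], angle=0.0),
                              self._field([1.0], angle=30.0))

    def test_max_pressure_invariant_under_reordering(self):
        f = self._field([0.1, 2.0, 1.4])
        g = self._field([2.0, 1.4, 0.1])
        assert max_pressure(f) == max_pressure(g)

    def test_empty_field_rejected(self):
        from pfjsim.geometry import TriMesh
        empty = PressureField(TriMesh(np.zeros((0, 3)), np.zeros((0, 3), int)),
                              np.zeros(0), np.zeros(0), 0.0)
        with pytest.raises(ContactError):
            max_pressure(empty)
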