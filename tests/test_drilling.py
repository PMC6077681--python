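"""Portal placement, MTA search, tunnel drilling and breakage classification."""

import numpy as np
import pytest
from scipy.optimize import brentq

from kneedrill.drilling import (DrillError, _cylinder_clearance, _obstacle_points,
                                classify_breakage, drill_axis, drill_tunnel,
                                find_mta, portal_at_angle, portal_line,
                                transverse_angle)
from kneedrill.kinematics import flex_knee
from kneedrill.mesh import Frame, SurfaceMesh
from kneedrill.synthetic import KneeParams, _box, _ellipsoid, _mesh_from_implicit, _subtract, generate_knee

R_SPHERE = 30.0
PITCH = 0.75


def _thick_sphere(defect=None) -> SurfaceMesh:
    f = _ellipsoid((0.0, 0.0, 0.0), (R_SPHERE,) * 3)
    if defect is not None:
        f = _subtract(f, defect)
    return _mesh_from_implicit(f, (-R_SPHERE,) * 3, (R_SPHERE,) * 3, PITCH)


@pytest.fixture(scope="module")
def intact_sphere():
    return _thick_sphere()


@pytest.fixture(scope="module")
def entrance_defect_sphere():
    """Wedge removing the aperture rim on one side: generators there first
    meet bone only beyond the oblique-aperture allowance."""
    cut = _box((2.5, -40.0, -40.0), (40.0, 40.0, -R_SPHERE + 8.5))
    return _thick_sphere(cut)


@pytest.fixture(scope="module")
def slot_defect_sphere():
    """3-mm transverse slot crossing the wall at t ~ 15 mm from the aperture."""
    cut = _box((2.5, -40.0, -R_SPHERE + 13.5), (40.0, 40.0, -R_SPHERE + 16.5))
    return _thick_sphere(cut)


F_SPHERE = np.array([0.0, 0.0, -R_SPHERE])
AXIS_UP = np.array([0.0, 0.0, 1.0])


@pytest.fixture(scope="session")
def posed120(knee, knee_landmarks):
    return flex_knee(knee, knee_landmarks, 120.0)


@pytest.fixture(scope="session")
def mta120(posed120, knee_landmarks):
    return find_mta(posed120, knee_landmarks.femoral_fp)


class TestPortalLine:
    def test_height_above_plateau(self, posed120):
        line = portal_line(posed120)
        f = posed120.plateau_frame_posed
        for s in (-30.0, 0.0, 25.0):
            h = float((line.point(s) - f.origin) @ f.w)
            assert h == pytest.approx(10.0, abs=1e-6)

    def test_direction_perpendicular_to_normal(self, posed120):
        line = portal_line(posed120)
        f = posed120.plateau_frame_posed
        assert abs(float(line.medial_dir @ f.w)) < 1e-9

    def test_lines_related_by_tea_rotation(self, knee, knee_landmarks):
        """Portal lines at flexion 100 and 130 are the same line carried by
        the 30-degree TEA rotation."""
        from kneedrill.mesh import rotate_about_axis

        p100 = portal_line(flex_knee(knee, knee_landmarks, 100.0))
        p130 = portal_line(flex_knee(knee, knee_landmarks, 130.0))
        tea = knee_landmarks.tea
        for s in (-20.0, 0.0, 20.0):
            carried = rotate_about_axis(p100.point(s).reshape(1, 3),
                                        tea.origin, tea.direction, -30.0)[0]
            np.testing.assert_allclose(carried, p130.point(s), atol=1e-9)


class TestTransverseAngle:
    def frame(self):
        return Frame((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1))

    def test_portal_directly_anterior_is_zero(self):
        f = self.frame()
        assert transverse_angle((0, 40, 5), (0, 0, 0), f) == pytest.approx(0.0, abs=1e-9)

    def test_pure_ml_is_ninety(self):
        f = self.frame()
        assert transverse_angle((-30, 0, 5), (0, 0, 0), f) == pytest.approx(90.0, abs=1e-9)

    def test_degenerate_perpendicular_drill_rejected(self):
        f = self.frame()
        with pytest.raises(DrillError):
            transverse_angle((0, 0, 10), (0, 0, 0), f)

    def test_strictly_increasing_medially(self, posed120, knee_landmarks):
        """50 portal positions moving medially: angles strictly increase."""
        from kneedrill.drilling import _sagittal_s

        line = portal_line(posed120)
        F = knee_landmarks.femoral_fp
        f = posed120.plateau_frame_posed
        s0 = _sagittal_s(line, F, f)
        ss = np.linspace(s0 + 1.0, s0 + 80.0, 50)
        angles = [transverse_angle(line.point(s), F, f) for s in ss]
        assert np.all(np.diff(angles) > 0)


class TestFindMta:
    def test_clearance_at_solution_within_band(self, posed120, mta120, knee, knee_landmarks):
        """At the MTA the cylinder just clears the medial condyle: clearance
        in [0, 0.1] mm; half a degree more medial makes contact."""
        assert mta120.constraint_active
        assert 0.0 <= mta120.clearance_mm <= 0.1
        line = portal_line(posed120)
        F = knee_landmarks.femoral_fp
        f = posed120.plateau_frame_posed
        obstacle = _obstacle_points(knee.femur)

        def angle_of(s):
            return transverse_angle(line.point(s), F, f)

        target = mta120.transverse_angle_deg + 0.5
        s_past = brentq(lambda s: angle_of(s) - target, mta120.s, mta120.s + 10.0)
        clear_past = _cylinder_clearance(knee.femur, obstacle, line.point(s_past), F, 4.0)
        assert clear_past < 0.0

    def test_unconstrained_when_no_medial_condyle(self, posed120, knee_landmarks):
        """Obstacle absent (medial condyle removed): the MTA runs to the
        medial end of the portal line and reports the constraint inactive."""
        far = np.array([[-1000.0, 0.0, 0.0]])
        sol = find_mta(posed120, knee_landmarks.femoral_fp, obstacle=far)
        assert not sol.constraint_active

    def test_widening_notch_does_not_decrease_mta(self):
        p = KneeParams(voxel_pitch=1.25)
        wide = KneeParams(voxel_pitch=1.25, notch_width=p.notch_width + 4.0)
        angles = []
        for params in (p, wide):
            from kneedrill.landmarks import compute_landmarks

            model = generate_knee(params, seed=6)
            lm = compute_landmarks(model.femur, model.tibia)
            posed = flex_knee(model, lm, 120.0)
            angles.append(find_mta(posed, lm.femoral_fp).transverse_angle_deg)
        assert angles[1] >= angles[0] - 0.1


class TestPortalAtAngle:
    def test_fixed_point_at_mta(self, posed120, mta120, knee_landmarks):
        sol = portal_at_angle(posed120, knee_landmarks.femoral_fp,
                              mta120.transverse_angle_deg, mta120)
        assert sol.transverse_angle_deg == pytest.approx(
            mta120.transverse_angle_deg, abs=0.01)
        assert sol.s == pytest.approx(mta120.s, abs=0.5)

    def test_offsets_hit_targets_and_order(self, posed120, mta120, knee_landmarks):
        F = knee_landmarks.femoral_fp
        m10 = portal_at_angle(posed120, F, mta120.transverse_angle_deg - 10.0, mta120)
        m20 = portal_at_angle(posed120, F, mta120.transverse_angle_deg - 20.0, mta120)
        assert m10.transverse_angle_deg == pytest.approx(
            mta120.transverse_angle_deg - 10.0, abs=0.01)
        assert m20.transverse_angle_deg == pytest.approx(
            mta120.transverse_angle_deg - 20.0, abs=0.01)
        assert m20.s < m10.s < mta120.s  # increasingly medial

    def test_target_above_mta_rejected(self, posed120, mta120, knee_landmarks):
        with pytest.raises(DrillError):
            portal_at_angle(posed120, knee_landmarks.femoral_fp,
                            mta120.transverse_angle_deg + 5.0, mta120)


class TestDrillAxis:
    def test_sphere_diameter_oracle(self, intact_sphere):
        """Axis through the centre of a 20-mm-radius sphere: length 40 mm."""
        from conftest import SPHERE_RADIUS

        f = _ellipsoid((0, 0, 0), (SPHERE_RADIUS,) * 3)
        mesh = _mesh_from_implicit(f, (-SPHERE_RADIUS,) * 3, (SPHERE_RADIUS,) * 3, PITCH)
        F = np.array([0.0, 0.0, -SPHERE_RADIUS])
        tun = drill_axis(mesh, F - 10 * AXIS_UP, F)
        assert tun.length_mm == pytest.approx(2 * SPHERE_RADIUS, abs=0.5)
        assert not tun.short
        np.testing.assert_allclose(tun.exit_point,
                                   F + tun.length_mm * AXIS_UP, atol=1e-9)

    def test_tangent_ray_gives_degenerate_short_tunnel(self, intact_sphere):
        F = np.array([0.0, 0.0, -R_SPHERE])
        portal = F - 10 * np.array([1.0, 0.0, 0.0])
        tun = drill_axis(intact_sphere, portal, F)
        assert tun.length_mm < 10.0
        assert tun.short

    def test_length_equals_exit_distance(self, posed120, mta120, knee_landmarks):
        tun = drill_tunnel(posed120, mta120, knee_landmarks.femoral_fp)
        assert tun.length_mm == pytest.approx(
            np.linalg.norm(tun.exit_point - tun.axis.origin), abs=1e-6)
        assert tun.short == (tun.length_mm < 25.0)


class TestClassifyBreakage:
    def test_intact_wall_none(self, intact_sphere):
        cls = classify_breakage(intact_sphere, F_SPHERE, AXIS_UP, 2 * R_SPHERE)
        assert cls == "none"

    def test_rim_wedge_defect_entrance(self, entrance_defect_sphere):
        cls = classify_breakage(entrance_defect_sphere, F_SPHERE, AXIS_UP, 2 * R_SPHERE)
        assert cls == "entrance"

    def test_transverse_slot_mid_tunnel(self, slot_defect_sphere):
        cls = classify_breakage(slot_defect_sphere, F_SPHERE, AXIS_UP, 2 * R_SPHERE)
        assert cls == "mid_tunnel"

    @pytest.mark.parametrize("fixture,expected", [
        ("intact_sphere", "none"),
        ("entrance_defect_sphere", "entrance"),
        ("slot_defect_sphere", "mid_tunnel"),
    ])
    def test_stable_under_halved_sampling(self, request, fixture, expected):
        mesh = request.getfixturevalue(fixture)
        cls = classify_breakage(mesh, F_SPHERE, AXIS_UP, 2 * R_SPHERE,
                                step=0.125, n_theta=144)
        assert cls == expected

    def test_classes_mutually_exclusive_on_grid(self, grid_results):
        ok = grid_results[grid_results["status"] == "ok"]
        assert set(ok["breakage"]) <= {"none", "entrance", "mid_tunnel"}


def test_mta_heuristic_obstacle_without_labels(knee, knee_landmarks, posed120):
    """An unlabelled femur falls back to the medial-quarter heuristic for the
    cartilage stand-in and still produces a bounded MTA."""
    from kneedrill.kinematics import PosedModel

    bare = SurfaceMesh(knee.femur.vertices, knee.femur.faces, validate=False)
    posed = PosedModel(
        base=type(knee)(femur=bare, tibia=knee.tibia, side=knee.side,
                        params=knee.params, subject_id="bare"),
        landmarks=posed120.landmarks, flexion_deg=posed120.flexion_deg,
        tibia_posed=posed120.tibia_posed,
        plateau_frame_posed=posed120.plateau_frame_posed,
        tibial_fp_posed=posed120.tibial_fp_posed,
        rotation=posed120.rotation, pivot=posed120.pivot)
    sol = find_mta(posed, knee_landmarks.femoral_fp)
    assert 0.0 < sol.transverse_angle_deg < 90.0
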