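"""Placement rules: entry point, depth/rotation solver, equivariance."""

import dataclasses
import math

import numpy as np
import pytest

from femfit.nails import build_nail_mesh, make_generic_spec
from femfit.placement import (PlacementOptions, entry_point, place_nail,
                              solve_depth_rotation)
from femfit.synthetic import (PopulationSpec, build_femur, cylinder_canal,
                              sample_population)
from femfit.transforms import RigidTransform, rotation_about_axis


@pytest.fixture(scope="module")
def straight_femur():
    """Straight-shaft synthetic femur with a 130° neck."""
    p = sample_population(PopulationSpec(n=1, seed=3))[0]
    p = dataclasses.replace(p, anterior_bow_radius=np.inf,
                            neck_shaft_angle=130.0)
    return build_femur(p)


@pytest.fixture(scope="module")
def matched_nail():
    """Straight nail whose head-element angle equals the femur's neck-shaft
    angle — constructed so an exact placement solution exists."""
    return build_nail_mesh(make_generic_spec(170.0, 10.0, ccd_angle=130.0,
                                             bend_station=90.0))


class TestEntryPoint:
    def test_anterior_third_rule_on_cylinder(self):
        canal = cylinder_canal(6.0, 120.0)
        e = canal.frame.to_frame(entry_point(canal))
        # trochanteric AP extent is [-6, 6]; anterior-third boundary at +r/3
        assert e[1] == pytest.approx(-6.0 + (2.0 / 3.0) * 12.0, abs=0.1)
        # AP view position coincides with the apex
        assert abs(e[0]) < 0.5
        assert abs(e[2]) < 0.5

    def test_translation_equivariance(self, straight_femur):
        t = np.array([12.0, -7.0, 4.0])
        rt = RigidTransform(np.eye(3), t)
        e0 = entry_point(straight_femur)
        e1 = entry_point(straight_femur.transformed(rt))
        assert np.abs(e1 - (e0 + t)).max() < 1e-9

    def test_entry_lies_on_the_surface(self, straight_femur):
        e = entry_point(straight_femur)
        d = straight_femur.endosteal_mesh.signed_distance(e[None, :])[0]
        assert abs(d) < 0.05


class TestPlaceNail:
    def test_matched_construction_converges(self, straight_femur,
                                            matched_nail):
        res = place_nail(straight_femur, matched_nail)
        assert res.converged
        assert res.head_center_miss < 0.5

    def test_mismatched_ccd_reports_nonconvergence(self, straight_femur):
        bad = build_nail_mesh(make_generic_spec(170.0, 10.0, ccd_angle=160.0,
                                                bend_station=90.0))
        res = place_nail(straight_femur, bad)   # 30° off the neck axis
        assert not res.converged
        assert res.head_center_miss > 5.0

    def test_rigid_equivariance(self, straight_femur, matched_nail):
        base = place_nail(straight_femur, matched_nail)
        rng = np.random.default_rng(17)
        for _ in range(3):
            rt = RigidTransform.random(rng)
            moved = place_nail(straight_femur.transformed(rt), matched_nail)
            expect = rt.compose(base.transform)
            assert np.abs(moved.transform.matrix - expect.matrix).max() < 1e-6
            assert moved.tip_offset == pytest.approx(base.tip_offset,
                                                     abs=1e-6)

    def test_placement_is_deterministic(self, straight_femur, matched_nail):
        a = place_nail(straight_femur, matched_nail)
        b = place_nail(straight_femur, matched_nail)
        assert np.array_equal(a.transform.matrix, b.transform.matrix)

    def test_transform_is_rigid(self, straight_femur, matched_nail):
        res = place_nail(straight_femur, matched_nail)
        R = res.transform.rotation
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestSolver:
    def brute_force(self, femur, nail, entry, opts, depths, rots):
        """Independent objective: build the full rigid transform per grid
        node and measure the head-axis miss from transformed geometry."""
        from femfit.placement import _insertion_axes
        z_dir, base_rot = _insertion_axes(femur, entry, opts,
                                          nail.total_length)
        head = femur.landmarks.head_center
        best = (np.inf, None, None)
        for d in depths:
            for r in rots:
                R = base_rot @ rotation_about_axis(np.array([0.0, 0.0, 1.0]),
                                                   math.radians(r))
                t = entry + d * z_dir
                a = R @ nail.head_axis_point + t
                u = R @ nail.head_axis_dir
                w = head - a
                miss = np.linalg.norm(w - (w @ u) * u)
                if miss < best[0] - 1e-12:
                    best = (miss, d, r)
        return best

    def test_solver_matches_finer_brute_force(self, straight_femur,
                                              matched_nail):
        entry = entry_point(straight_femur)
        opts = PlacementOptions()
        d, r, miss = solve_depth_rotation(straight_femur, matched_nail,
                                          entry, opts)
        bmiss, bd, br = self.brute_force(
            straight_femur, matched_nail, entry, opts,
            np.arange(d - 1.0, d + 1.0, 0.1), np.arange(r - 1.0, r + 1.0, 0.1))
        assert d == pytest.approx(bd, abs=0.1)
        assert r == pytest.approx(br, abs=0.1)
        assert miss <= bmiss + 1e-6

    def test_rotation_tie_breaks_toward_zero(self):
        """Head center on the insertion axis makes every rotation equally
        good; the documented tie-break returns the smallest rotation."""
        from femfit.placement import canal_corridor_direction
        canal = cylinder_canal(6.0, 160.0)
        lm = canal.landmarks
        e = entry_point(canal)
        nail = build_nail_mesh(make_generic_spec(100.0, 10.0,
                                                 ccd_angle=130.0,
                                                 bend_station=60.0))
        z_dir = canal_corridor_direction(canal, e, nail.total_length)
        lm.head_center = e - 30.0 * z_dir     # on the insertion axis
        d, r, miss = solve_depth_rotation(canal, nail, e)
        assert r == 0.0

    def test_empty_depth_range_is_an_error(self, straight_femur,
                                           matched_nail):
        from femfit.errors import GeometryError
        entry = entry_point(straight_femur)
        with pytest.raises(GeometryError, match="depth range"):
            solve_depth_rotation(straight_femur, matched_nail, entry,
                                 PlacementOptions(depth_range=(10.0, 10.0)))

    def test_tip_reproducible_to_hundredth_mm(self, straight_femur,
                                              matched_nail):
        res = place_nail(straight_femur, matched_nail)
        tip = res.transform.apply(np.zeros(3))
        res2 = place_nail(straight_femur, matched_nail)
        tip2 = res2.transform.apply(np.zeros(3))
        assert np.abs(tip - tip2).max() < 0.01
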