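"""Fitness metrics A–H: analytic oracles, classification, serialization."""

import numpy as np
import pytest

from femfit.errors import GeometryError
from femfit.femur import canonical_frame
from femfit.metrics import (FitnessOptions, FitnessReport, ImpingementPatch,
                            classify_region, classify_side, compute_fitness,
                            extract_patches, max_gap_middle,
                            penetration_field, protrusion_length,
                            region_boundaries)
from femfit.nails import build_nail_mesh, make_generic_spec
from femfit.placement import place_nail
from femfit.synthetic import (PopulationSpec, build_femur, sample_population)
from femfit.transforms import RigidTransform

from conftest import manual_placement


class TestPenetrationField:
    def test_concentric_annulus_depth_is_minus_one(self, concentric_field):
        field, _ = concentric_field
        d = field.depth[field.in_bone]
        assert np.abs(d + 1.0).max() < 0.05

    def test_offset_cylinder_max_depth_is_one(self, offset_field):
        field, _ = offset_field
        assert field.depth.max() == pytest.approx(1.0, abs=0.05)

    def test_doubling_density_changes_max_depth_little(self, canal6, nail80):
        pl = manual_placement([2.0, 0.0, 20.0])
        lo = penetration_field(canal6, nail80, pl, FitnessOptions(density=2.0))
        hi = penetration_field(canal6, nail80, pl, FitnessOptions(density=4.0))
        assert abs(lo.depth.max() - hi.depth.max()) < 0.05

    def test_unconverged_placement_needs_explicit_optin(self, canal6, nail80):
        pl = manual_placement([0.0, 0.0, 20.0])
        pl.converged = False
        with pytest.raises(GeometryError, match="converge"):
            penetration_field(canal6, nail80, pl)
        field = penetration_field(canal6, nail80, pl,
                                  FitnessOptions(allow_unconverged=True))
        assert len(field.depth)

    def test_sign_agrees_with_ray_parity_containment(self, offset_field,
                                                     canal6):
        field, _ = offset_field
        rng = np.random.default_rng(1)
        idx = rng.choice(len(field.points), size=300, replace=False)
        inside = canal6.endosteal_mesh.contains(field.points[idx])
        sd = field.depth[idx]
        clear = np.abs(sd) > 1e-6
        assert ((sd < 0) == inside)[clear].all()


class TestPatches:
    def test_concentric_case_has_no_patches(self, concentric_field):
        field, _ = concentric_field
        assert extract_patches(field) == []

    def test_offset_case_has_one_patch_with_unit_thickness(self,
                                                           offset_field):
        field, _ = offset_field
        patches = extract_patches(field)
        assert len(patches) == 1
        assert patches[0].max_thickness == pytest.approx(1.0, abs=0.05)

    def test_two_disjoint_zones_give_two_patches(self, offset_field):
        """Synthetic field with two over-threshold clusters 30 mm apart."""
        field, _ = offset_field
        import copy
        f = copy.copy(field)
        f.depth = np.full_like(field.depth, -1.0)
        near = (np.abs(field.station - 20.0) < 3.0)
        far = (np.abs(field.station - 50.0) < 3.0)
        lateral = field.points[:, 0] > 6.5  # one side of the offset nail
        f.depth[near & lateral] = 0.5
        f.depth[far & lateral] = 0.5
        patches = extract_patches(f, threshold=0.1, linkage_radius=5.0)
        assert len(patches) == 2

    def test_raising_threshold_cannot_create_incidence(self, offset_field):
        field, _ = offset_field
        assert len(extract_patches(field, threshold=0.1)) >= 1
        assert extract_patches(field, threshold=2.0) == []


def make_patch(centroid, axis_point, station):
    return ImpingementPatch(member_idx=np.arange(3), max_thickness=1.0,
                            axial_length=5.0,
                            centroid=np.asarray(centroid, float),
                            station_centroid=station,
                            axis_point=np.asarray(axis_point, float),
                            dist_to_gt_apex=1.0)


class TestClassification:
    BOUNDS = {"proximal_end": 100.0, "distal_start": 150.0,
              "entry_station": 0.0}

    @pytest.mark.parametrize("station, region", [
        (20.0, "proximal"), (100.0, "proximal"),   # boundary tie → proximal
        (120.0, "middle"), (150.0, "middle"),      # boundary tie → middle
        (160.0, "distal"),
    ])
    def test_region_by_station_with_proximal_tie_break(self, station, region):
        p = make_patch([0, 0, station], [0, 0, station], station)
        assert classify_region(p, self.BOUNDS) == region

    @pytest.mark.parametrize("offset, side", [
        ([0.0, 3.0, 0.0], "anterior"),
        ([0.0, -3.0, 0.0], "posterior"),
        ([3.0, 0.0, 0.0], "lateral"),
        ([-3.0, 0.0, 0.0], "medial"),
        ([3.0, 3.0, 0.0], "lateral"),      # 45° tie → mediolateral sector
        ([-2.0, -2.0, 0.0], "medial"),
    ])
    def test_side_sectors(self, canal6, offset, side):
        p = make_patch(np.array([0.0, 0.0, 50.0]) + offset, [0, 0, 50.0], 50.0)
        assert classify_side(p, canal6.frame) == side

    def test_centroid_on_axis_is_degenerate(self, canal6):
        p = make_patch([0, 0, 50.0], [0, 0, 50.0], 50.0)
        with pytest.raises(GeometryError):
            classify_side(p, canal6.frame)


class TestProtrusion:
    def test_direct_readout(self, canal6, nail80):
        pl = manual_placement([0.0, 0.0, -1.48])
        assert protrusion_length(nail80, pl, canal6.frame) == pytest.approx(
            1.48, abs=1e-9)

    def test_tip_below_plane_clamps_to_zero(self, canal6, nail80):
        pl = manual_placement([0.0, 0.0, 5.0])
        assert protrusion_length(nail80, pl, canal6.frame) == 0.0

    def test_common_translation_invariance(self, canal6, nail80):
        rt = RigidTransform(np.eye(3), np.array([4.0, -2.0, 9.0]))
        moved_femur = canal6.transformed(rt)
        pl = manual_placement(rt.apply(np.array([0.0, 0.0, -1.48])))
        assert protrusion_length(nail80, pl, moved_femur.frame
                                 ) == pytest.approx(1.48, abs=1e-9)


class TestAnteriorGap:
    def test_coaxial_annulus_gap_is_one(self, canal6, nail80,
                                        concentric_field):
        field, pl = concentric_field
        bounds = region_boundaries(nail80.spec, pl,
                                   FitnessOptions(proximal_margin=10.0))
        gap = max_gap_middle(canal6, field, bounds)
        assert gap.max_anterior_gap == pytest.approx(1.0, abs=0.05)
        assert gap.max_clearance == pytest.approx(1.0, abs=0.05)

    def test_anterior_translation_shrinks_gap_linearly(self, canal6, nail80):
        pl = manual_placement([0.0, 0.5, 20.0])
        field = penetration_field(canal6, nail80, pl)
        bounds = region_boundaries(nail80.spec, pl, FitnessOptions())
        gap = max_gap_middle(canal6, field, bounds)
        assert gap.max_anterior_gap == pytest.approx(0.5, abs=0.05)

    def test_bowed_canal_gap_peaks_inside_the_middle_region(self):
        p = sample_population(PopulationSpec(n=1, seed=3))[0]
        import dataclasses
        p = dataclasses.replace(p, anterior_bow_radius=800.0)
        fem = build_femur(p)
        nail = build_nail_mesh(make_generic_spec(170.0, 10.0,
                                                 ccd_angle=130.0,
                                                 bend_station=90.0))
        res = place_nail(fem, nail)
        rep_opts = FitnessOptions(density=2.0, allow_unconverged=True)
        field = penetration_field(fem, nail, res, rep_opts)
        bounds = region_boundaries(nail.spec, res, rep_opts)
        gap = max_gap_middle(fem, field, bounds)
        assert gap.max_anterior_gap is not None
        assert (bounds["proximal_end"] < gap.station_at_max
                < bounds["distal_start"])


class TestFitnessReport:
    def test_concentric_composition(self, canal6, nail80, concentric_field):
        field, pl = concentric_field
        rep = compute_fitness(canal6, nail80, pl, field_=field)
        assert rep.impinged == {"proximal": False, "middle": False,
                                "distal": False}
        assert rep.A_max_thickness_proximal is None   # null, not 0
        assert rep.D_protrusion == 0.0
        assert rep.G_max_gap_middle == pytest.approx(1.0, abs=0.05)

    def test_offset_report_A_equals_patch_oracle(self, canal6, nail80,
                                                 offset_field):
        field, pl = offset_field
        rep = compute_fitness(canal6, nail80, pl, field_=field)
        patches = extract_patches(field, 0.1, 2.0)
        assert rep.A_max_thickness_proximal == max(
            p.max_thickness for p in patches)
        assert rep.impinged["proximal"]
        assert rep.side["proximal"] == "lateral"

    def test_report_json_roundtrip(self, canal6, nail80, offset_field):
        field, pl = offset_field
        rep = compute_fitness(canal6, nail80, pl, field_=field)
        back = FitnessReport.from_json(rep.to_json())
        assert back.to_dict() == rep.to_dict()
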