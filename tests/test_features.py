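"""Ring geometry, region statistics, the 108-feature schema, CAD filtering."""

import numpy as np
import pytest

from threecb import (
    extract_feature_vector,
    calcification_cluster_hull,
    filter_cad_proposals,
    make_outer_rings,
    region_stats,
)
from threecb.decomposition import LWPMaps
from threecb.exceptions import InputError
from threecb.features import FEATURE_NAMES, REGIONS, STATISTICS, pathology_label
from threecb.phantom_sim import CadProposal


def _disk(shape, center, radius_px):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius_px


def _lwp_from(values):
    arr = np.asarray(values, dtype=float)
    return LWPMaps(lipid=arr, water=arr * 0.5, protein=arr * 0.25,
                   valid_mask=np.ones_like(arr, bool),
                   negativity_fraction=0.0)


class TestOuterRings:
    def test_disk_ring_areas_match_analytic_annuli(self):
        spacing = 0.1  # mm
        shape = (261, 261)
        lesion = _disk(shape, (130, 130), 5.0 / spacing)
        regions = make_outer_rings(lesion, np.ones(shape, bool), spacing)
        for k, (r1, r2) in enumerate([(5, 7), (7, 9), (9, 11)]):
            analytic = np.pi * (r2**2 - r1**2)  # mm^2
            measured = regions.ring_masks[k].sum() * spacing**2
            assert measured == pytest.approx(analytic, rel=0.05)

    def test_regions_pairwise_disjoint_and_clipped(self, small_phantom):
        p = small_phantom
        lesion = p.lesions[0].mask
        regions = make_outer_rings(lesion, p.breast_mask, p.pixel_spacing)
        masks = [regions.lesion_mask, *regions.ring_masks]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (masks[i] & masks[j]).any()
        for ring in regions.ring_masks:
            assert np.all(p.breast_mask[ring])

    def test_translation_equivariance(self):
        shape = (120, 120)
        a = _disk(shape, (40, 40), 12)
        b = np.roll(np.roll(a, 15, axis=0), 10, axis=1)
        ra = make_outer_rings(a, np.ones(shape, bool), 0.25)
        rb = make_outer_rings(b, np.ones(shape, bool), 0.25)
        for k in range(3):
            shifted = np.roll(np.roll(ra.ring_masks[k], 15, axis=0), 10, axis=1)
            assert np.array_equal(shifted, rb.ring_masks[k])

    def test_lesion_covering_breast_flags_empty_rings(self):
        mask = np.ones((50, 50), bool)
        regions = make_outer_rings(mask, mask, 0.25)
        assert regions.empty_rings == (True, True, True)

    def test_input_validation(self):
        mask = np.zeros((10, 10), bool)
        with pytest.raises(InputError):
            make_outer_rings(mask, np.ones((10, 10), bool), 0.25)
        mask[5, 5] = True
        with pytest.raises(InputError):
            make_outer_rings(mask, np.ones((10, 10), bool), 1.5)

    def test_other_lesions_excluded_from_rings(self):
        shape = (100, 100)
        lesion = _disk(shape, (50, 40), 8)
        other = _disk(shape, (50, 62), 6)
        regions = make_outer_rings(lesion, np.ones(shape, bool), 0.25,
                                   exclude_masks=[other])
        for ring in regions.ring_masks:
            assert not (ring & other).any()


class TestRegionStats:
    def test_hand_computed_sample(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        rs = region_stats(vals, np.ones((2, 2), bool), vals.sum())
        assert rs.mean == pytest.approx(2.5)
        assert rs.median == pytest.approx(2.5)
        assert rs.sd == pytest.approx(1.2909944487, abs=1e-9)
        assert rs.total == pytest.approx(10.0)
        assert rs.min == 1.0 and rs.max == 4.0

    def test_constant_region_is_degenerate(self):
        vals = np.full((3, 3), 2.5)
        rs = region_stats(vals, np.ones((3, 3), bool), vals.sum())
        assert rs.mean == rs.median == rs.min == rs.max == 2.5
        assert rs.sd == 0.0 and rs.kurtosis == 0.0 and rs.skew == 0.0
        assert rs.degenerate
        assert rs.total == pytest.approx(2.5 * 9)

    def test_single_pixel_region(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        rs = region_stats(np.arange(9.0).reshape(3, 3), mask, 4.0)
        assert rs.sd == 0.0 and rs.degenerate and rs.n_pixels == 1

    def test_empty_region_flagged(self):
        rs = region_stats(np.ones((3, 3)), np.zeros((3, 3), bool), 0.0)
        assert rs.empty and np.isnan(rs.mean)

    def test_component_percentages_sum_to_100(self):
        mask = np.ones((2, 2), bool)
        sums = {"lipid": 2.0, "water": 3.0, "protein": 5.0}
        total = sum(sums.values())
        pcts = [
            region_stats(np.full((2, 2), s / 4.0), mask, total).percentage
            for s in sums.values()
        ]
        assert pcts == pytest.approx([20.0, 30.0, 50.0])
        assert sum(pcts) == pytest.approx(100.0, abs=1e-9)


class TestFeatureVector:
    def test_exactly_108_features_in_schema_order(self, small_phantom):
        p = small_phantom
        lesion = p.lesions[0].mask
        regions = make_outer_rings(lesion, p.breast_mask, p.pixel_spacing)
        lwp = LWPMaps(p.lipid_map, p.water_map, p.protein_map,
                      p.breast_mask, 0.0)
        rec = extract_feature_vector(lwp, regions, 0.5, 1, "P0")
        assert len(rec.features) == 108
        assert tuple(rec.features) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 3 * len(REGIONS) * len(STATISTICS)
        # component percentages are complementary in every nonempty region
        for region in REGIONS:
            total = sum(rec.features[f"{c}_{region}_percentage"]
                        for c in ("lipid", "water", "protein"))
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_zero_maps_give_zero_statistics(self):
        shape = (80, 80)
        lesion = _disk(shape, (40, 40), 10)
        regions = make_outer_rings(lesion, np.ones(shape, bool), 0.25)
        lwp = _lwp_from(np.zeros(shape))
        rec = extract_feature_vector(lwp, regions, 0.0, 0, "P0")
        assert rec.features["lipid_lesion_mean"] == 0.0
        assert rec.features["water_ring1_total"] == 0.0
        assert np.isnan(rec.features["protein_ring2_percentage"])

    def test_label_mapping(self):
        assert [pathology_label(p) for p in ("BN", "FA", "DCIS", "IDC")] == [0, 0, 1, 1]
        with pytest.raises(InputError):
            pathology_label("XX")


class TestCadFiltering:
    def _proposal(self, mask, prob=0.5):
        return CadProposal(mask=mask, kind="mass", probability=prob,
                           matched_lesion=None)

    def test_identical_proposal_included(self):
        shape = (60, 60)
        roi = _disk(shape, (30, 30), 8)
        out = filter_cad_proposals([self._proposal(roi.copy())], [roi])
        assert len(out) == 1 and out[0][1] == 0

    def test_disjoint_proposal_excluded(self):
        shape = (60, 60)
        roi = _disk(shape, (20, 20), 6)
        prop = self._proposal(_disk(shape, (45, 45), 6))
        assert filter_cad_proposals([prop], [roi]) == []

    def test_exact_quarter_overlap_is_inclusive(self):
        shape = (20, 40)
        prop_mask = np.zeros(shape, bool)
        prop_mask[0:4, 0:10] = True  # 40 pixels
        roi = np.zeros(shape, bool)
        roi[0:4, 0:10] = False
        roi[0:2, 0:5] = True  # intersection exactly 10 px = 25 %
        roi[10:14, 20:30] = True
        out = filter_cad_proposals([self._proposal(prop_mask)], [roi])
        assert len(out) == 1

    def test_best_match_prefers_larger_overlap_then_lower_index(self):
        shape = (30, 30)
        prop_mask = np.zeros(shape, bool)
        prop_mask[10:20, 10:20] = True  # 100 px
        roi_a = np.zeros(shape, bool)
        roi_a[10:20, 10:14] = True  # 40 px overlap
        roi_b = np.zeros(shape, bool)
        roi_b[10:20, 14:20] = True  # 60 px overlap
        out = filter_cad_proposals([self._proposal(prop_mask)], [roi_a, roi_b])
        assert out[0][1] == 1
        # symmetric overlaps tie-break to the lower index
        out = filter_cad_proposals([self._proposal(prop_mask)], [roi_b, roi_b])
        assert out[0][1] == 0


class TestCalcificationHull:
    def test_single_mask_hull(self):
        shape = (40, 40)
        blob = _disk(shape, (20, 20), 5)
        hull = calcification_cluster_hull([blob])
        assert np.all(hull[blob])

    def test_two_points_hull_contains_segment(self):
        shape = (40, 40)
        a = np.zeros(shape, bool); a[5, 5] = True
        b = np.zeros(shape, bool); b[30, 30] = True
        hull = calcification_cluster_hull([a, b])
        for t in np.linspace(0, 1, 11):
            y, x = int(round(5 + 25 * t)), int(round(5 + 25 * t))
            assert hull[y, x]

    def test_right_triangle_hull_area(self):
        """Shoelace area of a 30x40 right triangle is 600."""
        shape = (60, 60)
        masks = []
        for (y, x) in [(5, 5), (35, 5), (5, 45)]:
            m = np.zeros(shape, bool)
            m[y, x] = True
            masks.append(m)
        hull = calcification_cluster_hull(masks)
        perimeter = 30 + 40 + 50
        assert abs(hull.sum() - 600) <= 2 * perimeter

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            calcification_cluster_hull([])
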