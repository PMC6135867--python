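import numpy as np
import pytest

from mseval import (
    DetectionParams,
    count_detected,
    detection_metrics,
    joint_histogram,
    label_lesions,
    no_consensus_metrics,
    per_lesion_detection_rates,
)
from conftest import cube, random_blob_mask, vol_from_coords
from _oracles import brute_count_detected, flood_fill_components, lesion_sets

P0 = DetectionParams(min_volume_mm3=0.0)


def labeled(coords_or_vol, **params):
    v = coords_or_vol if hasattr(coords_or_vol, "occupancy") else vol_from_coords(coords_or_vol)
    return label_lesions(v, DetectionParams(min_volume_mm3=0.0, **params))


class TestLabeling:
    def test_edge_adjacent_voxels_join_under_18(self):
        lm = labeled([(0, 0, 0), (1, 1, 0)])
        assert lm.n_lesions == 1

    def test_corner_adjacent_voxels_split_under_18(self):
        lm = labeled([(0, 0, 0), (1, 1, 1)])
        assert lm.n_lesions == 2

    def test_connectivity_kernels_distinguished(self):
        # face pair: one component at any connectivity
        # edge pair: splits at 6, joins at 18 and 26
        # corner pair: splits at 6 and 18, joins at 26
        face, edge, corner = [(0, 0, 0), (1, 0, 0)], [(0, 0, 0), (1, 1, 0)], [(0, 0, 0), (1, 1, 1)]
        expect = {6: (1, 2, 2), 18: (1, 1, 2), 26: (1, 1, 1)}
        for conn, counts in expect.items():
            got = tuple(labeled(c, connectivity=conn).n_lesions
                        for c in (face, edge, corner))
            assert got == counts, f"connectivity {conn}"

    def test_size_filter_keeps_only_large_component(self):
        # a 2-voxel and a 4-voxel component at 1 mm iso, min 3 mm^3
        v = vol_from_coords([(0, 0, 0), (0, 0, 1),
                             (8, 8, 8), (8, 8, 9), (8, 8, 10), (8, 8, 11)])
        lm = label_lesions(v, DetectionParams(min_volume_mm3=3.0))
        assert lm.n_lesions == 1
        assert lm.lesion_volumes_mm3[0] == pytest.approx(4.0)

    def test_size_filter_boundary_inclusive_by_default(self):
        v = vol_from_coords([(0, 0, 0), (0, 0, 1), (0, 1, 0)])  # exactly 3 mm^3
        keep = label_lesions(v, DetectionParams(min_volume_mm3=3.0))
        drop = label_lesions(v, DetectionParams(min_volume_mm3=3.0, strict_size=True))
        assert keep.n_lesions == 1
        assert drop.n_lesions == 0

    def test_size_filter_uses_physical_volume(self):
        # one voxel at 2x2x2 mm spacing is 8 mm^3: survives the 3 mm^3 rule
        v = vol_from_coords([(3, 3, 3)], spacing=(2.0, 2.0, 2.0))
        assert label_lesions(v, DetectionParams(min_volume_mm3=3.0)).n_lesions == 1

    def test_labels_ordered_by_decreasing_volume(self):
        v = vol_from_coords([(0, 0, 0),
                             (5, 5, 5), (5, 5, 6), (5, 5, 7),
                             (10, 10, 10), (10, 10, 11)])
        lm = labeled(v)
        assert list(lm.lesion_volumes_mm3) == [3.0, 2.0, 1.0]
        assert lm.labels[5, 5, 5] == 1 and lm.labels[10, 10, 10] == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(10):
            v = random_blob_mask(rng, shape=(14, 14, 14))
            lm = labeled(v, connectivity=connectivity)
            got = {
                frozenset(map(tuple, np.argwhere(lm.labels == l)))
                for l in range(1, lm.n_lesions + 1)
            }
            want = set(flood_fill_components(v.occupancy, connectivity))
            assert got == want

    def test_empty_mask_zero_lesions(self):
        assert labeled([]).n_lesions == 0


class TestJointHistogram:
    def test_identical_single_lesion(self):
        lm = labeled(cube((2, 2, 2), 2))
        h = joint_histogram(lm, lm).counts
        assert h[1, 1] == 8
        assert h[0, 1] == h[1, 0] == 0

    def test_disjoint_lesions_have_no_cross_mass(self):
        la = labeled(cube((1, 1, 1), 2))
        lg = labeled(cube((8, 8, 8), 2))
        h = joint_histogram(la, lg).counts
        assert h[1:, 1:].sum() == 0

    def test_total_equals_grid_voxels(self, rng):
        for _ in range(5):
            la = labeled(random_blob_mask(rng, shape=(12, 12, 12)))
            lg = labeled(random_blob_mask(rng, shape=(12, 12, 12)))
            assert joint_histogram(la, lg).counts.sum() == 12 ** 3


class TestMatchingRules:
    def test_identical_lesion_is_detected(self):
        lm = labeled(cube((2, 2, 2), 3))
        tp, flags = count_detected(lm, lm, params=P0)
        assert tp == 1 and flags.tolist() == [True]

    def test_rule1_rejects_low_coverage(self):
        # 100-voxel reference bar, evaluated lesion covers 5 of it: 5% < alpha=10%
        g = vol_from_coords([(i, j, 0) for i in range(10) for j in range(10)],
                            shape=(12, 12, 4))
        a = vol_from_coords([(i, 0, 0) for i in range(5)], shape=(12, 12, 4))
        tp, _ = count_detected(labeled(g), labeled(a), params=P0)
        assert tp == 0

    def test_rule2_rejects_sprawling_component(self):
        # 20-voxel reference fully covered by a 200-voxel evaluated lesion:
        # coverage 100% but the contributor lies 90% outside (> beta=70%)
        g = vol_from_coords([(i, j, 0) for i in range(5) for j in range(4)],
                            shape=(20, 12, 4))
        a_coords = [(i, j, k) for i in range(10) for j in range(10) for k in range(2)]
        a = vol_from_coords(a_coords, shape=(20, 12, 4))
        assert len(a_coords) == 200
        tp, _ = count_detected(labeled(g), labeled(a), params=P0)
        assert tp == 0
        # the same overlap passes once beta tolerates it
        loose = DetectionParams(min_volume_mm3=0.0, beta_pct=95.0)
        tp, _ = count_detected(labeled(g), labeled(a), params=loose)
        assert tp == 1

    def test_gamma_limits_contributor_set(self):
        # 10-voxel reference bar: a tight lesion covers i=0..6 (7/9 of the
        # overlap mass), a sprawling one covers i=8..9 with a 50-voxel tail.
        # gamma=65%: the tight contributor alone reaches 77.8% of the
        # overlap, so the sprawler is never vetted by beta -> detected.
        g = vol_from_coords([(i, 0, 0) for i in range(10)], shape=(20, 60, 8))
        tight = [(i, 0, 0) for i in range(7)]
        sprawl = [(8, 0, 0), (9, 0, 0)] + [(9, j, 0) for j in range(1, 51)]
        a = vol_from_coords(tight + sprawl, shape=(20, 60, 8))
        la, lg = labeled(a), labeled(g)
        assert la.n_lesions == 2  # gap at i=7 keeps the components apart
        tp, _ = count_detected(lg, la, params=P0)
        assert tp == 1
        # requiring 90% of the overlap mass pulls in the sprawling lesion,
        # whose 50/52 = 96% outside fraction breaks beta=70%
        strict = DetectionParams(min_volume_mm3=0.0, gamma_pct=90.0)
        tp, _ = count_detected(lg, la, params=strict)
        assert tp == 0

    def test_role_symmetry(self, rng):
        for _ in range(5):
            la = labeled(random_blob_mask(rng, shape=(14, 14, 14)))
            lg = labeled(random_blob_mask(rng, shape=(14, 14, 14)))
            tp_ga, _ = count_detected(lg, la, params=P0)
            rep = detection_metrics(la, lg, P0)  # roles reversed
            assert rep.tp_a == tp_ga

    def test_monotone_in_alpha_and_beta(self, rng):
        la = labeled(random_blob_mask(rng, shape=(16, 16, 16)))
        lg = labeled(random_blob_mask(rng, shape=(16, 16, 16)))
        tps_alpha = [count_detected(lg, la, params=DetectionParams(
            alpha_pct=a, min_volume_mm3=0.0))[0] for a in (5, 10, 30, 60, 90)]
        assert tps_alpha == sorted(tps_alpha, reverse=True)
        tps_beta = [count_detected(lg, la, params=DetectionParams(
            beta_pct=b, min_volume_mm3=0.0))[0] for b in (90, 70, 50, 30, 10)]
        assert tps_beta == sorted(tps_beta, reverse=True)

    def test_invariant_under_translation(self, small_phantom):
        gt, _ = small_phantom
        rolled = gt.with_occupancy(np.roll(gt.occupancy, (2, -3, 1), axis=(0, 1, 2)))
        # the phantom has a clear margin, so rolling is a rigid translation
        rep1 = detection_metrics(labeled(gt), labeled(gt), P0)
        rep2 = detection_metrics(labeled(rolled), labeled(rolled), P0)
        assert (rep1.tp_g, rep1.m) == (rep2.tp_g, rep2.m)

    def test_agrees_with_set_arithmetic_oracle(self, rng):
        for _ in range(10):
            la = labeled(random_blob_mask(rng, shape=(14, 14, 14)))
            lg = labeled(random_blob_mask(rng, shape=(14, 14, 14)))
            tp, flags = count_detected(lg, la, params=P0)
            want_tp, want_flags = brute_count_detected(
                lesion_sets(lg), lesion_sets(la), 10.0, 65.0, 70.0)
            assert tp == want_tp
            assert flags.tolist() == want_flags

    def test_union_mode_differs_when_contributors_split(self):
        # 8-voxel reference bar; contributor a1 is 5 voxels with 1 outside
        # (20%), contributor a2 is 12 voxels with 9 outside (75%). At
        # beta=70% the per-contributor rule fails on a2, but the union
        # (10 of 17 voxels outside, 59%) passes.
        g = vol_from_coords([(i, 0, 0) for i in range(8)], shape=(20, 20, 8))
        a1 = [(i, 0, 0) for i in range(4)] + [(0, 1, 0)]
        a2 = [(i, 0, 0) for i in range(5, 8)] + [(7, j, 0) for j in range(1, 10)]
        a = vol_from_coords(a1 + a2, shape=(20, 20, 8))
        la, lg = labeled(a), labeled(g)
        assert la.n_lesions == 2  # gap at i=4 keeps the contributors apart
        per = DetectionParams(min_volume_mm3=0.0, gamma_pct=99.0)
        uni = DetectionParams(min_volume_mm3=0.0, gamma_pct=99.0, beta_on_union=True)
        assert count_detected(lg, la, params=per)[0] == 0
        assert count_detected(lg, la, params=uni)[0] == 1


class TestDetectionReport:
    def test_perfect_match(self):
        lm = labeled(cube((2, 2, 2), 3))
        rep = detection_metrics(lm, lm, P0)
        assert rep.lesion_sensitivity == rep.lesion_ppv == rep.f1 == 1.0

    def test_partial_match_arithmetic(self):
        # M=2 reference lesions, N=1 evaluated lesion matching one exactly
        g = vol_from_coords([(2, 2, 2), (2, 2, 3), (10, 10, 10), (10, 10, 11)])
        a = vol_from_coords([(2, 2, 2), (2, 2, 3)])
        rep = detection_metrics(labeled(g), labeled(a), P0)
        assert rep.lesion_sensitivity == pytest.approx(0.5)
        assert rep.lesion_ppv == pytest.approx(1.0)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_empty_evaluated_mask_scores_zero(self):
        g = labeled(cube((2, 2, 2), 2))
        a = labeled([])
        rep = detection_metrics(g, a, P0)
        assert rep.lesion_sensitivity == 0.0
        assert rep.lesion_ppv == 0.0
        assert rep.f1 == 0.0

    def test_empty_reference_flagged_for_no_consensus(self):
        rep = detection_metrics(labeled([]), labeled(cube((2, 2, 2), 2)), P0)
        assert np.isnan(rep.f1)
        assert "empty_reference_route_to_no_consensus" in rep.flags


class TestNoConsensus:
    def test_empty_mask_is_perfect(self):
        rep = no_consensus_metrics(vol_from_coords([]))
        assert (rep.n_lesions, rep.total_volume_cm3) == (0, 0.0)

    def test_unit_conversion_to_cm3(self):
        v = vol_from_coords([(5, 5, z) for z in range(10)])
        rep = no_consensus_metrics(v)
        assert rep.n_lesions == 1
        assert rep.total_volume_cm3 == pytest.approx(0.010)

    def test_corner_touching_voxels_fall_below_size_rule(self):
        # two 1 mm^3 voxels touching only at a corner: separate components
        # under 18-connectivity, each below 3 mm^3
        v = vol_from_coords([(3, 3, 3), (4, 4, 4)])
        rep = no_consensus_metrics(v)
        assert (rep.n_lesions, rep.total_volume_cm3) == (0, 0.0)


class TestPerLesionRates:
    def test_all_performers_perfect(self):
        lg = labeled(cube((2, 2, 2), 3))
        df = per_lesion_detection_rates([(lg, [lg, lg, lg])], P0)
        assert (df["detection_rate_pct"] == 100.0).all()

    def test_all_performers_empty(self):
        lg = labeled(cube((2, 2, 2), 3))
        empty = labeled([])
        df = per_lesion_detection_rates([(lg, [empty, empty])], P0)
        assert (df["detection_rate_pct"] == 0.0).all()

    def test_half_of_performers_detect(self):
        lg = labeled(cube((2, 2, 2), 3))
        empty = labeled([])
        df = per_lesion_detection_rates([(lg, [lg, lg, empty, empty])], P0)
        assert df["detection_rate_pct"].tolist() == [50.0]
        assert df["volume_mm3"].tolist() == [27.0]
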