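import numpy as np
import pytest

from leafpheno.architecture import (
    analyze_architecture,
    compute_vein_angle,
    determine_petiole,
    extract_first_order_laminas,
    find_attachment_point,
    midrib_main_path,
    partition_blade_regions,
    reconstruct_midrib_from_laminas,
    simplify_polygon,
    skeletonize_component,
    split_left_right,
)
from leafpheno.synthetic import LeafParams, generate_leaf


def max_deviation(contour, polygon):
    """Oracle: largest perpendicular distance from any dropped contour
    point to its simplified chord (polygon vertices are contour points
    in order)."""
    poly = [tuple(p) for p in polygon]
    idx = []
    j = 0
    for i, pt in enumerate(map(tuple, contour)):
        if j < len(poly) and pt == poly[j]:
            idx.append(i)
            j += 1
    assert j == len(poly), "polygon vertices are not an ordered subset"
    worst = 0.0
    for a, b in zip(idx, idx[1:]):
        p0, p1 = contour[a], contour[b]
        seg = p1 - p0
        norm = np.linalg.norm(seg)
        for k in range(a + 1, b):
            v = contour[k] - p0
            cross = seg[0] * v[1] - seg[1] * v[0]
            d = abs(cross) / norm if norm > 0 else np.linalg.norm(v)
            worst = max(worst, d)
    return worst


class TestSkeleton:
    def test_thin_line_is_its_own_skeleton(self):
        m = np.zeros((10, 30), bool)
        m[5, 5:25] = True
        g = skeletonize_component(m)
        assert (g.mask == m).all()
        assert len(g.endpoints) == 2
        assert len(g.branch_points) == 0
        assert g.total_length == pytest.approx(19.0)

    def test_t_shape_has_three_endpoints_one_branch(self):
        m = np.zeros((20, 20), bool)
        m[5, 3:16] = True
        m[5:15, 9] = True
        g = skeletonize_component(m)
        assert len(g.endpoints) == 3
        assert len(g.branch_points) == 1

    def test_thick_band_length_close_to_true_length(self):
        m = np.zeros((20, 120), bool)
        m[8:13, 10:110] = True
        g = skeletonize_component(m)
        assert len(g.segments) == 1
        assert g.total_length == pytest.approx(100, rel=0.05)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            skeletonize_component(np.zeros((5, 5), bool))


class TestBladePartition:
    def test_vertical_cut_gives_two_regions(self):
        bd = np.ones((20, 20), bool)
        skel = np.zeros_like(bd)
        skel[:, 10] = True
        g = skeletonize_component(skel)
        labels = partition_blade_regions(bd, g)
        assert labels.max() == 2

    def test_no_skeleton_gives_one_region(self):
        from leafpheno.architecture import SkeletonGraph

        bd = np.ones((10, 10), bool)
        empty = SkeletonGraph(np.zeros_like(bd), [], [], [], 0.0)
        assert partition_blade_regions(bd, empty).max() == 1

    def test_synthetic_leaf_region_count(self, default_leaf):
        """Cutting the blade by the venation skeleton yields at least the
        ground-truth lamina count of regions."""
        sample, truth = default_leaf
        g = skeletonize_component(sample.components["VV"])
        labels = partition_blade_regions(sample.components["BD"], g)
        areas = np.bincount(labels.ravel())[1:]
        assert (areas > 25).sum() >= truth.LM_N

    def test_skeleton_must_be_inside_blade(self, default_leaf):
        sample, _ = default_leaf
        g = skeletonize_component(sample.components["VV"])
        assert not (g.mask & ~sample.components["BD"]).any()


class TestLeftRightSplit:
    def test_partition_properties(self, default_leaf):
        sample, _ = default_leaf
        mrp = midrib_main_path(sample.components["MR"])
        bd = sample.components["BD"]
        left, right = split_left_right(bd, mrp)
        assert not (left & right).any()
        assert ((left | right) & ~bd).sum() == 0
        divider = bd & ~left & ~right
        assert (left | right | divider == bd).all()

    def test_symmetric_leaf_splits_evenly(self):
        sample, _ = generate_leaf(LeafParams(seed=5, midrib_curvature=0.0))
        mrp = midrib_main_path(sample.components["MR"])
        left, right = split_left_right(sample.components["BD"], mrp)
        assert 0.95 <= left.sum() / right.sum() <= 1.05

    def test_mask_on_one_side_only(self, default_leaf):
        sample, _ = default_leaf
        mrp = midrib_main_path(sample.components["MR"])
        bd = sample.components["BD"]
        left_only, _ = split_left_right(bd, mrp)
        left2, right2 = split_left_right(left_only, mrp)
        assert right2.sum() == 0
        assert (left2 == left_only).all()


class TestPetiole:
    def test_lengths_are_complementary(self, default_leaf):
        sample, _ = default_leaf
        pet = determine_petiole(sample.components["MR"],
                                sample.components["LM"])
        assert pet.PE_L + pet.AP_L == pytest.approx(pet.MR_L, abs=2.0)

    def test_petiole_matches_ground_truth(self, default_leaf):
        sample, truth = default_leaf
        pet = determine_petiole(sample.components["MR"],
                                sample.components["LM"])
        assert pet.PE_L == pytest.approx(truth.PE_L, abs=5.0)

    def test_no_adjacent_lamina_leaves_petiole_undefined(self, default_leaf):
        sample, _ = default_leaf
        empty_lm = np.zeros_like(sample.components["LM"])
        with pytest.warns(UserWarning, match="no lamina"):
            pet = determine_petiole(sample.components["MR"], empty_lm)
        assert pet.PE_L is None
        assert not pet.petiole_mask.any()


class TestPolygonSimplification:
    def test_collinear_chain_reduces_to_endpoints(self):
        chain = np.column_stack([np.zeros(30), np.arange(30.0)])
        out = simplify_polygon(chain, tolerance=5)
        assert len(out) == 2

    def test_square_keeps_its_corners(self):
        side = np.arange(40.0)
        sq = np.vstack([
            np.column_stack([np.zeros(40), side]),
            np.column_stack([side, np.full(40, 40.0)]),
            np.column_stack([np.full(40, 40.0), side[::-1] + 1]),
            np.column_stack([side[::-1] + 1, np.zeros(40)]),
            [[0.0, 0.0]],
        ])
        out = simplify_polygon(sq, tolerance=5)
        verts = {tuple(v) for v in out}
        for corner in [(0, 0), (0, 40), (40, 41), (41, 0)]:
            assert any(np.hypot(v[0] - corner[0], v[1] - corner[1]) <= 1.5
                       for v in verts), corner

    @pytest.mark.parametrize("seed", range(5))
    def test_subset_and_deviation_on_random_star_polygons(self, seed):
        """Output vertices are an ordered subset of the input and the
        dropped points stay within tolerance (brute-force check)."""
        rng = np.random.default_rng(seed)
        n = 400
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = 50 + 12 * np.sin(th * rng.integers(3, 7)) + rng.normal(0, 1, n)
        contour = np.column_stack([r * np.cos(th), r * np.sin(th)])
        contour = np.vstack([contour, contour[:1]])
        tol = 5.0
        poly = simplify_polygon(contour, tolerance=tol)
        assert max_deviation(contour, poly) <= tol

    def test_degenerate_contour_raises(self):
        with pytest.raises(ValueError):
            simplify_polygon(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestAttachmentAndAngle:
    def _path(self):
        mr = np.zeros((60, 20), bool)
        mr[5:55, 10] = True
        return midrib_main_path(mr)

    def test_unique_touching_vertex_wins(self):
        mrp = self._path()
        poly = np.array([[30.0, 11.0], [20.0, 30.0], [40.0, 30.0]])
        i, att = find_attachment_point(poly, mrp)
        assert att == (30.0, 11.0)

    def test_tie_broken_toward_base(self):
        mrp = self._path()  # base at row 54
        poly = np.array([[20.0, 12.0], [40.0, 12.0], [30.0, 30.0]])
        _, att = find_attachment_point(poly, mrp)
        assert att[0] == 40.0  # the vertex nearer the (lower) base

    def test_perpendicular_edges_give_90(self):
        poly = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0],
                         [10.0, 0.0], [0.0, 0.0]])
        assert compute_vein_angle(poly, 1) == pytest.approx(90.0)

    def test_collinear_edges_give_180(self):
        poly = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0], [5.0, 8.0],
                         [0.0, 0.0]])
        assert compute_vein_angle(poly, 1) == pytest.approx(180.0)

    def test_zero_length_edges_are_skipped(self):
        poly = np.array([[0.0, 0.0], [0.0, 10.0], [0.0, 10.0],
                         [10.0, 10.0], [0.0, 0.0]])
        assert compute_vein_angle(poly, 1) == pytest.approx(90.0)


class TestGroundTruthRecovery:
    def test_counts_attachments_angles_on_clean_leaf(self, default_leaf):
        sample, truth = default_leaf
        arch = analyze_architecture(sample.components)
        assert (arch.LM_N, arch.LM_N_LT, arch.LM_N_RT) == (
            truth.LM_N, truth.LM_N_LT, truth.LM_N_RT)
        by_key = {(L.side, L.order_index): L for L in truth.laminas}
        for L in arch.laminas:
            T = by_key[(L.side, L.order_index)]
            err = np.hypot(L.attachment[0] - T.attachment[0],
                           L.attachment[1] - T.attachment[1])
            assert err <= 3.0
            assert L.vein_angle == pytest.approx(T.vein_angle, abs=5.0)
            assert L.area == T.area

    def test_right_angle_veins_recovered(self):
        sample, truth = generate_leaf(LeafParams(
            seed=9, vein_angles_left=(90.0,) * 4,
            vein_angles_right=(90.0,) * 4))
        arch = analyze_architecture(sample.components)
        assert arch.LM_Ave_ANG == pytest.approx(90.0, abs=5.0)

    def test_angle_lists_ordered_base_to_apex(self, default_leaf):
        sample, truth = default_leaf
        arch = analyze_architecture(sample.components)
        for side in ("left", "right"):
            arcs = [L.arc_position for L in arch.laminas if L.side == side]
            assert arcs == sorted(arcs)
        assert all(0 < a <= 180 for a in
                   arch.LM_ANG_List_LT + arch.LM_ANG_List_RT)
        assert arch.LM_Ave_ANG == pytest.approx(
            np.mean(arch.LM_ANG_List_LT + arch.LM_ANG_List_RT))


class TestMidribReconstruction:
    def test_reconstruction_overlaps_true_midrib(self, default_leaf):
        sample, _ = default_leaf
        arch = analyze_architecture(sample.components)
        rec = reconstruct_midrib_from_laminas(
            arch.laminas, sample.components["VS"], sample.components["BD"])
        mr = sample.components["MR"]
        iou = (rec & mr).sum() / (rec | mr).sum()
        assert iou >= 0.6

    def test_one_sided_laminas_raise(self, default_leaf):
        sample, _ = default_leaf
        arch = analyze_architecture(sample.components)
        left_only = [L for L in arch.laminas if L.side == "left"]
        with pytest.raises(ValueError):
            reconstruct_midrib_from_laminas(left_only,
                                            sample.components["VS"])
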