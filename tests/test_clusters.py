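import numpy as np
import pandas as pd
import pytest

from mccad.clusters import (
    ClusterDetection,
    clusters_rule1,
    clusters_rule2,
    cumulative_probability_map,
    match_cluster,
    mm_to_px,
    write_clusters,
)
from mccad.config import ClusterRuleConfig
from mccad.io import ClusterAnnotationSet

# spacing 0.1 mm/px: d_c1 = 4 mm = 40 px
CFG = ClusterRuleConfig(spacing_mm=0.1)


def _brute_force_rule1(points, config):
    """Naive re-implementation: per-seed neighborhoods, pairwise and
    region-size constraints, greedy largest-first member-disjoint output."""
    pts = [tuple(map(float, p)) for p in points]
    d_px = config.d_c1_mm / config.spacing_mm
    half = 0.5 * np.sqrt(config.a_c1_mm2) / config.spacing_mm

    def dist(a, b):
        return np.hypot(a[0] - b[0], a[1] - b[1])

    cands = []
    for seed in pts:
        members = [q for q in pts if dist(seed, q) <= d_px]
        if len(members) < 3:
            continue
        if max(dist(a, b) for a in members for b in members) > d_px:
            continue
        cr = sum(m[0] for m in members) / len(members)
        cc = sum(m[1] for m in members) / len(members)
        if max(max(abs(m[0] - cr), abs(m[1] - cc)) for m in members) > half:
            continue
        cands.append((len(members), (int(seed[0]), int(seed[1])), frozenset(members)))
    cands.sort(key=lambda t: (-t[0], t[1]))
    out, used = [], set()
    for _, _, members in cands:
        if members & used:
            continue
        used |= members
        out.append(members)
    return out


class TestMmToPx:
    def test_one_cm_window_sides(self):
        assert mm_to_px(10.0, 0.1) == 100
        assert mm_to_px(10.0, 0.05) == 200
        assert mm_to_px(10.0, 0.2) == 50

    def test_rounding(self):
        assert mm_to_px(0.26, 0.1) == 3

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            mm_to_px(1.0, 0.0)


class TestRule1:
    def test_three_point_cluster(self):
        pts = [(0, 0), (0, 20), (20, 0)]
        out = clusters_rule1(pts, CFG)
        assert len(out) == 1
        assert out[0].n_members == 3
        assert sorted(out[0].members) == sorted(pts)
        assert out[0].rule == "pairwise"
        assert out[0].score == 3.0

    def test_two_points_are_not_a_cluster(self):
        assert clusters_rule1([(0, 0), (0, 10)], CFG) == []

    def test_chain_fails_pairwise_constraint(self):
        # middle point sees both ends, but the ends are 70 px apart (> 40)
        assert clusters_rule1([(0, 0), (0, 35), (0, 70)], CFG) == []

    def test_overlap_resolved_greedily_largest_first(self):
        a, a2, b, c = (0, 0), (0, 10), (0, 20), (0, 40)
        d_, e = (0, 60), (0, 80)
        out = clusters_rule1([a, a2, b, c, d_, e], CFG)
        # N(a) = {a, a2, b, c} (size 4) and N(e) = {c, d_, e} (size 3)
        # share c; the larger wins and the smaller is dropped entirely
        assert len(out) == 1
        assert sorted(out[0].members) == [a, a2, b, c]

    def test_equal_size_overlap_ties_to_smallest_seed(self):
        a, b, c, d_, e = (0, 0), (0, 20), (0, 40), (0, 60), (0, 80)
        out = clusters_rule1([a, b, c, d_, e], CFG)
        assert len(out) == 1
        assert sorted(out[0].members) == [a, b, c]

    def test_region_size_constraint(self):
        cfg = ClusterRuleConfig(d_c1_mm=40.0, a_c1_mm2=16.0, spacing_mm=1.0)
        pts = [(0, 0), (0, 10), (10, 5)]  # pairwise <= 11.2 but spread > 2 px
        assert clusters_rule1(pts, cfg) == []
        roomy = ClusterRuleConfig(d_c1_mm=40.0, a_c1_mm2=10000.0, spacing_mm=1.0)
        assert len(clusters_rule1(pts, roomy)) == 1

    def test_centroid_and_bbox(self):
        out = clusters_rule1([(0, 0), (0, 20), (20, 0), (20, 20)], CFG)
        assert len(out) == 1
        assert out[0].center == (10, 10)
        assert out[0].bbox == (0, 0, 20, 20)

    def test_empty_input(self):
        assert clusters_rule1([], CFG) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        pts = [tuple(p) for p in rng.integers(0, 120, size=(12, 2))]
        pts = list(dict.fromkeys(pts))  # dedupe
        got = clusters_rule1(pts, CFG)
        want = _brute_force_rule1(pts, CFG)
        got_sets = {frozenset((float(r), float(c)) for r, c in cl.members) for cl in got}
        assert got_sets == set(want)


class TestCumulativeProbabilityMap:
    @pytest.mark.parametrize("side", [1, 3, 5, 9])
    def test_matches_nested_loop_exactly(self, side):
        rng = np.random.default_rng(3)
        p = np.zeros((20, 24))
        pos = rng.integers(0, 20 * 24, size=30)
        # dyadic values make both summation orders exact in floating point
        p.ravel()[pos] = rng.integers(0, 64, size=30) / 64.0
        got = cumulative_probability_map(p, side)
        half = side // 2
        padded = np.pad(p, half)
        want = np.zeros_like(p)
        for r in range(p.shape[0]):
            for c in range(p.shape[1]):
                want[r, c] = padded[r : r + side, c : c + side].sum()
        np.testing.assert_array_equal(got, want)

    def test_float_inputs_close(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=(16, 16))
        got = cumulative_probability_map(p, 5)
        padded = np.pad(p, 2)
        want = np.array(
            [[padded[r : r + 5, c : c + 5].sum() for c in range(16)] for r in range(16)]
        )
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 64, size=(12, 12)) / 64.0
        b = rng.integers(0, 64, size=(12, 12)) / 64.0
        np.testing.assert_array_equal(
            cumulative_probability_map(a + b, 3),
            cumulative_probability_map(a, 3) + cumulative_probability_map(b, 3),
        )

    def test_window_validation(self):
        with pytest.raises(ValueError):
            cumulative_probability_map(np.zeros((5, 5)), 2)
        with pytest.raises(ValueError):
            cumulative_probability_map(np.zeros((5, 5)), 0)


class TestRule2:
    CFG2 = ClusterRuleConfig(a_c2_mm2=25.0, p_c_threshold=1.0, spacing_mm=1.0)

    def test_three_detections_form_one_cluster(self):
        p = np.zeros((20, 20))
        for r, c in ((10, 10), (10, 12), (12, 10)):
            p[r, c] = 0.5
        out = clusters_rule2(p, self.CFG2)
        assert len(out) == 1
        cl = out[0]
        assert cl.rule == "cumulative"
        assert cl.score == pytest.approx(1.5)  # all three in one 5x5 window
        r0, c0, r1, c1 = cl.bbox
        assert r0 <= 10 and c0 <= 10 and r1 >= 12 and c1 >= 12

    def test_threshold_above_mass_gives_nothing(self):
        p = np.zeros((20, 20))
        p[10, 10] = 0.5
        cfg = ClusterRuleConfig(a_c2_mm2=25.0, p_c_threshold=2.0, spacing_mm=1.0)
        assert clusters_rule2(p, cfg) == []

    def test_two_separated_groups(self):
        p = np.zeros((40, 40))
        for r, c in ((5, 5), (5, 7), (30, 30), (30, 32)):
            p[r, c] = 0.6
        out = clusters_rule2(p, self.CFG2)
        assert len(out) == 2


class TestMatching:
    def test_center_in_box(self):
        ann = ClusterAnnotationSet(regions=[ClusterAnnotationSet.box(0, 0, 10, 10)])
        inside = ClusterDetection(center=(10, 10), bbox=(9, 9, 10, 10), score=3, rule="pairwise")
        outside = ClusterDetection(center=(11, 10), bbox=(10, 9, 11, 10), score=3, rule="pairwise")
        assert match_cluster(inside, ann)  # boundary is inclusive
        assert not match_cluster(outside, ann)

    def test_center_in_circle_square(self):
        ann = ClusterAnnotationSet(regions=[ClusterAnnotationSet.circle(20, 20, 5)])
        det = ClusterDetection(center=(24, 24), bbox=(24, 24, 24, 24), score=3, rule="pairwise")
        assert match_cluster(det, ann)

    def test_write_clusters_csv(self, tmp_path):
        out = clusters_rule1([(0, 0), (0, 20), (20, 0)], CFG)
        path = tmp_path / "clusters.csv"
        write_clusters(out, path, image_id="img0")
        df = pd.read_csv(path)
        assert list(df["rule"]) == ["pairwise"]
        assert list(df["n_members"]) == [3]
        assert df["image_id"].iloc[0] == "img0"
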