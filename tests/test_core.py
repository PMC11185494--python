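"""Unit and property tests for the two-neighbor edge rule, the
conventional 4-neighbor baseline and stimulation rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rped import (
    ActivationMap,
    GrayImage,
    RPEDParams,
    conventional_detect,
    edge_compare,
    intensity_detect,
    partition_clusters,
    quantize_threshold_step,
    render_stimulation,
    rped_detect,
)
from conftest import rped_bruteforce


def _images(max_side=12):
    return st.integers(2, max_side).flatmap(
        lambda h: st.integers(2, max_side).flatmap(
            lambda w: st.lists(
                st.integers(0, 255), min_size=h * w, max_size=h * w
            ).map(lambda v: GrayImage(np.array(v).reshape(h, w)))
        )
    )


class TestQuantizeThresholdStep:
    @pytest.mark.parametrize(
        "lo, hi, n, expected",
        [(24, 229, 15, 14), (0, 255, 15, 17), (50, 50, 15, 0), (0, 255, 1, 255)],
    )
    def test_examples(self, lo, hi, n, expected):
        assert quantize_threshold_step(lo, hi, n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            quantize_threshold_step(0, 255, 0)
        with pytest.raises(ValueError):
            quantize_threshold_step(100, 50, 15)


class TestEdgeCompare:
    @pytest.mark.parametrize(
        "center, neighbor, thr, expected",
        [
            (100, 40, 56, (True, False)),
            (40, 100, 56, (False, True)),
            (96, 40, 56, (False, False)),  # strict: 96 > 96 fails
            (40, 96, 56, (False, False)),
        ],
    )
    def test_examples(self, center, neighbor, thr, expected):
        assert edge_compare(center, neighbor, thr) == expected

    @given(
        st.integers(0, 255), st.integers(0, 255), st.integers(1, 255)
    )
    def test_at_most_one_marked_for_positive_threshold(self, c, n, thr):
        mc, mn = edge_compare(c, n, thr)
        assert not (mc and mn)


class TestPartitionClusters:
    @pytest.mark.parametrize(
        "h, w, cr, cc, n_blocks, block_shape",
        [(45, 45, 5, 5, 25, (9, 9)), (40, 40, 5, 5, 25, (8, 8)), (4, 4, 1, 1, 1, (4, 4))],
    )
    def test_even_partitions(self, h, w, cr, cc, n_blocks, block_shape):
        blocks = partition_clusters(h, w, cr, cc)
        assert len(blocks) == n_blocks
        for r0, c0, r1, c1 in blocks:
            assert (r1 - r0, c1 - c0) == block_shape

    def test_covers_grid_disjointly(self):
        for h, w, cr, cc in [(45, 45, 5, 5), (10, 7, 3, 2), (16, 16, 4, 3)]:
            cover = np.zeros((h, w), dtype=int)
            for r0, c0, r1, c1 in partition_clusters(h, w, cr, cc):
                cover[r0:r1, c0:c1] += 1
            assert (cover == 1).all()

    def test_too_fine_grid_rejected(self):
        with pytest.raises(ValueError):
            partition_clusters(4, 4, 5, 1)


class TestRPEDDetect:
    def test_constant_image_inactive(self):
        img = GrayImage(np.full((6, 6), 42))
        p = RPEDParams(thr_index=1, thr_step=10, alpha=1, cluster_rows=2, cluster_cols=2)
        assert rped_detect(img, p).n_active == 0

    def test_step_worked_example(self, step4x4):
        p = RPEDParams(thr_index=1, thr_step=50, alpha=1, cluster_rows=1, cluster_cols=1)
        am = rped_detect(step4x4, p)
        expected = np.zeros((4, 4), dtype=bool)
        expected[:, 2] = True  # brighter side of the 10|200 boundary
        assert (am.active == expected).all()
        assert am.n_active == 4

    def test_bright_center_pixel(self):
        vals = np.full((5, 5), 10)
        vals[2, 2] = 200
        p = RPEDParams(thr_index=1, thr_step=50, alpha=1, cluster_rows=1, cluster_cols=1)
        am = rped_detect(GrayImage(vals), p)
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        assert (am.active == expected).all()

    def test_alpha_too_large_rejected(self):
        img = GrayImage(np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError):
            rped_detect(img, RPEDParams(alpha=4, cluster_rows=1, cluster_cols=1))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        _images(),
        st.integers(0, 260),
        st.integers(1, 3),
        st.integers(1, 4),
        st.integers(1, 4),
        st.sampled_from(["top-left", "center"]),
    )
    def test_oracle_equivalence(self, img, thr, alpha, cr, cc, policy):
        """Scan order, clustering and seed choice never change the
        sticky-OR result: it always equals brute-force evaluation."""
        h, w = img.shape
        alpha = min(alpha, min(h, w) - 1)
        cr, cc = min(cr, h), min(cc, w)
        p = RPEDParams(
            thr_index=1, thr_step=thr, alpha=alpha,
            cluster_rows=cr, cluster_cols=cc, seed_policy=policy,
        )
        assert (rped_detect(img, p).active == rped_bruteforce(img.values, thr, alpha)).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(_images(10), st.integers(1, 2))
    def test_n_active_non_increasing_in_threshold(self, img, alpha):
        alpha = min(alpha, min(img.shape) - 1)
        counts = []
        for thr in (0, 20, 60, 120, 250):
            p = RPEDParams(thr_index=1, thr_step=thr, alpha=alpha,
                           cluster_rows=1, cluster_cols=1)
            counts.append(rped_detect(img, p).n_active)
        assert counts == sorted(counts, reverse=True)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(3, 10), st.integers(0, 200), st.data())
    def test_left_right_reflection_symmetry(self, w, thr, data):
        """For an image with purely horizontal contrast, mirroring the
        image left-right mirrors the activation map: the right/down
        neighbor convention hides no directional bias."""
        row = data.draw(st.lists(st.integers(0, 255), min_size=w, max_size=w))
        img = GrayImage(np.tile(np.array(row), (4, 1)))
        p = RPEDParams(thr_index=1, thr_step=thr, alpha=1,
                       cluster_rows=1, cluster_cols=1)
        a = rped_detect(img, p).active
        mirrored = rped_detect(GrayImage(img.values[:, ::-1]), p).active
        assert (mirrored[:, ::-1] == a).all()

    def test_zero_threshold_marks_brighter_member_of_every_pair(self, rng):
        """At thr = 0 each comparison of unequal pixels marks its
        brighter member, so exactly the pixels that are strictly
        brighter than at least one compared partner end up active."""
        vals = rng.permutation(64).reshape(8, 8).astype(np.int64)
        p = RPEDParams(thr_index=0, thr_step=14, alpha=1, cluster_rows=2, cluster_cols=2)
        active = rped_detect(GrayImage(vals), p).active
        expected = np.zeros((8, 8), dtype=bool)
        for r in range(8):
            for c in range(8):
                for nr, nc in ((r, c + 1), (r + 1, c)):
                    if nr < 8 and nc < 8:
                        if vals[r, c] > vals[nr, nc]:
                            expected[r, c] = True
                        elif vals[nr, nc] > vals[r, c]:
                            expected[nr, nc] = True
        assert (active == expected).all()


class TestConventionalDetect:
    def test_constant_image_inactive(self):
        img = GrayImage(np.full((5, 5), 7))
        assert conventional_detect(img, 10).n_active == 0

    def test_step_any_neighbor(self, step4x4):
        am = conventional_detect(step4x4, 50, 1, "any-neighbor")
        expected = np.zeros((4, 4), dtype=bool)
        expected[:, 1:3] = True  # both sides of the boundary
        assert (am.active == expected).all()
        assert am.n_active == 8

    def test_step_mean_of_neighbors(self, step4x4):
        # interior pixels of cols 1-2 see |center - mean| = 47.5 < 50
        am = conventional_detect(step4x4, 50, 1, "mean-of-neighbors")
        assert not am.active[1:3, 1].any()
        assert not am.active[1:3, 2].any()

    def test_unknown_mode_rejected(self, step4x4):
        with pytest.raises(ValueError):
            conventional_detect(step4x4, 50, 1, "median")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(_images(9), st.integers(0, 200))
    def test_locality(self, img, thr):
        """Any-neighbor activation of a pixel depends only on its
        4-neighborhood: perturbing a far pixel cannot change it."""
        am = conventional_detect(img, thr, 1)
        vals = img.values.copy()
        vals[0, 0] = (vals[0, 0] + 131) % 256
        am2 = conventional_detect(GrayImage(vals), thr, 1)
        h, w = img.shape
        far = np.ones((h, w), dtype=bool)
        far[0 : min(2, h), 0 : min(2, w)] = False
        assert (am.active[far] == am2.active[far]).all()


class TestRenderStimulation:
    def test_masking(self):
        img = GrayImage(np.array([[10, 20], [30, 40]]))
        am = ActivationMap(np.array([[True, False], [False, True]]))
        frame = render_stimulation(img, am)
        assert (frame.values == np.array([[10, 0], [0, 40]])).all()

    def test_all_false_and_all_true(self, step4x4):
        off = ActivationMap(np.zeros((4, 4), dtype=bool))
        on = ActivationMap(np.ones((4, 4), dtype=bool))
        assert (render_stimulation(step4x4, off).values == 0).all()
        assert (render_stimulation(step4x4, on).values == step4x4.values).all()

    def test_idempotent_through_second_masking(self, step4x4, rng):
        am = ActivationMap(rng.random((4, 4)) < 0.5)
        once = render_stimulation(step4x4, am)
        twice = render_stimulation(GrayImage(once.values), am)
        assert (once.values == twice.values).all()

    def test_dimension_mismatch(self, step4x4):
        with pytest.raises(ValueError):
            render_stimulation(step4x4, ActivationMap(np.zeros((3, 3), dtype=bool)))


def test_intensity_detect_thresholds_luminance(step4x4):
    am = intensity_detect(step4x4, 100)
    assert (am.active == (step4x4.values > 100)).all()
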