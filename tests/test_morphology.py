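"""Convexity, border fractal dimension, and cross-pair correlation."""

import numpy as np
import pandas as pd
import pytest

from ithsim import morphology, synthetic
from ithsim.morphology import (
    DegenerateShapeError,
    PointPattern,
    aggressiveness_rank_pcf,
    border_fd,
    circle_window_area,
    convexity,
    cross_pcf,
    morphology_report,
    tumor_mask,
)


def snapshot_from_mask(mask, cell_type="MTC", genome=None):
    rows, cols = np.nonzero(mask)
    return pd.DataFrame({
        "cell_id": np.arange(len(rows)), "type": cell_type,
        "row": rows, "col": cols, "birth_step": 0, "a0": 1.5,
        "genome": genome or "1" + "0" * 49,
    })


class TestTumorMask:
    def test_no_mtc_gives_empty_mask(self):
        snap = snapshot_from_mask(synthetic.disk_mask(5), cell_type="NC")
        assert not tumor_mask(snap, 20).any()

    def test_mask_sum_equals_mtc_count(self):
        mask = synthetic.disk_mask(8)
        snap = snapshot_from_mask(mask)
        assert tumor_mask(snap, mask.shape[0]).sum() == mask.sum()

    def test_ctls_do_not_alter_mask(self):
        mask = synthetic.disk_mask(8)
        snap = snapshot_from_mask(mask)
        ctl = pd.DataFrame({
            "cell_id": [99999], "type": ["CTL"], "row": [0], "col": [0],
            "birth_step": [0], "a0": [0.0], "genome": [""],
        })
        with_ctl = pd.concat([snap, ctl], ignore_index=True)
        assert np.array_equal(tumor_mask(with_ctl, mask.shape[0]),
                              tumor_mask(snap, mask.shape[0]))


class TestConvexity:
    def test_disk_is_nearly_convex(self):
        C, P, P_H = convexity(synthetic.disk_mask(40))
        # staircase rasterization inflates the marching-squares perimeter
        # by a few percent, so C sits just below 1 for a true disk
        assert 0.9 <= C <= 1.0
        assert P_H <= P

    def test_plus_sign_clearly_non_convex(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[27:32, 5:50] = True
        mask[5:50, 27:32] = True
        C, _, _ = convexity(mask)
        assert C < 0.8

    def test_spikes_reduce_convexity(self):
        disk = synthetic.disk_mask(30)
        C_disk, _, _ = convexity(disk)
        spiky = disk.copy()
        c = disk.shape[0] // 2
        rng = np.random.default_rng(0)
        for ang in rng.uniform(0, 2 * np.pi, 12):
            for t in range(30, 34):
                r_i = int(round(c + t * np.sin(ang)))
                c_i = int(round(c + t * np.cos(ang)))
                spiky[r_i, c_i] = True
        C_spiky, _, _ = convexity(spiky)
        assert C_spiky < C_disk

    def test_degenerate_masks_rejected(self):
        with pytest.raises(DegenerateShapeError):
            convexity(np.zeros((10, 10), dtype=bool))
        tiny = np.zeros((10, 10), dtype=bool)
        tiny[5, 5] = True
        with pytest.raises(DegenerateShapeError):
            convexity(tiny)


class TestBorderFd:
    def test_disk_boundary_is_smooth_curve(self):
        assert border_fd(synthetic.disk_mask(40)) == pytest.approx(1.0, abs=0.1)

    def test_quadratic_koch_boundary_dimension(self):
        island = synthetic.quadratic_koch_island(4)
        assert border_fd(island) == pytest.approx(1.5, abs=0.1)

    def test_boundary_spikes_raise_dimension(self):
        disk = synthetic.disk_mask(40)
        spiky = disk.copy()
        c = disk.shape[0] // 2
        rng = np.random.default_rng(1)
        for ang in rng.uniform(0, 2 * np.pi, 20):
            for t in range(40, 44):
                spiky[int(round(c + t * np.sin(ang))),
                      int(round(c + t * np.cos(ang)))] = True
        assert border_fd(spiky) > border_fd(disk)

    def test_report_counts_satellites(self):
        mask = synthetic.disk_mask(15)
        big = np.zeros((80, 80), dtype=bool)
        big[:mask.shape[0], :mask.shape[1]] = mask
        big[70, 70] = True  # detached satellite
        rep = morphology_report(big)
        assert rep.n_satellites == 1
        assert 0 < rep.C <= 1


class TestCircleWindowArea:
    def test_interior_circle_full_area(self):
        A = circle_window_area(np.array([50.0]), np.array([50.0]),
                               np.array([10.0]), (100.0, 100.0))
        assert A[0, 0] == pytest.approx(np.pi * 100, rel=1e-6)

    def test_corner_circle_quarter_area(self):
        A = circle_window_area(np.array([0.0]), np.array([0.0]),
                               np.array([10.0]), (100.0, 100.0))
        assert A[0, 0] == pytest.approx(np.pi * 100 / 4, rel=1e-5)

    def test_edge_circle_half_area(self):
        A = circle_window_area(np.array([0.0]), np.array([50.0]),
                               np.array([10.0]), (100.0, 100.0))
        assert A[0, 0] == pytest.approx(np.pi * 100 / 2, rel=1e-5)

    def test_matches_polygon_clipping(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, box

        rng = np.random.default_rng(0)
        pts = rng.random((20, 2)) * [100, 80]
        radii = np.array([3.0, 15.0, 45.0])
        A = circle_window_area(pts[:, 0], pts[:, 1], radii, (100.0, 80.0))
        win = box(0, 0, 100, 80)
        for i, (x, y) in enumerate(pts):
            for j, r in enumerate(radii):
                ref = Point(x, y).buffer(r, quad_segs=128).intersection(win).area
                assert A[i, j] == pytest.approx(ref, rel=2e-3, abs=1e-3)


class TestCrossPcf:
    def test_no_targets_in_range_gives_zero(self):
        ref = np.array([[50.0, 50.0]])
        tgt = np.array([[95.0, 95.0]])
        df = cross_pcf(ref, tgt, np.array([5.0, 10.0]), (100.0, 100.0))
        assert (df["cpcf"] == 0).all()

    def test_single_annulus_closed_form(self):
        # 8 targets at distance ~7 from a central reference; only the
        # (5, 10] annulus is populated and its value is count/(lambda*area)
        ref = np.array([[50.0, 50.0]])
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        tgt = np.stack([50 + 7 * np.cos(ang), 50 + 7 * np.sin(ang)], axis=1)
        df = cross_pcf(ref, tgt, np.array([5.0, 10.0]), (100.0, 100.0))
        lam = 8 / 10_000
        area = np.pi * (100 - 25)
        assert df["cpcf"].iloc[0] == 0.0
        assert df["cpcf"].iloc[1] == pytest.approx(8 / (lam * area), rel=1e-3)
        assert df["cpcf"].iloc[1] > 1

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        ref = rng.random((200, 2)) * 60 + 20
        tgt = rng.random((200, 2)) * 60 + 20
        radii = np.array([4.0, 8.0, 12.0])
        a = cross_pcf(ref, tgt, radii, (100.0, 100.0))["cpcf"]
        b = cross_pcf(ref + 5, tgt + 5, radii, (105.0, 105.0))["cpcf"]
        assert np.allclose(a, b, rtol=0.15)

    def test_empty_patterns_rejected(self):
        with pytest.raises(ValueError):
            cross_pcf(np.zeros((0, 2)), np.ones((3, 2)), np.array([1.0]), (10.0, 10.0))

    def test_point_pattern_window_validation(self):
        with pytest.raises(ValueError):
            PointPattern(np.array([[5.0, 20.0]]), (10.0, 10.0))


class TestAggressivenessRankPcf:
    @staticmethod
    def _snapshot():
        # most aggressive clone (2 drivers) centered, second (1 driver)
        # adjacent, normal cells far away
        rows, cols, genomes = [], [], []
        two = "1001" + "0" * 46   # BRAF + TERT
        one = "1" + "0" * 49      # BRAF
        wild = "0" * 50
        for k in range(20):
            rows.append(50 + k % 5); cols.append(50 + k // 5); genomes.append(two)
        for k in range(20):
            rows.append(56 + k % 5); cols.append(50 + k // 5); genomes.append(one)
        for k in range(20):
            rows.append(5 + k % 5); cols.append(5 + k // 5); genomes.append(wild)
        return pd.DataFrame({
            "cell_id": np.arange(60), "type": ["MTC"] * 40 + ["NC"] * 20,
            "row": rows, "col": cols, "birth_step": 0, "a0": 1.5,
            "genome": genomes,
        })

    def test_labels_and_ordering(self):
        curves = aggressiveness_rank_pcf(self._snapshot(), np.array([4.0, 8.0, 16.0]),
                                         window=(100.0, 100.0))
        assert list(curves) == ["2", "NC"]

    def test_adjacent_clone_clusters_distant_ncs_do_not(self):
        curves = aggressiveness_rank_pcf(self._snapshot(), np.array([8.0, 16.0]),
                                         window=(100.0, 100.0))
        assert curves["2"]["cpcf"].iloc[0] > 1
        assert curves["NC"]["cpcf"].iloc[0] == 0.0

    def test_single_group_rejected(self):
        snap = self._snapshot()
        snap["genome"] = "1" + "0" * 49
        snap["type"] = "MTC"
        with pytest.raises(DegenerateShapeError):
            aggressiveness_rank_pcf(snap, np.array([4.0]), window=(100.0, 100.0))
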