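"""Dot detection, cluster correction and positivity calling."""

import numpy as np
import pandas as pd
import pytest

import trpscope as t
from trpscope.rnascope import (
    cluster_to_dots,
    count_dots_per_cell,
    detect_spots,
    fraction_positive,
    records_table,
    rolling_ball,
    single_dot_intensity,
)
from trpscope.synthgen import _add_gaussian_spot, grid_cell_masks

PX = 0.325  # um / px, matching the generator default


def _spot_image(positions, shape=(120, 120), diameter_um=0.8, intensity=1000.0):
    img = np.zeros(shape)
    sigma = (diameter_um / PX) / (2 * np.sqrt(2))
    for y, x in positions:
        _add_gaussian_spot(img, y, x, sigma, intensity)
    return img


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        out = rolling_ball(np.full((40, 40), 7.0), 1.0, PX)
        np.testing.assert_allclose(out, 0.0)

    def test_radius_below_one_px_rejected(self):
        with pytest.raises(ValueError, match="below 1 px"):
            rolling_ball(np.zeros((10, 10)), 0.2, 0.325)

    def test_gradient_removed_spots_preserved(self):
        """Smooth gradient + narrow spots: gradient removed within 5%,
        spot integrated intensity preserved within 10%."""
        yy, xx = np.mgrid[0:120, 0:120]
        gradient = 50.0 + 0.3 * xx + 0.2 * yy
        pos = [(30.0, 30.0), (60.0, 90.0), (95.0, 40.0)]
        spots = _spot_image(pos)
        out = rolling_ball(gradient + spots, 1.0, PX)
        # gradient residual, away from the spots
        far = np.ones((120, 120), bool)
        for y, x in pos:
            far[(yy - y) ** 2 + (xx - x) ** 2 < 100] = False
        assert np.abs(out[far]).max() < 0.05 * gradient.max()
        # integrated spot signal preserved
        for y, x in pos:
            near = (yy - y) ** 2 + (xx - x) ** 2 < 64
            assert out[near].sum() == pytest.approx(spots[near].sum(), rel=0.10)

    def test_large_radius_limit(self):
        """Huge ball: output tends to image - min(image)."""
        rng = np.random.default_rng(0)
        img = rng.random((30, 30)) + 2.0
        out = rolling_ball(img, radius_um=100.0, pixel_size_um=1.0)
        np.testing.assert_allclose(out, img - img.min(), atol=1e-12)


class TestDetectSpots:
    def test_blank_image_no_spots(self):
        assert len(detect_spots(np.zeros((60, 60)), PX)) == 0

    def test_singles_detected_and_localized(self):
        """20 well-separated singles at SNR 10: all found, centroid error
        below 1 px, none flagged as clusters."""
        rng = np.random.default_rng(1)
        pos = [(15.0 + 25 * (k // 5), 15.0 + 25 * (k % 5)) for k in range(20)]
        img = _spot_image(pos, shape=(130, 130))
        peak = img.max()
        img = np.clip(img + rng.normal(0, peak / 10, img.shape), 0, None)
        spots = detect_spots(rolling_ball(img, 1.0, PX), PX)
        assert abs(len(spots) - 20) <= 1
        assert not spots["is_cluster"].any()
        for y, x in pos:
            d = np.hypot(spots["y"] - y, spots["x"] - x).min()
            assert d < 1.0

    def test_three_dot_cluster_flagged(self):
        """A chain of three overlapping dots is one object flagged as a
        cluster with ~3x the single intensity."""
        d_px = 0.8 / PX
        singles = [(20.0, 20.0), (20.0, 60.0), (60.0, 20.0), (60.0, 60.0),
                   (40.0, 80.0), (80.0, 40.0)]
        cluster = [(85.0, 85.0), (85.0, 85.0 + 0.9 * d_px), (85.0 + 0.9 * d_px, 85.0)]
        img = _spot_image(singles + cluster, shape=(110, 110))
        spots = detect_spots(img, PX)
        clusters = spots[spots["is_cluster"]]
        assert len(clusters) == 1
        ref = single_dot_intensity(spots)
        assert cluster_to_dots(clusters["intensity"].iloc[0], ref) == 3

    def test_cluster_factor_sensitivity(self, rnascope_dataset):
        """The diameter factor separating singles from clusters is not
        knife-edge: nearby values give similar corrected totals."""
        sub = rolling_ball(
            rnascope_dataset["channels"]["probe"], 1.0, PX
        )
        totals = {}
        for factor in (1.3, 1.5, 1.7):
            spots = detect_spots(sub, PX, cluster_diameter_factor=factor)
            recs, _ = count_dots_per_cell(
                rnascope_dataset["truth"].cell_masks, spots, pixel_size_um=PX
            )
            totals[factor] = records_table(recs)["dots_total"].sum()
        base = totals[1.5]
        for v in totals.values():
            assert abs(v - base) / base < 0.10


class TestClusterCorrection:
    def test_reference_is_mean_of_singles(self):
        spots = pd.DataFrame(
            {
                "intensity": [900.0, 1000.0, 1100.0, 5000.0, 950.0, 1050.0],
                "is_cluster": [False, False, False, True, False, False],
            }
        )
        assert single_dot_intensity(spots) == pytest.approx(1000.0)

    def test_all_clusters_rejected(self):
        spots = pd.DataFrame({"intensity": [3000.0] * 6, "is_cluster": [True] * 6})
        with pytest.raises(ValueError, match="single dots"):
            single_dot_intensity(spots)

    def test_rounding_rule(self):
        assert cluster_to_dots(3000, 1000) == 3
        assert cluster_to_dots(1499, 1000) == 1
        assert cluster_to_dots(1501, 1000) == 2
        assert cluster_to_dots(100, 1000) == 1  # never below one dot

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cluster_to_dots(-5, 1000)
        with pytest.raises(ValueError, match="positive"):
            cluster_to_dots(1000, 0)


class TestCountDotsPerCell:
    def _synthetic_spots(self, masks, per_cell):
        """Spot table placed at cell centroids, bypassing detection."""
        from scipy import ndimage

        rows = []
        for cid, (n_single, cluster_ints) in per_cell.items():
            cy, cx = ndimage.center_of_mass(masks == cid)
            for k in range(n_single):
                rows.append(
                    {"y": cy + k * 0.1, "x": cx, "intensity": 1000.0,
                     "is_cluster": False}
                )
            for ci in cluster_ints:
                rows.append(
                    {"y": cy, "x": cx + 0.2, "intensity": ci, "is_cluster": True}
                )
        return pd.DataFrame(rows)

    def test_four_singles_negative_five_positive(self):
        masks = grid_cell_masks((80, 80), 2, 15)
        spots = self._synthetic_spots(masks, {1: (4, []), 2: (5, [])})
        recs, _ = count_dots_per_cell(masks, spots, ref_intensity=1000.0)
        by_id = {r.cell_id: r for r in recs}
        assert not by_id[1].positive and by_id[1].dots_total == 4
        assert by_id[2].positive and by_id[2].dots_total == 5

    def test_cluster_equivalents_add(self):
        """2 singles + one 4-equivalent cluster = 6 dots, positive."""
        masks = grid_cell_masks((60, 60), 1, 15)
        spots = self._synthetic_spots(masks, {1: (2, [4000.0])})
        recs, _ = count_dots_per_cell(masks, spots, ref_intensity=1000.0)
        assert recs[0].dots_total == 6
        assert recs[0].positive

    def test_background_spots_counted_separately(self):
        masks = grid_cell_masks((60, 60), 1, 10)
        spots = pd.DataFrame(
            [{"y": 1.0, "x": 1.0, "intensity": 1000.0, "is_cluster": False}]
        )
        recs, n_bg = count_dots_per_cell(masks, spots, ref_intensity=1000.0)
        assert n_bg == 1
        assert recs[0].dots_total == 0

    def test_uncorrected_fallback_flagged(self):
        masks = grid_cell_masks((60, 60), 1, 15)
        spots = self._synthetic_spots(masks, {1: (2, [4000.0])})
        with pytest.warns(UserWarning, match="correction disabled"):
            recs, _ = count_dots_per_cell(masks, spots)  # only 2 singles
        assert not recs[0].corrected
        assert recs[0].dots_total == 3  # cluster counts 1 uncorrected

    def test_total_intensity_conserved_noise_free(self):
        """Cluster correction conserves signal: sum(dots_total) x ref is
        within 10% of the summed spot intensities on a noise-free slide."""
        truth = t.make_rnascope_truth(
            shape=(400, 400), n_cells=25, cell_radius_px=25, mean_dots=8,
            snr=0, seed=13,
        )
        channels, truth = t.gen_rnascope_image(truth, (400, 400), PX, seed=14)
        sub = rolling_ball(channels["probe"], 1.0, PX)
        spots = detect_spots(sub, PX)
        ref = single_dot_intensity(spots)
        recs, _ = count_dots_per_cell(truth.cell_masks, spots, ref_intensity=ref)
        total_dots = sum(r.dots_total for r in recs)
        assert total_dots * ref == pytest.approx(spots["intensity"].sum(), rel=0.10)

    def test_rescaling_invariance(self):
        """dots_total is invariant under multiplicative rescaling of the
        probe channel (the intensity ratio cancels)."""
        truth = t.make_rnascope_truth(
            shape=(300, 300), n_cells=16, cell_radius_px=25, mean_dots=8,
            snr=0, seed=15,
        )
        channels, truth = t.gen_rnascope_image(truth, (300, 300), PX, seed=16)
        counts = {}
        for scale in (1.0, 7.3):
            sub = rolling_ball(channels["probe"] * scale, 1.0, PX)
            spots = detect_spots(sub, PX)
            recs, _ = count_dots_per_cell(truth.cell_masks, spots, pixel_size_um=PX)
            counts[scale] = [r.dots_total for r in recs]
        assert counts[1.0] == counts[7.3]

    def test_positivity_threshold_monotone(self):
        """Raising the positivity threshold never increases the positive
        fraction."""
        rng = np.random.default_rng(17)
        dots = rng.poisson(6, 50)
        fractions = [(dots >= thr).mean() for thr in range(1, 12)]
        assert all(a >= b for a, b in zip(fractions[:-1], fractions[1:]))


class TestFractionPositive:
    @staticmethod
    def _records(fracs, n=10):
        recs = []
        cid = 1
        grouping = {}
        for g, f in enumerate(fracs):
            for k in range(n):
                recs.append(
                    t.CellDotRecord(
                        cell_id=cid, area_um2=100.0,
                        n_single_dots=8 if k < f * n else 0,
                        n_cluster_equivalents=0,
                    )
                )
                grouping[cid] = f"animal{g}"
                cid += 1
        return recs, grouping

    def test_single_group_fraction(self):
        recs, _ = self._records([0.7])
        per_group, summary = fraction_positive(recs)
        assert per_group["fraction"].iloc[0] == pytest.approx(0.7)

    def test_mean_and_sem_over_animals(self):
        recs, grouping = self._records([0.6, 0.8])
        per_group, summary = fraction_positive(recs, grouping)
        assert summary["mean"].iloc[0] == pytest.approx(0.7)
        assert summary["sem"].iloc[0] == pytest.approx(0.1)

    def test_cohort_positivity_recovered(self):
        """6 virtual animals x 100 cells at true positivity 0.75: the group
        mean lands inside the aggregate binomial 95% band."""
        rng = np.random.default_rng(18)
        recs, grouping = [], {}
        cid = 1
        for a in range(6):
            for _ in range(100):
                dots = 8 if rng.random() < 0.75 else 0
                recs.append(
                    t.CellDotRecord(cell_id=cid, area_um2=100.0,
                                    n_single_dots=dots, n_cluster_equivalents=0)
                )
                grouping[cid] = f"animal{a}"
                cid += 1
        _, summary = fraction_positive(recs, grouping)
        half_width = 1.96 * np.sqrt(0.75 * 0.25 / 600)
        assert abs(summary["mean"].iloc[0] - 0.75) < 2 * half_width

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            fraction_positive([])
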