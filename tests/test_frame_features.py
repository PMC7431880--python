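"""Per-frame morphometric and QPI features."""

import numpy as np
import pandas as pd
import pytest

from phasetrack.frame_features import (
    SERIES_FEATURE_NAMES,
    build_series,
    frame_feature_table,
    morphometric_features,
    qpi_features,
)
from phasetrack.recon import PhaseImage
from phasetrack.tracking import CellTrack


def disk_labels(radius=20, pad=5):
    n = 2 * (radius + pad)
    rr = np.hypot(*np.meshgrid(*(np.arange(n) - n / 2,) * 2, indexing="ij"))
    return (rr <= radius).astype(np.int32)


class TestMorphometric:
    def test_digital_disk(self):
        feats, _ = morphometric_features(disk_labels(), 1)
        # solidity bound reflects the pixelated convex-hull estimator
        assert feats["solidity"] >= 0.95
        assert 0.9 <= feats["roundness"] <= 1.05
        assert feats["eccentricity"] < 0.2

    def test_rectangle_moments(self):
        labels = np.zeros((20, 60), np.int32)
        labels[5:15, 10:50] = 1  # 10 x 40 filled rectangle
        feats, centroid = morphometric_features(labels, 1)
        assert feats["extent"] == 1.0
        # eccentricity of the equivalent second-moment ellipse; discrete
        # pixel-center variance of n columns is (n^2 - 1)/12, so
        # e = sqrt(1 - (10^2 - 1)/(40^2 - 1))
        assert feats["eccentricity"] == pytest.approx(
            np.sqrt(1 - 99 / 1599), abs=1e-12
        )
        assert centroid == pytest.approx((9.5, 29.5))

    def test_convex_region_unit_ratios(self):
        labels = np.zeros((30, 30), np.int32)
        labels[5:25, 8:22] = 1
        feats, _ = morphometric_features(labels, 1)
        assert feats["indentation"] == pytest.approx(1.0, rel=0.02)
        assert feats["solidity"] == pytest.approx(1.0, rel=0.02)

    def test_pixel_size_scaling(self):
        feats1, _ = morphometric_features(disk_labels(), 1, pixel_size_um=1.0)
        feats2, _ = morphometric_features(disk_labels(), 1, pixel_size_um=0.5)
        assert feats2["footprint_area_um2"] == pytest.approx(feats1["footprint_area_um2"] / 4)
        assert feats2["perimeter_um"] == pytest.approx(feats1["perimeter_um"] / 2)
        assert feats2["solidity"] == feats1["solidity"]

    def test_translation_and_rotation_invariance(self):
        labels = np.zeros((60, 60), np.int32)
        labels[10:25, 20:45] = 1
        shifted = np.roll(labels, (7, -5), axis=(0, 1))
        rotated = np.rot90(labels).copy()
        base, _ = morphometric_features(labels, 1)
        for variant in (shifted, rotated):
            other, _ = morphometric_features(variant, 1)
            for name in ("solidity", "roundness", "indentation", "eccentricity", "extent"):
                assert other[name] == pytest.approx(base[name], rel=0.02)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            morphometric_features(np.zeros((8, 8), np.int32), 1)


class TestQpi:
    def test_uniform_region_degenerate_stats(self):
        labels = np.zeros((8, 8), np.int32)
        labels[2:6, 2:6] = 1
        phase = PhaseImage(np.full((8, 8), 1.5))
        feats = qpi_features(labels, 1, phase)
        assert feats["total_phase"] == pytest.approx(16 * 1.5)
        assert feats["phase_variance"] == 0.0
        assert feats["phase_skewness"] == 0.0 and feats["phase_kurtosis"] == 0.0

    def test_hand_computed_four_values(self):
        labels = np.zeros((2, 2), np.int32) + 1
        phase = PhaseImage(np.array([[1.0, 2.0], [3.0, 4.0]]))
        feats = qpi_features(labels, 1, phase)
        assert feats["mean_phase"] == 2.5
        assert feats["median_phase"] == 2.5
        assert feats["phase_variance"] == pytest.approx(1.25)
        assert feats["phase_std"] == pytest.approx(np.sqrt(1.25))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.5, 2.0, (10, 10))
        labels = np.ones((10, 10), np.int32)
        one = qpi_features(labels, 1, PhaseImage(values))
        two = qpi_features(labels, 1, PhaseImage(2 * values))
        for name in ("total_phase", "mean_phase", "median_phase", "phase_std"):
            assert two[name] == pytest.approx(2 * one[name])
        assert two["phase_skewness"] == pytest.approx(one["phase_skewness"])
        assert two["phase_kurtosis"] == pytest.approx(one["phase_kurtosis"])


class TestSeries:
    def toy_table(self, n=30):
        rows = []
        for t in range(n):
            row = {"cell_id": 0, "frame": t}
            row.update({name: 1.0 for name in SERIES_FEATURE_NAMES})
            row.update({"centroid_row_px": 5.0, "centroid_col_px": 5.0})
            rows.append(row)
        return pd.DataFrame(rows)

    def toy_track(self, n=30):
        return CellTrack(0, [(t, 1, (5.0, 5.0)) for t in range(n)])

    def test_shape_is_frames_by_features(self):
        series = build_series(self.toy_track(), self.toy_table())
        assert series.values.shape == (30, len(SERIES_FEATURE_NAMES))

    def test_constant_cell_constant_columns(self):
        series = build_series(self.toy_track(), self.toy_table())
        assert np.all(series.values == 1.0)

    def test_missing_frame_rejected(self):
        table = self.toy_table()
        with pytest.raises(ValueError):
            build_series(self.toy_track(n=31), table)

    def test_mesenchymal_eccentricity_trends_up(self, paper_sim_40):
        sim = paper_sim_40
        masks = [m.astype(np.int32) for m in sim.label_masks]
        tracks = [
            CellTrack(
                cid,
                [
                    (t, cid + 1, (row["y_px"], row["x_px"]))
                    for t, row in sim.tracks[sim.tracks["cell_id"] == cid]
                    .set_index("frame")
                    .iterrows()
                ],
            )
            for cid in range(8)  # a handful from each class
        ] + [
            CellTrack(
                cid,
                [
                    (t, cid + 1, (row["y_px"], row["x_px"]))
                    for t, row in sim.tracks[sim.tracks["cell_id"] == cid]
                    .set_index("frame")
                    .iterrows()
                ],
            )
            for cid in range(20, 28)
        ]
        table = frame_feature_table(sim.phase_frames, masks, tracks)
        ecc_idx = SERIES_FEATURE_NAMES.index("eccentricity")
        slopes = {"epithelial": [], "mesenchymal": []}
        class_of = dict(zip(sim.labels["cell_id"], sim.labels["class"]))
        for track in tracks:
            series = build_series(track, table)
            slope = np.polyfit(np.arange(30), series.values[:, ecc_idx], 1)[0]
            slopes[class_of[track.cell_id]].append(slope)
        assert np.mean(slopes["mesenchymal"]) > np.mean(slopes["epithelial"])
        assert np.mean(slopes["mesenchymal"]) > 0
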