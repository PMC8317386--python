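"""SMLM pipeline: fitting, drift, merging, rendering, cluster areas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from centroquant.errors import DomainError, SchemaError, UndefinedValueError
from centroquant.simulate import SmlmSimConfig, render_raw_frames, simulate_smlm
from centroquant.smlm import (
    SuperResImage, cluster_area, correct_drift, fit_events, merge_consecutive,
    object_pixel_nm, render,
)


def loc_row(frame=0, x=0.0, y=0.0, unc=20.0, photons=1000.0, fid=False):
    return {"frame": frame, "x": x, "y": y, "uncertainty": unc,
            "sigma_psf": 190.0, "photons": photons, "merged_id": np.nan,
            "is_fiducial": fid}


class TestGeometry:
    def test_object_plane_pixel(self):
        assert object_pixel_nm(16.0, 111.0) == pytest.approx(144.14, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            object_pixel_nm(0, 111)


class TestFitEvents:
    def test_blank_frames_no_events(self, rng):
        frames = rng.normal(10, 1, size=(5, 32, 32)).clip(0)
        assert len(fit_events(frames, 144.0)) == 0

    def test_non_2d_frames_rejected(self):
        with pytest.raises(SchemaError):
            fit_events(np.zeros((2, 2, 2, 2)), 144.0)

    def test_two_emitters_recovered(self):
        pixel = 144.0
        locs = pd.DataFrame([
            loc_row(0, x=10.5 * pixel, y=16.5 * pixel),
            loc_row(0, x=20.5 * pixel, y=16.5 * pixel),
        ])
        frames = render_raw_frames(locs, (32, 32), pixel, background=5,
                                   read_sigma=1, seed=0)
        fit = fit_events(frames, pixel)
        assert len(fit) == 2
        for x in (10.5 * pixel, 20.5 * pixel):
            d = np.hypot(fit.x - x, fit.y - 16.5 * pixel).min()
            assert d < pixel  # within one raw pixel of truth

    def test_monte_carlo_precision(self, rng):
        """Per-axis RMS error stays within the photon-statistics budget."""
        pixel, spsf, photons, n = 144.0, 1.3 * 144.0, 1000.0, 120
        rows, truth = [], []
        for i in range(n):
            x = (16 + rng.uniform(-0.5, 0.5)) * pixel
            y = (16 + rng.uniform(-0.5, 0.5)) * pixel
            rows.append(loc_row(i, x=x, y=y, photons=photons))
            truth.append((x, y))
        frames = render_raw_frames(pd.DataFrame(rows), (32, 32), pixel,
                                   psf_sigma_nm=spsf, background=10,
                                   read_sigma=2, seed=3)
        fit = fit_events(frames, pixel)
        errs = []
        for i, (x, y) in enumerate(truth):
            sub = fit[fit.frame == i]
            if len(sub) == 1:
                errs.extend([sub.x.iloc[0] - x, sub.y.iloc[0] - y])
        assert len(errs) > 1.5 * n          # most emitters localized
        rms = float(np.sqrt(np.mean(np.square(errs))))
        assert rms <= 2 * spsf / np.sqrt(photons)


class TestDrift:
    def test_zero_drift_is_near_identity(self):
        cfg = SmlmSimConfig(n_frames=300, drift_nm_per_frame=(0, 0), seed=5)
        locs, _ = simulate_smlm(cfg)
        corr, traj = correct_drift(locs)
        assert len(corr) == len(locs)
        assert np.hypot(traj.dx, traj.dy).max() < cfg.sigma_loc_nm
        resid = np.hypot(corr.x - locs.x, corr.y - locs.y)
        assert resid.max() < cfg.sigma_loc_nm

    def test_linear_drift_recovered_within_2nm(self):
        cfg = SmlmSimConfig(n_frames=2000, drift_nm_per_frame=(0.5, 0.0), seed=1)
        locs, truth = simulate_smlm(cfg)
        corr, traj = correct_drift(locs)
        rms = np.sqrt(np.mean((traj.dx - truth.drift.dx.to_numpy()) ** 2
                              + (traj.dy - truth.drift.dy.to_numpy()) ** 2))
        assert rms < 2.0
        mol = corr[~corr.is_fiducial].merge(truth.emitters, on="emitter",
                                            suffixes=("", "_t"))
        scatter = np.sqrt(np.mean((mol.x - mol.x_t) ** 2)
                          + np.mean((mol.y - mol.y_t) ** 2))
        assert scatter == pytest.approx(np.sqrt(2) * cfg.sigma_loc_nm, rel=0.15)

    def test_second_pass_recovers_no_drift(self):
        cfg = SmlmSimConfig(n_frames=500, drift_nm_per_frame=(0.8, -0.3), seed=2)
        locs, _ = simulate_smlm(cfg)
        corr, _ = correct_drift(locs)
        _, traj2 = correct_drift(corr)
        assert np.hypot(traj2.dx, traj2.dy).max() < 2.0

    def test_no_fiducials_raises(self):
        locs = pd.DataFrame([loc_row(0), loc_row(1)])
        with pytest.raises(DomainError):
            correct_drift(locs)


class TestMerge:
    def test_singleton_unchanged(self):
        locs = pd.DataFrame([loc_row(3, x=100, y=200)])
        out = merge_consecutive(locs)
        assert len(out) == 1
        assert out.x.iloc[0] == 100 and out.photons.iloc[0] == 1000

    def test_three_frame_chain_combines(self):
        locs = pd.DataFrame([loc_row(f, x=500.0, y=500.0, unc=12.0,
                                     photons=100.0) for f in (3, 4, 5)])
        out = merge_consecutive(locs, radius_nm=50)
        assert len(out) == 1
        assert out.photons.iloc[0] == pytest.approx(300.0)
        assert out.uncertainty.iloc[0] == pytest.approx(12.0 / np.sqrt(3))
        assert out.frame.iloc[0] == 3

    def test_gap_tolerance(self):
        locs = pd.DataFrame([loc_row(0, x=0, y=0), loc_row(2, x=5, y=0)])
        assert len(merge_consecutive(locs, radius_nm=50, max_gap=1)) == 1
        assert len(merge_consecutive(locs, radius_nm=50, max_gap=0)) == 2

    def test_distant_detections_not_merged(self):
        locs = pd.DataFrame([loc_row(0, x=0, y=0), loc_row(1, x=500, y=0)])
        assert len(merge_consecutive(locs, radius_nm=50)) == 2

    def test_count_never_increases_on_simulated_data(self):
        locs, _ = simulate_smlm(SmlmSimConfig(n_frames=300, seed=3))
        out = merge_consecutive(locs)
        assert len(out) <= len(locs)

    def test_negative_radius_raises(self):
        with pytest.raises(DomainError):
            merge_consecutive(pd.DataFrame([loc_row()]), radius_nm=-1)


class TestRender:
    def test_empty_table_gives_zero_canvas(self):
        img = render(pd.DataFrame(columns=["frame", "x", "y", "uncertainty",
                                           "is_fiducial"]), 144.0, 10, (8, 8))
        assert img.data.shape == (80, 80) and img.data.sum() == 0

    def test_amplitudes_add(self):
        # place on a canvas pixel centre so the unit peak is sampled exactly
        x = (40 + 0.5) * 14.4
        locs = pd.DataFrame([loc_row(0, x=x, y=x), loc_row(1, x=x, y=x)])
        img = render(locs, 144.0, 10, (8, 8))
        assert img.data.max() == pytest.approx(2.0, rel=1e-3)

    def test_gaussian_sum_matches_integral(self):
        locs = pd.DataFrame([loc_row(0, x=720, y=720, unc=20.0)])
        img = render(locs, 144.0, 10, (10, 10))
        expect = 2 * np.pi * (20.0 / 14.4) ** 2
        assert img.data.sum() == pytest.approx(expect, rel=0.01)

    def test_fiducials_excluded(self):
        locs = pd.DataFrame([loc_row(0, x=720, y=720, fid=True)])
        img = render(locs, 144.0, 10, (10, 10))
        assert img.data.sum() == 0


class TestClusterArea:
    def test_counted_pixels_example(self):
        data = np.zeros((3, 3))
        data[0, 0], data[0, 1], data[0, 2] = 1.0, 0.6, 0.4
        img = SuperResImage(data, 14.4)
        m = cluster_area(img, (0, 3 * 14.4, 0, 3 * 14.4), threshold=0.5)
        assert m.n_pixels == 2
        assert m.area_um2 == pytest.approx(2 * 0.0144 ** 2)  # 4.147e-4

    def test_threshold_one_counts_only_max(self):
        data = np.array([[0.2, 1.0], [0.99, 0.5]])
        img = SuperResImage(data, 10.0)
        assert cluster_area(img, (0, 20, 0, 20), 1.0).n_pixels == 1

    def test_scale_invariance(self, rng):
        data = rng.random((16, 16))
        img1 = SuperResImage(data, 14.4)
        img2 = SuperResImage(data * 37.0, 14.4)
        roi = (0, 16 * 14.4, 0, 16 * 14.4)
        assert cluster_area(img1, roi, 0.4).area_um2 == \
            cluster_area(img2, roi, 0.4).area_um2

    def test_all_zero_roi_raises(self):
        img = SuperResImage(np.zeros((4, 4)), 10.0)
        with pytest.raises(UndefinedValueError):
            cluster_area(img, (0, 40, 0, 40), 0.5)

    def test_bad_threshold_raises(self):
        img = SuperResImage(np.ones((4, 4)), 10.0)
        with pytest.raises(DomainError):
            cluster_area(img, (0, 40, 0, 40), 0.0)

    @given(hnp.arrays(np.float64, (12, 12),
                      elements=st.floats(0, 100, allow_nan=False)),
           st.lists(st.floats(0.05, 1.0), min_size=2, max_size=6))
    def test_monotone_nonincreasing_in_threshold(self, data, thresholds):
        if data.max() <= 0:
            data[0, 0] = 1.0
        img = SuperResImage(data, 10.0)
        roi = (0, 120, 0, 120)
        areas = [cluster_area(img, roi, t).area_um2 for t in sorted(thresholds)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))
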