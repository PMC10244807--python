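"""Merging, molecule grouping, rendering and time-course utilities."""

import numpy as np
import pandas as pd
import pytest

from nanofa.locproc import (MergeConfig, RenderConfig, gap_close_and_merge,
                            group_molecule_detections, merge_cutoff_distance,
                            recruitment_timecourse, render,
                            sliding_window_reconstruction)
from nanofa.synthetic import PhotophysicsConfig, simulate_blinking


class TestCutoffDistance:
    def test_printed_values(self):
        assert merge_cutoff_distance(29, 2) == 82   # PALM (mEos3.2)
        assert merge_cutoff_distance(19, 3) == 81   # dSTORM (HMSiR)

    def test_linearity_in_sigma(self):
        assert merge_cutoff_distance(58, 2) == pytest.approx(
            2 * merge_cutoff_distance(29, 2), abs=1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            merge_cutoff_distance(0, 2)
        with pytest.raises(ValueError):
            merge_cutoff_distance(29, 4)


class TestMerging:
    def test_nearby_consecutive_localizations_merge(self, simple_locs):
        out = gap_close_and_merge(simple_locs, MergeConfig(max_distance=82))
        # rows 0,1 (10 nm apart, consecutive) merge; row 3 (frame 5) is a
        # separate on-event; row 2 is 200+ nm away
        assert len(out) == 3
        ev = out[out.n_merged == 2].iloc[0]
        assert ev.photons == pytest.approx(110.0)
        # photon-weighted mean position
        assert ev.x_nm == pytest.approx((100 * 50 + 105 * 60) / 110)

    def test_distant_localizations_stay_separate(self):
        locs = pd.DataFrame({"frame": [0, 1], "x_nm": [0.0, 200.0],
                             "y_nm": [0.0, 0.0], "photons": [1.0, 1.0],
                             "uncertainty_nm": [29.0, 29.0]})
        assert len(gap_close_and_merge(locs, MergeConfig(max_distance=82))) == 2

    def test_on_event_recovery_from_simulation(self):
        rng = np.random.default_rng(1)
        mols = pd.DataFrame({"x_nm": rng.uniform(0, 4000, 1200),
                             "y_nm": rng.uniform(0, 4000, 1200)})
        phot = PhotophysicsConfig(p_bleach=0.72, loc_sigma=15.0)
        locs = simulate_blinking(mols, phot, 10_000, 7)
        merged = gap_close_and_merge(locs, MergeConfig(max_distance=82))
        truth = locs.event_id.nunique()
        assert abs(len(merged) - truth) / truth < 0.02

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        mols = pd.DataFrame({"x_nm": rng.uniform(0, 2000, 300),
                             "y_nm": rng.uniform(0, 2000, 300)})
        locs = simulate_blinking(mols, PhotophysicsConfig(), 5000, 8)
        m1 = gap_close_and_merge(locs, MergeConfig(max_distance=82))
        m2 = gap_close_and_merge(m1, MergeConfig(max_distance=82))
        pd.testing.assert_frame_equal(m1, m2)

    def test_unsorted_input_warns(self, simple_locs):
        with pytest.warns(UserWarning, match="sort"):
            gap_close_and_merge(simple_locs.iloc[::-1],
                                MergeConfig(max_distance=82))


class TestMoleculeGrouping:
    def test_three_events_one_molecule(self):
        ev = pd.DataFrame({"frame": [0, 500, 1500],
                           "x_nm": [0.0, 10.0, 20.0],
                           "y_nm": [0.0, 10.0, 0.0],
                           "photons": [1.0] * 3,
                           "uncertainty_nm": [29.0] * 3})
        g = group_molecule_detections(ev, MergeConfig(max_distance=82,
                                                      cutoff_time=3.0))
        assert list(g.n_detections) == [3]

    def test_cutoff_time_splits_molecules(self):
        # events 5 s apart at a 3-s cutoff (mEos3.2) -> two molecules
        ev = pd.DataFrame({"frame": [0, 5000], "x_nm": [0.0, 5.0],
                           "y_nm": [0.0, 0.0], "photons": [1.0, 1.0],
                           "uncertainty_nm": [29.0, 29.0]})
        g = group_molecule_detections(ev, MergeConfig(max_distance=82,
                                                      cutoff_time=3.0))
        assert len(g) == 2

    def test_mean_detections_recovered_on_sparse_field(self):
        rng = np.random.default_rng(3)
        mols = pd.DataFrame({"x_nm": rng.uniform(0, 12000, 600),
                             "y_nm": rng.uniform(0, 12000, 600)})
        phot = PhotophysicsConfig(p_bleach=0.72, loc_sigma=15.0)
        locs = simulate_blinking(mols, phot, 5000, 9)
        merged = gap_close_and_merge(locs, MergeConfig(max_distance=82))
        g = group_molecule_detections(
            merged, MergeConfig(max_distance=82, cutoff_time=5.0))
        assert abs(g.n_detections.mean() - 1 / 0.72) / (1 / 0.72) < 0.05


class TestRender:
    def test_single_localization_unit_integral(self):
        locs = pd.DataFrame({"x_nm": [500.0], "y_nm": [500.0]})
        img = render(locs, RenderConfig(pixel=10, sigma=29),
                     shape=(100, 100))
        assert img.sum() == pytest.approx(1.0, abs=1e-3)

    def test_coincident_localizations_double_peak(self):
        one = pd.DataFrame({"x_nm": [500.0], "y_nm": [500.0]})
        two = pd.DataFrame({"x_nm": [500.0] * 2, "y_nm": [500.0] * 2})
        cfg = RenderConfig(pixel=10, sigma=29)
        assert render(two, cfg, shape=(100, 100)).max() == pytest.approx(
            2 * render(one, cfg, shape=(100, 100)).max())

    def test_intensity_conservation_interior(self):
        rng = np.random.default_rng(4)
        locs = pd.DataFrame({"x_nm": rng.uniform(300, 700, 500),
                             "y_nm": rng.uniform(300, 700, 500)})
        img = render(locs, RenderConfig(pixel=10, sigma=29),
                     shape=(100, 100))
        assert img.sum() == pytest.approx(500, rel=1e-3)

    def test_aliasing_warning(self):
        locs = pd.DataFrame({"x_nm": [50.0], "y_nm": [50.0]})
        with pytest.warns(UserWarning, match="aliasing"):
            render(locs, RenderConfig(pixel=55.1, sigma=10), shape=(4, 4))


class TestSlidingWindow:
    def _locs(self, n_frames, frame_time=4.0):
        rng = np.random.default_rng(5)
        frames = rng.integers(0, n_frames, 2000)
        frames[-1] = n_frames - 1   # pin the acquisition duration
        return pd.DataFrame({"frame": frames,
                             "x_nm": rng.uniform(0, 500, 2000),
                             "y_nm": rng.uniform(0, 500, 2000)})

    def test_60s_window10_step1_gives_51_frames(self):
        locs = self._locs(15_000)   # 60 s at 250 Hz
        stack = sliding_window_reconstruction(
            locs, RenderConfig(pixel=50, sigma=50), window=10, step=1,
            frame_time=4.0)
        assert stack.shape[0] == 51

    def test_step_equal_window_tiles(self):
        locs = self._locs(15_000)
        stack = sliding_window_reconstruction(
            locs, RenderConfig(pixel=50, sigma=0), window=10, step=10,
            frame_time=4.0)
        assert stack.shape[0] == 6
        assert stack.sum() == pytest.approx(2000, rel=1e-9)

    def test_window_longer_than_acquisition(self):
        locs = self._locs(100)
        with pytest.raises(ValueError, match="window"):
            sliding_window_reconstruction(locs, RenderConfig(50, 50),
                                          window=10, step=1, frame_time=4.0)


class TestRecruitmentTimecourse:
    FA = [(0, 0), (1000, 0), (1000, 1000), (0, 1000)]

    def test_all_in_one_circle(self):
        locs = pd.DataFrame({"frame": np.arange(100),
                             "x_nm": np.full(100, 200.0),
                             "y_nm": np.full(100, 200.0)})
        tc = recruitment_timecourse(locs, [(200, 200, 250), (800, 800, 250)],
                                    self.FA, window=10, frame_time=4.0)
        assert tc.circle_0_pct.iloc[0] == 100.0
        assert tc.circle_1_pct.iloc[0] == 0.0

    def test_csr_matches_area_fraction(self):
        rng = np.random.default_rng(6)
        n = 40_000
        locs = pd.DataFrame({"frame": rng.integers(0, 2500, n),
                             "x_nm": rng.uniform(0, 1000, n),
                             "y_nm": rng.uniform(0, 1000, n)})
        circ = (500, 500, 250)
        tc = recruitment_timecourse(locs, [circ], self.FA, window=10,
                                    frame_time=4.0)
        frac = 100 * np.pi * 125 ** 2 / 1e6
        assert tc.circle_0_pct.mean() == pytest.approx(frac, rel=0.1)

    def test_empty_window_reported_missing(self):
        locs = pd.DataFrame({"frame": [0, 6000], "x_nm": [2000.0, 2000.0],
                             "y_nm": [2000.0, 2000.0]})
        tc = recruitment_timecourse(locs, [(500, 500, 250)], self.FA,
                                    window=10, frame_time=4.0)
        assert np.isnan(tc.circle_0_pct).all()   # nothing inside the FA
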