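"""Dwell-time extraction, summaries, cumulative curves and N/C ratio series."""

import numpy as np
import pandas as pd
import pytest

from nucassembly import fixtures, simulate as sim, timing as tim


def track_from(phases, dt=3.0, track_id=0):
    return tim.TrackAnnotation(
        track_id=track_id,
        frames=pd.DataFrame({
            "time_min": [k * dt for k in range(len(phases))],
            "phase": phases,
        }),
    )


class TestMitoticExitDwell:
    def test_hand_countable_example(self):
        # ana at t=0,3; telo t=6..18; inter at t=21
        phases = ["meta", "ana", "ana"] + ["telo"] * 5 + ["inter"]
        res = tim.mitotic_exit_dwell(track_from(phases))
        # onset at t=3 (first ana); exit at t=24 -> but relative: 21 min
        assert res.duration_min == 21.0
        assert res.ana_min == 6.0
        assert res.telo_min == 15.0
        assert not res.censored

    def test_track_ending_in_telophase_censored(self):
        res = tim.mitotic_exit_dwell(track_from(["meta", "ana", "telo", "telo"]))
        assert res.censored and res.duration_min is None

    def test_no_anaphase_errors(self):
        with pytest.raises(ValueError, match="anaphase"):
            tim.mitotic_exit_dwell(track_from(["inter", "pro", "meta"]))

    def test_point_mass_median_is_21(self):
        cfg = sim.TrackSimConfig(
            n_tracks=1000, frame_interval_min=3.0,
            exit_duration_model={"name": "point", "value": 21.0}, seed=1)
        table, _ = sim.generate_tracks(cfg)
        s = tim.dwell_summary(tim.annotations_from_table(table))
        assert s.median_min == 21.0

    def test_flicker_smoothing_optional(self):
        phases = ["ana", "telo", "ana", "telo", "telo", "inter"]
        rough = tim.mitotic_exit_dwell(track_from(phases, dt=1.0))
        smooth = tim.mitotic_exit_dwell(track_from(phases, dt=1.0), smooth=True)
        assert rough.duration_min == smooth.duration_min == 5.0
        # simultaneous majority vote: the lone telo joins the ana block and
        # the lone ana joins the telo block
        assert (smooth.ana_min, smooth.telo_min) == (2.0, 3.0)
        assert (rough.ana_min, rough.telo_min) == (2.0, 3.0)


class TestDwellSummary:
    def test_hand_countable_median_iqr(self):
        df = pd.DataFrame({
            "track_id": [0, 1, 2], "duration_min": [18.0, 21.0, 24.0],
            "ana_min": [6.0] * 3, "telo_min": [12.0, 15.0, 18.0],
            "censored": [False] * 3,
        })
        s = tim.dwell_summary(df)
        assert s.median_min == 21.0
        assert s.iqr_min == pytest.approx(3.0)  # quartiles 19.5 and 22.5

    def test_single_track(self):
        df = pd.DataFrame({
            "track_id": [0], "duration_min": [27.0], "ana_min": [6.0],
            "telo_min": [21.0], "censored": [False],
        })
        s = tim.dwell_summary(df)
        assert s.median_min == 27.0 and s.iqr_min == 0.0

    def test_all_censored_returns_none(self):
        df = pd.DataFrame({
            "track_id": [0], "duration_min": [None], "ana_min": [6.0],
            "telo_min": [3.0], "censored": [True],
        })
        assert tim.dwell_summary(df) is None

    def test_lognormal_median_within_one_frame_of_closed_form(self):
        model = {"name": "lognormal", "median": 24.0, "sigma": 0.3}
        cfg = sim.TrackSimConfig(n_tracks=5000, frame_interval_min=3.0,
                                 exit_duration_model=model, seed=4)
        table, _ = sim.generate_tracks(cfg)
        s = tim.dwell_summary(tim.annotations_from_table(table))
        assert abs(s.median_min - sim.distribution_median(model)) <= 3.0

    def test_median_recovery_over_seeds(self):
        model = fixtures.EXIT_DURATION_MODELS["control"]
        for seed in range(20):
            cfg = sim.TrackSimConfig(n_tracks=150, frame_interval_min=3.0,
                                     exit_duration_model=dict(model), seed=seed)
            table, _ = sim.generate_tracks(cfg)
            s = tim.dwell_summary(tim.annotations_from_table(table))
            assert abs(s.median_min - sim.distribution_median(model)) <= 3.0


class TestQuantizationBound:
    def test_measured_minus_true_in_zero_one_frame(self):
        cfg = sim.TrackSimConfig(
            n_tracks=300, frame_interval_min=3.0,
            exit_duration_model={"name": "lognormal", "median": 22.0, "sigma": 0.35},
            seed=5)
        table, truth = sim.generate_tracks(cfg)
        tracks = tim.annotations_from_table(table)
        for t in tracks:
            res = tim.mitotic_exit_dwell(t)
            d_true = truth.table.loc[truth.table.track_id == t.track_id,
                                     "duration_true_min"].item()
            assert 0.0 <= res.duration_min - d_true < cfg.frame_interval_min


class TestCumulativeCurve:
    def test_point_mass_single_step(self):
        cfg = sim.TrackSimConfig(
            n_tracks=40, exit_duration_model={"name": "point", "value": 21.0}, seed=6)
        table, _ = sim.generate_tracks(cfg)
        curve = tim.cumulative_interphase_curve(tim.annotations_from_table(table))
        assert curve.percent_interphase.iloc[0] == 0.0
        assert curve.percent_interphase.iloc[-1] == 100.0
        assert list(curve.time_min) == [0.0, 21.0]

    def test_censoring_plateaus_below_100(self):
        cfg = sim.TrackSimConfig(
            n_tracks=100, frame_interval_min=3.0,
            exit_duration_model={"name": "lognormal", "median": 30.0, "sigma": 0.3},
            movie_length_min=33.0, seed=7)
        table, truth = sim.generate_tracks(cfg)
        curve = tim.cumulative_interphase_curve(tim.annotations_from_table(table))
        expected_plateau = 100.0 * (~truth.table.censored).mean()
        assert curve.percent_interphase.iloc[-1] == pytest.approx(expected_plateau)
        assert curve.percent_interphase.is_monotonic_increasing

    def test_equals_brute_force_ecdf(self):
        cfg = sim.TrackSimConfig(
            n_tracks=500, frame_interval_min=3.0,
            exit_duration_model={"name": "lognormal", "median": 20.0, "sigma": 0.3},
            seed=8)
        table, _ = sim.generate_tracks(cfg)
        tracks = tim.annotations_from_table(table)
        curve = tim.cumulative_interphase_curve(tracks)
        durations = sorted(tim.mitotic_exit_dwell(t).duration_min for t in tracks)
        # oracle: percentage of sorted durations <= t, by direct counting
        for _, row in curve.iloc[1:].iterrows():
            oracle = 100.0 * sum(d <= row.time_min for d in durations) / len(durations)
            assert row.percent_interphase == pytest.approx(oracle)


class TestNcRatio:
    def base(self, nuclear, cyto, n=5):
        return pd.DataFrame({
            "time_min": np.arange(n) * 3.0,
            "nuclear_mean": nuclear, "cytoplasm_mean": cyto,
        })

    def test_equal_means_unit_ratio(self):
        nc = tim.nc_ratio_series(self.base([50.0] * 5, [50.0] * 5), onset_time_min=6.0)
        assert np.allclose(nc.nc_ratio, 1.0)
        assert nc.time_since_onset_min.iloc[0] == -6.0

    def test_double_nuclear_ratio_two(self):
        nc = tim.nc_ratio_series(self.base([80.0] * 5, [40.0] * 5), onset_time_min=0.0)
        assert np.allclose(nc.nc_ratio, 2.0)

    def test_zero_cytoplasm_frames_dropped(self):
        nc = tim.nc_ratio_series(self.base([10.0] * 5, [5, 0, 5, 0, 5]), 0.0)
        assert len(nc) == 3 and nc.attrs["n_dropped"] == 2

    def test_import_kinetics_plateau_recovered_within_5pct(self):
        plateau = 3.2
        df = sim.generate_nc_series(n_tracks=6, plateau=plateau, tau_min=10.0,
                                    n_frames=25, noise_sd=2.0, seed=9)
        nc = tim.nc_ratio_series(df, onset_time_min=0.0)
        fit = tim.fit_import_kinetics(nc)
        assert fit["plateau"] == pytest.approx(plateau, rel=0.05)
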