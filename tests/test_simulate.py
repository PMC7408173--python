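"""Generator contracts: exact painting, seed determinism, mask nesting,
void prevalence, and ceiling quantization of track durations."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from nucassembly import simulate as sim


def brute_force_band(mask, width):
    """Per-pixel Euclidean distance to the nearest background pixel, by loops
    over boundary candidates — independent of the EDT used by the package."""
    ys, xs = np.nonzero(~mask)
    bg = np.stack([ys, xs], axis=1)
    band = np.zeros_like(mask)
    fys, fxs = np.nonzero(mask)
    for y, x in zip(fys, fxs):
        d2 = np.min((bg[:, 0] - y) ** 2 + (bg[:, 1] - x) ** 2)
        if d2 <= width**2:
            band[y, x] = True
    return band


class TestCellField:
    def test_zero_noise_painted_means_exact(self, noiseless_field):
        (fld, truth), cfg = noiseless_field
        assert len(truth.nuclei) == 3
        for i in range(1, 4):
            mask = truth.label_map == i
            assert fld["chromatin"][mask].mean() == cfg.chromatin_level

    def test_nuclei_disjoint_and_voids_nested(self):
        cfg = sim.ImageSimConfig(
            field_size_px=(512, 512), n_nuclei=5, seed=11,
            nucleoli_per_nucleus={"name": "point", "value": 2},
        )
        _, truth = sim.generate_cell_field(cfg)
        # labels partition: one positive label per nucleus, no overlap possible
        # in a single raster; check voids nest inside their parent nucleus
        for _, v in truth.voids.iterrows():
            vmask = truth.void_label_map == v.void_id
            parent = truth.label_map == v.nucleus_id
            assert not np.any(vmask & ~parent)

    def test_seed_determinism_bit_identical(self):
        cfg = sim.ImageSimConfig(field_size_px=(320, 320), n_nuclei=3, seed=42)
        f1, t1 = sim.generate_cell_field(cfg)
        f2, t2 = sim.generate_cell_field(cfg)
        for c in f1.channel_names:
            assert np.array_equal(f1[c], f2[c])
        assert np.array_equal(t1.label_map, t2.label_map)

    def test_different_seeds_differ(self):
        base = dict(field_size_px=(320, 320), n_nuclei=3)
        _, t1 = sim.generate_cell_field(sim.ImageSimConfig(seed=1, **base))
        _, t2 = sim.generate_cell_field(sim.ImageSimConfig(seed=2, **base))
        c1 = t1.nuclei[["center_y", "center_x"]].to_numpy()
        c2 = t2.nuclei[["center_y", "center_x"]].to_numpy()
        assert not np.allclose(c1, c2)

    def test_band_mean_matches_brute_force_oracle(self):
        cfg = sim.ImageSimConfig(
            field_size_px=(180, 180), n_nuclei=1, camera_noise_sd=0, seed=3,
            nucleus_radius_px=(40.0, 0.0), shape_irregularity=0.0,
            marker_specs=[sim.MarkerSpec("m", nuclear_mean=50.0, cytoplasm_mean=5.0,
                                         periphery_enrichment=2.0)],
        )
        fld, truth = sim.generate_cell_field(cfg)
        mask = truth.label_map == 1
        band = brute_force_band(mask, cfg.band_width_px)
        oracle_mean = fld["m"][band].mean()
        recorded = truth.region_means.query(
            "channel == 'm' and region == 'periphery_band'"
        )["mean"].item()
        assert oracle_mean == pytest.approx(recorded, abs=1e-9)
        assert recorded == pytest.approx(100.0)  # 2 x interior mean

    def test_impossible_packing_reports_parameter(self):
        cfg = sim.ImageSimConfig(field_size_px=(200, 200), n_nuclei=10,
                                 nucleus_radius_px=(60.0, 0.0))
        with pytest.raises(ValueError, match="n_nuclei|field_size"):
            sim.generate_cell_field(cfg)

    def test_radius_too_small_rejected(self):
        with pytest.raises(ValueError, match="25"):
            sim.ImageSimConfig(nucleus_radius_px=(20.0, 1.0)).validate()


class TestInvitro:
    def test_prevalence_zero_means_no_voids(self):
        cfg = sim.ImageSimConfig(field_size_px=(256, 256), n_nuclei=10,
                                 nucleus_radius_px=(45.0, 4.0),
                                 hole_prevalence=0.0, seed=4)
        _, truth = sim.generate_invitro_nuclei(cfg)
        assert not truth.table.has_hole.any()
        assert truth.table.void_area_px2.eq(0).all()

    def test_hole_geometry_matches_disk_area(self):
        cfg = sim.ImageSimConfig(field_size_px=(256, 256), n_nuclei=6,
                                 nucleus_radius_px=(45.0, 0.0),
                                 hole_prevalence=1.0,
                                 hole_radius_px={"name": "point", "value": 8.0},
                                 camera_noise_sd=0, seed=5)
        _, truth = sim.generate_invitro_nuclei(cfg)
        assert truth.table.has_hole.all()
        for area in truth.table.void_area_px2:
            assert area == pytest.approx(math.pi * 64, rel=0.08)

    def test_empirical_prevalence_within_binomial_ci(self):
        p, n = 0.3, 500
        cfg = sim.ImageSimConfig(field_size_px=(192, 192), n_nuclei=n,
                                 nucleus_radius_px=(30.0, 2.0),
                                 hole_prevalence=p,
                                 hole_radius_px={"name": "point", "value": 9.0},
                                 camera_noise_sd=0, seed=6)
        _, truth = sim.generate_invitro_nuclei(cfg)
        k = int(truth.table.has_hole.sum())
        lo, hi = sps.binom.interval(0.95, n, p)
        assert lo <= k <= hi


class TestTracks:
    def test_point_mass_duration_hand_countable(self):
        cfg = sim.TrackSimConfig(
            n_tracks=5, frame_interval_min=3.0,
            exit_duration_model={"name": "point", "value": 21.0}, seed=0,
        )
        table, truth = sim.generate_tracks(cfg)
        for _, grp in table.groupby("track_id"):
            onset = grp.loc[grp.phase == "ana", "time_min"].min()
            first_inter_after = grp.loc[(grp.phase == "inter") & (grp.time_min > onset),
                                        "time_min"].min()
            assert first_inter_after - onset == 21.0
            ana = grp[grp.phase == "ana"]
            assert list(ana.time_min - onset) == [0.0, 3.0]

    def test_quantization_is_ceiling(self):
        cfg = sim.TrackSimConfig(
            n_tracks=200, frame_interval_min=1.0,
            exit_duration_model={"name": "lognormal", "median": 20.0, "sigma": 0.3},
            seed=2,
        )
        table, truth = sim.generate_tracks(cfg)
        for tid, grp in table.groupby("track_id"):
            d_true = truth.table.loc[truth.table.track_id == tid,
                                     "duration_true_min"].item()
            onset = grp.loc[grp.phase == "ana", "time_min"].min()
            exit_t = grp.loc[(grp.phase == "inter") & (grp.time_min > onset),
                             "time_min"].min()
            measured = exit_t - onset
            assert measured >= d_true
            assert measured - d_true < cfg.frame_interval_min
            assert measured == cfg.frame_interval_min * math.ceil(
                d_true / cfg.frame_interval_min)

    def test_montecarlo_median_matches_closed_form(self):
        model = {"name": "lognormal", "median": 19.5, "sigma": 0.25}
        cfg = sim.TrackSimConfig(n_tracks=10_000, frame_interval_min=1.0,
                                 exit_duration_model=model, seed=3)
        table, _ = sim.generate_tracks(cfg)
        meds = []
        for _, grp in table.groupby("track_id"):
            onset = grp.loc[grp.phase == "ana", "time_min"].min()
            exit_t = grp.loc[(grp.phase == "inter") & (grp.time_min > onset),
                             "time_min"].min()
            meds.append(exit_t - onset)
        assert abs(np.median(meds) - sim.distribution_median(model)) <= cfg.frame_interval_min

    def test_phase_order_monotone(self):
        cfg = sim.TrackSimConfig(n_tracks=20, seed=9)
        table, _ = sim.generate_tracks(cfg)
        order = {p: k for k, p in enumerate(["inter", "pro", "prometa", "meta",
                                             "ana", "telo"])}
        for _, grp in table.groupby("track_id"):
            phases = list(grp.sort_values("time_min").phase)
            # strictly one mitotic passage: phases never regress before the
            # final interphase re-entry
            codes = [order[p] for p in phases]
            final_inter = phases[-1] == "inter"
            assert final_inter
            body = codes[:-1]
            assert all(a <= b for a, b in zip(body, body[1:]))

    def test_censoring_at_movie_end(self):
        cfg = sim.TrackSimConfig(
            n_tracks=50, frame_interval_min=3.0,
            exit_duration_model={"name": "lognormal", "median": 30.0, "sigma": 0.3},
            movie_length_min=36.0, seed=8,
        )
        table, truth = sim.generate_tracks(cfg)
        assert truth.table.censored.any() and not truth.table.censored.all()
        censored_ids = set(truth.table.loc[truth.table.censored, "track_id"])
        for tid, grp in table.groupby("track_id"):
            last = grp.sort_values("time_min").phase.iloc[-1]
            assert (last != "inter") == (tid in censored_ids)


def test_nc_series_exact_without_noise():
    df = sim.generate_nc_series(n_tracks=2, plateau=3.0, tau_min=12.0,
                                n_frames=10, noise_sd=0.0, seed=1)
    one = df[df.track_id == 0]
    ratio = one.nuclear_mean / one.cytoplasm_mean
    expected = 1 + 2 * (1 - np.exp(-one.time_min / 12.0))
    assert np.allclose(ratio, expected)
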