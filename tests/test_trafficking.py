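from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mitoaxon import scenario_defaults
from mitoaxon.simulate import generate_timelapse
from mitoaxon.trafficking import (
    CAUDAL,
    ROSTRAL,
    LinkingParams,
    MotilityTrack,
    classify_motile,
    link_tracks,
    segment_timelapse,
    trafficking_summary,
)

INTERVAL = 1.97


def _detections(trajectories, lengths=None, n_frames=50):
    """Build a per-frame object table from {id: position function}."""
    rows = []
    for f in range(n_frames):
        for tid, traj in trajectories.items():
            x = traj(f)
            if x is None:
                continue
            rows.append({
                "frame": f, "axon_id": 0, "centroid_x_um": x,
                "length_um": (lengths or {}).get(tid, 2.0),
                "tmrm_mean": 50.0,
            })
    return pd.DataFrame(rows)


def _track(xs, frames=None, motile=None):
    xs = np.asarray(xs, float)
    frames = np.arange(xs.size) if frames is None else np.asarray(frames)
    t = MotilityTrack(0, 0, frames, xs, 2.0, 50.0, INTERVAL)
    t.motile = classify_motile(t) if motile is None else motile
    return t


class TestLinking:
    def test_missing_frame_interval_is_an_error(self):
        with pytest.raises(ValueError):
            link_tracks(_detections({0: lambda f: 10.0}), None)

    def test_static_objects_yield_stationary_tracks(self):
        rng = np.random.default_rng(0)
        dets = _detections({
            i: (lambda x0: lambda f: x0 + rng.normal(0, 0.05))(10.0 + 8 * i)
            for i in range(5)})
        tracks = link_tracks(dets, INTERVAL)
        assert len(tracks) == 5
        assert all(abs(t.net_displacement_um) < 0.5 for t in tracks)
        assert not any(t.motile for t in tracks)

    def test_single_mover_speed_is_half_micron_per_frame(self):
        """0.5 um/frame at 1.97 s/frame is 0.254 um/s."""
        dets = _detections({0: lambda f: 5.0 + 0.5 * f})
        tracks = link_tracks(dets, INTERVAL)
        assert len(tracks) == 1
        t = tracks[0]
        assert t.motile
        assert t.mean_speed_um_s == pytest.approx(0.5 / 1.97, rel=0.02)
        assert t.direction == ROSTRAL

    def test_crossing_movers_keep_their_lengths(self):
        """Two objects crossing at matched speeds keep identity via the
        conserved-length tie-break."""
        dets = _detections(
            {0: lambda f: 10.0 + 0.8 * f, 1: lambda f: 50.0 - 0.8 * f},
            lengths={0: 1.2, 1: 4.0})
        tracks = link_tracks(dets, INTERVAL,
                             LinkingParams(repair=False))
        big = [t for t in tracks if t.n_frames >= 20]
        assert len(big) == 2
        by_dir = {t.direction: t for t in big}
        assert by_dir[ROSTRAL].length_um == pytest.approx(1.2, abs=0.3)
        assert by_dir[CAUDAL].length_um == pytest.approx(4.0, abs=0.3)


class TestMotilityClassification:
    def test_zero_net_displacement_is_not_motile(self):
        assert not classify_motile(_track(np.full(50, 7.0), motile=False))

    def test_threshold_is_inclusive_at_two_microns(self):
        xs = np.linspace(0.0, 2.0, 50)
        assert classify_motile(_track(xs, motile=False))
        xs = np.linspace(0.0, 1.9, 50)
        assert not classify_motile(_track(xs, motile=False))

    def test_short_tracks_never_motile(self):
        assert not classify_motile(_track([0, 1, 2, 3, 4], motile=False))


class TestSummary:
    def test_zero_axon_length_is_an_error(self):
        with pytest.raises(ValueError):
            trafficking_summary([], 0.0)

    def test_no_motile_tracks_flags_undefined_fractions(self):
        tracks = [_track(np.full(50, 5.0), motile=False)]
        s = trafficking_summary(tracks, 100.0)
        assert s.motile_per_100um == 0.0
        assert s.rostral_fraction is None
        assert s.mean_speed_um_s is None

    def test_track_invariants(self, naive_movie):
        _, _, _, tracks = naive_movie
        for t in tracks:
            assert abs(t.net_displacement_um) <= t.path_length_um + 0.3
            assert t.mean_speed_um_s >= 0
            if not t.motile:
                assert t.direction is None


class TestKymograph:
    def test_png_written(self, tmp_path):
        from mitoaxon.trafficking import plot_kymograph
        dets = _detections({0: lambda f: 5.0 + 0.5 * f,
                            1: lambda f: 40.0})
        tracks = link_tracks(dets, INTERVAL)
        out = tmp_path / "kymo.png"
        plot_kymograph(dets, 0, out, tracks)
        assert out.stat().st_size > 0


class TestRecoveryOnScenarios:
    def test_naive_density_within_tolerance(self, naive_movie):
        cfg, _, truth, tracks = naive_movie
        s = trafficking_summary(tracks, cfg.total_axon_length_um)
        gt_density = 100.0 * truth.mitochondria["motile"].sum() \
            / cfg.total_axon_length_um
        assert s.motile_per_100um == pytest.approx(gt_density, rel=0.2)

    def test_speed_recovery_within_ten_percent(self, naive_movie):
        cfg, _, _, tracks = naive_movie
        s = trafficking_summary(tracks, cfg.total_axon_length_um)
        assert s.n_motile >= 20
        assert s.mean_speed_um_s == pytest.approx(cfg.speed_mean_um_s,
                                                  rel=0.10)

    def test_direction_symmetry_under_balanced_generator(self):
        """With a 50/50 generator the recovered rostral fraction lies in
        the binomial 95% interval around one half."""
        cfg = replace(scenario_defaults("naive"), rostral_fraction=0.5)
        movie, truth = generate_timelapse(cfg, seed=2)
        per_frame = segment_timelapse(movie, axon_y_um=truth.axon_y_um)
        tracks = link_tracks(per_frame, movie.frame_interval_s)
        s = trafficking_summary(tracks, cfg.total_axon_length_um)
        half_width = 1.96 * np.sqrt(0.25 / s.n_motile)
        assert abs(s.rostral_fraction - 0.5) <= half_width

    def test_onset_motile_pool_shifts_below_small_class(self, onset_movie,
                                                        naive_movie):
        """At onset the motile pool gains a large sub-1.5 um component
        and is shorter than the control motile pool, which contains no
        sub-1.5 um mitochondria at all."""
        cfg_on, _, _, tracks_on = onset_movie
        cfg_na, _, _, tracks_na = naive_movie
        on = trafficking_summary(tracks_on, cfg_on.total_axon_length_um)
        na = trafficking_summary(tracks_na, cfg_na.total_axon_length_um)
        assert (on.motile_lengths_um < 1.5).mean() >= 0.1
        assert (on.motile_lengths_um < 1.5).mean() \
            > (na.motile_lengths_um < 1.5).mean()
        assert np.median(on.motile_lengths_um) \
            < np.median(na.motile_lengths_um)
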