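from dataclasses import replace

import numpy as np
import pytest

from mitoaxon import scenario_defaults
from mitoaxon.scenarios import SMALL_CLASS
from mitoaxon.simulate import (
    CFP_MITO_AMP,
    GroundTruth,
    generate_field,
    generate_timelapse,
)


class TestDeterminism:
    def test_same_seed_gives_bitwise_identical_fields(self):
        cfg = scenario_defaults("asymptomatic")
        a, ta = generate_field(cfg, seed=5)
        b, tb = generate_field(cfg, seed=5)
        for c in ("CFP", "TMRM"):
            assert np.array_equal(a.channels[c], b.channels[c])
        assert ta.mitochondria.equals(tb.mitochondria)
        assert ta.infiltrates.equals(tb.infiltrates)

    def test_same_seed_gives_identical_movies(self):
        cfg = scenario_defaults("naive")
        m1, t1 = generate_timelapse(cfg, seed=2, n_frames=5)
        m2, t2 = generate_timelapse(cfg, seed=2, n_frames=5)
        assert np.array_equal(m1.frames[-1].channels["CFP"],
                              m2.frames[-1].channels["CFP"])
        assert t1.positions.equals(t2.positions)


class TestGroundTruthInvariants:
    def test_naive_length_range_and_majority(self, naive_still):
        """Control lengths lie in 1.5-13 um with the majority in 1.5-6."""
        _, _, truth, _, _ = naive_still
        lengths = truth.mitochondria["length_um"].to_numpy()
        assert lengths.min() >= 1.5 and lengths.max() <= 13.0
        assert ((lengths >= 1.5) & (lengths <= 6.0)).mean() > 0.5

    def test_depolarized_mass_fraction_matches_config(self):
        """Pooled over >= 50 axons the ground-truth depolarized mass
        fraction is within 2% of the configured value."""
        cfg = scenario_defaults("onset")
        lengths, depol = [], []
        for seed in range(30, 36):  # 6 fields x 12 axons
            _, truth = generate_field(cfg, seed)
            lengths.append(truth.mitochondria["length_um"].to_numpy())
            depol.append(~truth.mitochondria["polarized"].to_numpy())
        lengths = np.concatenate(lengths)
        depol = np.concatenate(depol)
        frac = lengths[depol].sum() / lengths.sum()
        assert frac == pytest.approx(cfg.frac_mass_depolarized, abs=0.02)

    def test_motile_implies_polarized_exhaustively(self):
        cfg = scenario_defaults("relapse")  # half depolarized: strictest
        for seed in (1, 2, 3):
            _, truth = generate_timelapse(cfg, seed, n_frames=2)
            m = truth.mitochondria
            assert m.loc[m["motile"], "polarized"].all()

    def test_every_rendered_object_has_one_record(self, onset_still):
        _, _, truth, _, _ = onset_still
        assert truth.mitochondria["id"].is_unique


class TestRendering:
    def test_zero_mass_scenario_renders_background_only(self):
        cfg = replace(scenario_defaults("naive"), mass_scale=0.0,
                      infiltrate_density=0.0)
        field, truth = generate_field(cfg, seed=1)
        assert len(truth.mitochondria) == 0
        from mitoaxon.morphometry import segment_mitochondria
        objects, _ = segment_mitochondria(field)
        assert len(objects) == 0

    def test_noise_and_psf_free_peak_matches_amplitude(self):
        """Rendering fidelity: without optics the per-object peak CFP
        equals the configured amplitude within 1%."""
        cfg = replace(scenario_defaults("naive"), psf_sigma_um=0.0,
                      read_noise_sd=0.0, poisson_gain=0.0,
                      infiltrate_density=0.0)
        field, truth = generate_field(cfg, seed=4)
        cfp = field.channels["CFP"]
        px = cfg.pixel_size_um
        for row in truth.mitochondria.itertuples():
            r = int(row.y_um / px)
            c = int(row.x_um / px)
            peak = cfp[max(r - 3, 0):r + 4, max(c - 3, 0):c + 4].max()
            base = CFP_MITO_AMP  # axoplasm + offset add a small pedestal
            assert peak >= base * 0.99

    def test_field_too_small_for_axons_raises(self):
        cfg = replace(scenario_defaults("naive"), n_axons=60)
        with pytest.raises(ValueError, match="too small"):
            generate_field(cfg, seed=1)


class TestTimelapse:
    def test_default_protocol_is_50_frames_98_5_s(self):
        cfg = scenario_defaults("onset")
        movie, _ = generate_timelapse(cfg, seed=3)
        assert movie.n_frames == 50
        assert movie.total_span_s == pytest.approx(98.5)
        assert movie.frame_interval_s == pytest.approx(1.97)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError):
            generate_timelapse(scenario_defaults("naive"), seed=1, n_frames=1)

    def test_zero_motile_density_keeps_everything_stationary(self):
        cfg = replace(scenario_defaults("naive"),
                      motile_density_per_100um=0.0)
        _, truth = generate_timelapse(cfg, seed=1, n_frames=10)
        assert not truth.mitochondria["motile"].any()
        span = truth.positions.groupby("id")["x_um"].agg(np.ptp)
        assert span.max() <= 10 * 0.1  # jitter bound per frame

    def test_motile_ground_truth_advances_at_configured_speed(self):
        cfg = scenario_defaults("naive")
        _, truth = generate_timelapse(cfg, seed=6, n_frames=20)
        m = truth.mitochondria.set_index("id")
        pos = truth.positions.pivot(index="frame", columns="id",
                                    values="x_um")
        motile = m.index[m["motile"]][:10]
        for mid in motile:
            drift = np.polyfit(np.arange(20) * 1.97, pos[mid].to_numpy(), 1)[0]
            sign = 1.0 if m.loc[mid, "direction"] == "rostral" else -1.0
            assert drift == pytest.approx(sign * m.loc[mid, "speed_um_s"],
                                          abs=0.02)

    def test_stationary_jitter_bounded_per_frame(self):
        cfg = scenario_defaults("naive")
        _, truth = generate_timelapse(cfg, seed=7, n_frames=10)
        m = truth.mitochondria.set_index("id")
        pos = truth.positions.pivot(index="frame", columns="id",
                                    values="x_um")
        stationary = m.index[~m["motile"]]
        steps = pos[stationary].diff().abs().to_numpy()
        assert np.nanmax(steps) <= 0.2 + 1e-9  # two one-sided jitter bounds
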