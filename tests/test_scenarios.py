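from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from mitoaxon.scenarios import (
    SMALL_CLASS,
    LengthDistribution,
    ScenarioConfig,
    assign_depolarized,
    calibrate_scenarios,
    sample_field_placement,
    scenario_defaults,
)


class TestLengthDistribution:
    def test_moments_match_numeric_integration(self):
        """Closed-form truncated log-normal moments agree with quadrature."""
        d = LengthDistribution(1.8, 0.33, 0.5, 13.0)
        mu, s = np.log(d.median_um), d.sigma_log

        def pdf(x):
            return np.exp(-((np.log(x) - mu) ** 2) / (2 * s * s)) / (
                x * s * np.sqrt(2 * np.pi))

        z, _ = quad(pdf, d.min_um, d.max_um)
        p_num, _ = quad(pdf, *SMALL_CLASS)
        m_num, _ = quad(lambda x: x * pdf(x), d.min_um, d.max_um)
        assert d.prob(*SMALL_CLASS) == pytest.approx(p_num / z, rel=1e-8)
        assert d.mean_um == pytest.approx(m_num / z, rel=1e-8)

    def test_quantiles_invert_probabilities(self):
        d = LengthDistribution(3.2, 0.45, 1.5, 13.0)
        q = d.ppf([0.0, 0.25, 0.5, 0.99])
        assert q[0] == pytest.approx(1.5, rel=1e-6)
        assert d.prob(d.min_um, q[1]) == pytest.approx(0.25, abs=1e-9)

    def test_support_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            LengthDistribution(2.0, 0.4, 0.2, 13.0)


class TestScenarioDefaults:
    def test_unknown_stage_names_valid_set(self):
        with pytest.raises(ValueError, match="naive.*relapse"):
            scenario_defaults("chronic")

    @pytest.mark.parametrize("stage,field,value", [
        ("naive", "motile_density_per_100um", 8.58),
        ("naive", "rostral_fraction", 0.56),
        ("adjuvant", "motile_density_per_100um", 10.63),
        ("adjuvant", "frac_mass_depolarized", 0.0),
        ("adjuvant", "polarized_intensity_scale", 1.0),
        ("asymptomatic", "frac_small_depolarized", 0.36),
        ("asymptomatic", "frac_mass_depolarized", 0.28),
        ("asymptomatic", "polarized_intensity_scale", 0.81),
        ("onset", "frac_small_depolarized", 0.54),
        ("onset", "frac_mass_depolarized", 0.40),
        ("onset", "polarized_intensity_scale", 0.61),
        ("onset", "motile_density_per_100um", 2.04),
        ("remission", "frac_mass_depolarized", 0.19),
        ("remission", "motile_density_per_100um", 1.62),
        ("relapse", "polarized_intensity_scale", 0.59),
    ])
    def test_locked_stage_endpoints(self, stage, field, value):
        assert getattr(scenario_defaults(stage), field) == pytest.approx(value)

    def test_fraction_and_support_invariants(self):
        for stage in ("naive", "adjuvant", "asymptomatic", "onset",
                      "remission", "relapse"):
            cfg = scenario_defaults(stage)
            for name in ("frac_small_depolarized", "frac_mass_depolarized",
                         "depolarized_other_prob", "rostral_fraction"):
                assert 0.0 <= getattr(cfg, name) <= 1.0
            d = cfg.length_distribution
            assert 0.5 <= d.min_um < d.max_um <= 13.0
            assert cfg.pixel_size_um > 0
            assert cfg.speed_mean_um_s >= 0 and cfg.speed_sd_um_s >= 0

    def test_invalid_fraction_rejected(self):
        cfg = scenario_defaults("onset")
        with pytest.raises(ValueError):
            replace(cfg, rostral_fraction=1.2)


class TestCalibration:
    def test_ground_truth_hits_all_endpoints(self):
        """Sampled ground truth reproduces every locked stage endpoint
        (depolarized fractions, capacity ratios, small-class increase)
        within 1%."""
        report = calibrate_scenarios()
        assert report.passed
        table = report.table.set_index(["stage", "endpoint"])
        onset_cap = table.loc[("onset", "capacity_ratio_vs_naive"),
                              "achieved"]
        assert onset_cap == pytest.approx(0.19, rel=0.02)
        rem_cap = table.loc[("remission", "capacity_ratio_vs_naive"),
                            "achieved"]
        assert rem_cap == pytest.approx(0.52, rel=0.02)

    def test_adjuvant_capacity_ratio_to_itself_is_one(self):
        cfg = scenario_defaults("adjuvant")
        cap = (cfg.mass_per_100um * (1 - cfg.frac_mass_depolarized)
               * cfg.polarized_intensity_scale)
        assert cap / cap == 1.0


class TestGroundTruthSampling:
    def test_placement_respects_geometry(self):
        rng = np.random.default_rng(0)
        d = LengthDistribution(3.2, 0.45, 1.5, 13.0)
        centers, lengths, axons = sample_field_placement(
            rng, d, 45.0, 102.4, 4, min_gap_um=1.2)
        assert np.all(centers - lengths / 2 >= 0)
        assert np.all(centers + lengths / 2 <= 102.4)
        for a in range(4):
            sel = axons == a
            order = np.argsort(centers[sel])
            left = (centers[sel] - lengths[sel] / 2)[order]
            right = (centers[sel] + lengths[sel] / 2)[order]
            assert np.all(left[1:] - right[:-1] >= 1.2 - 1e-9)

    def test_depolarization_assignment_matches_fractions(self):
        rng = np.random.default_rng(1)
        lengths = LengthDistribution(1.8, 0.33).ppf(rng.uniform(size=4000))
        depol = assign_depolarized(rng, lengths, 0.54, 0.24)
        small = (lengths >= 1.5) & (lengths < 2.5)
        assert depol[small].mean() == pytest.approx(0.54, abs=0.01)
        assert depol[~small].mean() == pytest.approx(0.24, abs=0.01)
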