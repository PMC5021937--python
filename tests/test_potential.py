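import numpy as np
import pandas as pd
import pytest

from mitoaxon.potential import (
    DEPOLARIZED,
    POLARIZED,
    AxonalPotential,
    PolarizationParams,
    axonal_potential,
    capacity_index,
    classify_polarization,
    detect_infiltrates,
    estimate_background,
    intensity_metric,
    measure_amplitudes,
)
from mitoaxon.simulate import ImagingField


def _objects(tmrm_means, lengths=None, classes=None):
    n = len(tmrm_means)
    df = pd.DataFrame({
        "tmrm_mean": tmrm_means,
        "length_um": lengths if lengths is not None else np.ones(n),
    })
    if classes is not None:
        df["polarization_class"] = classes
    return df


class TestClassification:
    def test_object_at_background_mean_is_depolarized(self):
        params = PolarizationParams(10.0, 2.0)
        out = classify_polarization(_objects([10.0]), params)
        assert out["polarization_class"].iloc[0] == DEPOLARIZED

    def test_threshold_boundary_is_inclusive(self):
        params = PolarizationParams(10.0, 2.0, k_detect=2.0)
        out = classify_polarization(_objects([14.0, 14.0001]), params)
        assert list(out["polarization_class"]) == [DEPOLARIZED, POLARIZED]

    def test_three_sigma_object_is_polarized_at_k2(self):
        params = PolarizationParams(10.0, 2.0, k_detect=2.0)
        out = classify_polarization(_objects([16.0]), params)
        assert out["polarization_class"].iloc[0] == POLARIZED

    def test_missing_background_is_an_error(self):
        with pytest.raises(ValueError):
            classify_polarization(_objects([1.0]), None)

    def test_virtually_all_polarized_in_naive_field(self, naive_still):
        _, field, truth, objects, labels = naive_still
        bg = estimate_background(field, labels, truth.vessel_mask)
        out = classify_polarization(objects, bg)
        frac = (out["polarization_class"] == POLARIZED).mean()
        assert frac >= 0.95


class TestIntensityMetric:
    def test_cv_of_identical_intensities_is_zero(self):
        m = intensity_metric(_objects([20.0, 20.0, 20.0]))
        assert m.cv == 0.0

    def test_two_object_hand_computation(self):
        """Means 10 and 30: mean 20, sample sd 14.14, sd/mean 0.707."""
        m = intensity_metric(_objects([10.0, 30.0]))
        assert m.normalized_mean == pytest.approx(20.0)
        assert m.cv == pytest.approx(0.7071, abs=1e-4)

    def test_zero_polarized_objects_flagged_empty(self):
        m = intensity_metric(_objects([5.0], classes=[DEPOLARIZED]))
        assert m.normalized_mean == 0.0
        assert m.empty

    def test_scaling_leaves_cv_and_scales_mean(self):
        base = _objects([12.0, 18.0, 25.0])
        scaled = _objects([36.0, 54.0, 75.0])
        m0, m3 = intensity_metric(base), intensity_metric(scaled)
        assert m3.cv == pytest.approx(m0.cv, rel=1e-12)
        assert m3.normalized_mean == pytest.approx(3 * m0.normalized_mean)


class TestCapacityIndex:
    def test_product_identity_holds_exactly(self):
        df = _objects([10.0, 20.0, 5.0], lengths=[2.0, 3.0, 5.0],
                      classes=[POLARIZED, POLARIZED, DEPOLARIZED])
        cap = capacity_index(df)
        assert cap.index_value == cap.combined_polarized_length_um \
            * cap.intensity
        assert cap.combined_polarized_length_um == pytest.approx(5.0)

    def test_worked_example_lengths_and_metric(self):
        """Three polarized objects of 2, 3 and 5 um with metric 0.5 give
        combined length 10 um and index 5.0."""
        df = _objects([0.5, 0.5, 0.5], lengths=[2.0, 3.0, 5.0],
                      classes=[POLARIZED] * 3)
        cap = capacity_index(df)
        assert cap.combined_polarized_length_um == pytest.approx(10.0)
        assert cap.index_value == pytest.approx(5.0)

    def test_no_polarized_objects_gives_zero(self):
        df = _objects([1.0], classes=[DEPOLARIZED])
        assert capacity_index(df).index_value == 0.0


class TestAxonalPotential:
    def _field(self, axoplasm, vessel):
        tmrm = np.full((40, 40), axoplasm, dtype=float)
        vessel_mask = np.zeros((40, 40), dtype=bool)
        vessel_mask[:, 30:] = True
        tmrm[:, 30:] = vessel
        cfp = np.zeros_like(tmrm)
        return (ImagingField({"CFP": cfp, "TMRM": tmrm}, 0.2, "naive", 0),
                vessel_mask)

    def test_axoplasm_twice_vessel_gives_ratio_two(self):
        field, vessel = self._field(8.0, 4.0)
        labels = np.zeros((40, 40), dtype=int)
        ap = axonal_potential(field, [2.0, 4.0], vessel, labels)
        assert ap.ratio == pytest.approx(2.0)

    def test_equal_levels_give_ratio_one(self):
        field, vessel = self._field(5.0, 5.0)
        labels = np.zeros((40, 40), dtype=int)
        ap = axonal_potential(field, [2.0], vessel, labels)
        assert ap.ratio == pytest.approx(1.0)

    def test_empty_vessel_mask_instructs_manual_roi(self, onset_still):
        _, field, truth, _, labels = onset_still
        empty = np.zeros_like(truth.vessel_mask)
        with pytest.raises(ValueError, match="ROI"):
            axonal_potential(field, truth.axon_y_um, empty, labels)

    def test_onset_axons_more_depolarized_than_naive(self, onset_still,
                                                     naive_still):
        _, f_on, t_on, _, l_on = onset_still
        _, f_na, t_na, _, l_na = naive_still
        r_on = axonal_potential(f_on, t_on.axon_y_um, t_on.vessel_mask,
                                l_on).ratio
        r_na = axonal_potential(f_na, t_na.axon_y_um, t_na.vessel_mask,
                                l_na).ratio
        assert r_on < r_na


class TestInfiltrateDetection:
    def test_counts_match_ground_truth(self, onset_still):
        _, field, truth, _, labels = onset_still
        n, centroids = detect_infiltrates(field, labels, truth.vessel_mask)
        assert n == truth.infiltrate_count
        assert len(centroids) == n


class TestAmplitudes:
    def test_depolarized_amplitude_near_zero(self, onset_still):
        _, field, truth, objects, labels = onset_still
        bg = estimate_background(field, labels, truth.vessel_mask)
        out = classify_polarization(objects, bg)
        out = measure_amplitudes(field, out, labels, bg,
                                 axon_y_um=truth.axon_y_um)
        dep = out.loc[out["polarization_class"] == DEPOLARIZED, "tmrm_amp"]
        pol = out.loc[out["polarization_class"] == POLARIZED, "tmrm_amp"]
        assert abs(dep.mean()) < 0.2 * pol.mean()
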