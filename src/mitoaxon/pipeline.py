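"""End-to-end orchestration: simulate -> segment -> classify -> (track)
-> summarize -> statistics.

The unit of still analysis is one two-channel field; per-field summaries
feed the statistics layer, and per-batch (per-mouse) pooling of objects
feeds the capacity index.  ``recover_endpoints`` reruns the full
pipeline on the packaged scenarios and returns the recovered study
endpoints; it is the engine behind both the acceptance script and the
``reproduce-paper`` command.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import morphometry, potential, stats, trafficking
from .morphometry import SegmentationParams
from .scenarios import SMALL_CLASS, ScenarioConfig, scenario_defaults
from .simulate import generate_field, generate_timelapse
from .trafficking import LinkingParams

#: Endpoints printed by the source study, for the juxtaposition table of
#: the ``reproduce-paper`` command (recovered vs published).
PUBLISHED_ENDPOINTS = {
    "small_depolarized_asymptomatic_pct": 36.0,
    "mass_depolarized_asymptomatic_pct": 28.0,
    "mass_depolarized_onset_pct": 40.0,
    "intensity_decrease_asymptomatic_pct": 19.0,
    "capacity_decrease_onset_vs_naive_pct": 81.0,
    "capacity_remission_pct_of_normal": 52.0,
    "motile_per_100um_naive": 8.58,
    "motile_per_100um_onset": 2.04,
    "rostral_fraction_controls_pct": 56.0,
    "infiltrate_r2_onset": 0.48,
    "small_count_increase_onset_pct": 104.0,
}

#: Map of acceptance-target ids to endpoint names.
TARGET_NAMES = {
    "t1": "small_depolarized_asymptomatic_pct",
    "t2": "mass_depolarized_asymptomatic_pct",
    "t3": "mass_depolarized_onset_pct",
    "t4": "intensity_decrease_asymptomatic_pct",
    "t5": "capacity_decrease_onset_vs_naive_pct",
    "t6": "capacity_remission_pct_of_normal",
    "t7": "motile_per_100um_naive",
    "t8": "motile_per_100um_onset",
    "t9": "rostral_fraction_controls_pct",
    "t10": "infiltrate_r2_onset",
    "t11": "small_count_increase_onset_pct",
}


def analyze_field(field, axon_y_um, vessel_mask=None,
                  seg_params: SegmentationParams | None = None,
                  mouse_id: int = 0, field_id: int = 0):
    """Segment, classify and summarise one still field.

    Returns ``(objects, labels, summary)`` where objects carry the
    polarization class and ratiometric TMRM amplitude and summary is a
    flat dict (one FieldSummary row).
    """
    objects, labels = morphometry.segment_mitochondria(
        field, seg_params, axon_y_um=axon_y_um)
    n_axons = len(np.atleast_1d(axon_y_um))
    total_axon_um = n_axons * field.shape[1] * field.pixel_size_um
    summary = {
        "stage": field.stage, "mouse_id": mouse_id, "field_id": field_id,
        "n_objects": len(objects),
        "total_axon_length_um": total_axon_um,
    }
    if len(objects) == 0:
        summary.update({
            "median_length_um": np.nan, "mass_per_100um": 0.0,
            "cfp_area_fraction": 0.0, "dep_mass_fraction": np.nan,
            "dep_small_fraction": np.nan, "intensity_mean": np.nan,
            "intensity_cv": np.nan, "capacity_index": 0.0,
            "capacity_per_100um": 0.0, "axonal_ratio": np.nan,
            "infiltrate_count": 0, "small_per_100um": 0.0,
        })
        return objects, labels, summary

    bg = potential.estimate_background(field, labels, vessel_mask)
    objects = potential.classify_polarization(objects, bg)
    objects = potential.measure_amplitudes(field, objects, labels, bg,
                                           axon_y_um=axon_y_um)
    hist = morphometry.length_histogram(objects)
    lengths = objects["length_um"].to_numpy()
    depol = (objects["polarization_class"] == potential.DEPOLARIZED).to_numpy()
    small = (lengths >= SMALL_CLASS[0]) & (lengths < SMALL_CLASS[1])
    metric = potential.intensity_metric(objects, bg)
    cap = potential.capacity_index(objects, bg, total_axon_um)
    mass = morphometry.mass_summary(
        objects, total_axon_um,
        axoplasm_mask=_axoplasm_mask(field, axon_y_um), labels=labels)
    n_inf, _ = potential.detect_infiltrates(field, labels, vessel_mask)
    axratio = np.nan
    if vessel_mask is not None and np.asarray(vessel_mask).any():
        axratio = potential.axonal_potential(
            field, axon_y_um, vessel_mask, labels).ratio
    summary.update({
        "median_length_um": hist.median_um,
        "mass_per_100um": mass.integrated_length_per_100um,
        "cfp_area_fraction": mass.cfp_area_fraction,
        "dep_mass_fraction": lengths[depol].sum() / lengths.sum(),
        "dep_small_fraction": depol[small].mean() if small.any() else np.nan,
        "intensity_mean": metric.normalized_mean,
        "intensity_cv": metric.cv,
        "capacity_index": cap.index_value,
        "capacity_per_100um": cap.per_100um,
        "axonal_ratio": axratio,
        "infiltrate_count": n_inf,
        "small_per_100um": 100.0 * small.sum() / total_axon_um,
    })
    return objects, labels, summary


def _axoplasm_mask(field, axon_y_um, halfwidth_um: float = 0.8):
    px = field.pixel_size_um
    ys = (np.arange(field.shape[0]) + 0.5) * px
    mask = np.zeros(field.shape, dtype=bool)
    for y in np.atleast_1d(axon_y_um):
        mask[np.abs(ys - y) <= halfwidth_um, :] = True
    return mask


@dataclass
class BatchResult:
    """Per-field summaries plus pooled objects of one scenario batch."""

    config: ScenarioConfig
    summaries: pd.DataFrame
    objects: pd.DataFrame

    @property
    def total_axon_length_um(self) -> float:
        return float(self.summaries["total_axon_length_um"].sum())

    def pooled_intensity(self) -> float:
        """Mean ratiometric TMRM amplitude over all polarized objects."""
        pol = self.objects[self.objects["polarization_class"]
                           == potential.POLARIZED]
        return float(pol["tmrm_amp"].mean())

    def pooled_capacity(self) -> float:
        """Combined polarized length times pooled intensity metric."""
        pol = self.objects[self.objects["polarization_class"]
                           == potential.POLARIZED]
        return float(pol["length_um"].sum()) * self.pooled_intensity()

    def pooled_depolarized_mass_pct(self) -> float:
        lengths = self.objects["length_um"].to_numpy()
        dep = (self.objects["polarization_class"]
               == potential.DEPOLARIZED).to_numpy()
        return 100.0 * lengths[dep].sum() / lengths.sum()

    def pooled_small_depolarized_pct(self) -> float:
        lengths = self.objects["length_um"].to_numpy()
        small = (lengths >= SMALL_CLASS[0]) & (lengths < SMALL_CLASS[1])
        dep = (self.objects["polarization_class"]
               == potential.DEPOLARIZED).to_numpy()
        return 100.0 * dep[small].mean()

    def small_per_100um(self) -> float:
        lengths = self.objects["length_um"].to_numpy()
        small = (lengths >= SMALL_CLASS[0]) & (lengths < SMALL_CLASS[1])
        return 100.0 * small.sum() / self.total_axon_length_um


def analyze_batch(stage: str | ScenarioConfig, n_fields: int,
                  base_seed: int = 0, n_mice: int = 4,
                  seg_params: SegmentationParams | None = None
                  ) -> BatchResult:
    """Simulate and analyse a batch of still fields for one scenario."""
    config = (stage if isinstance(stage, ScenarioConfig)
              else scenario_defaults(stage))
    rows, tables = [], []
    for i in range(n_fields):
        field, truth = generate_field(config, base_seed + i + 1)
        objects, _, summary = analyze_field(
            field, truth.axon_y_um, truth.vessel_mask, seg_params,
            mouse_id=i % n_mice, field_id=i)
        rows.append(summary)
        objects = objects.assign(field_id=i)
        tables.append(objects)
    return BatchResult(config, pd.DataFrame(rows),
                       pd.concat(tables, ignore_index=True))


def analyze_movie(config: ScenarioConfig, seed: int,
                  seg_params: SegmentationParams | None = None,
                  link_params: LinkingParams | None = None):
    """Simulate one time-lapse and recover its trafficking summary."""
    movie, truth = generate_timelapse(config, seed)
    per_frame = trafficking.segment_timelapse(movie, seg_params,
                                              axon_y_um=truth.axon_y_um)
    tracks = trafficking.link_tracks(per_frame, movie.frame_interval_s,
                                     link_params)
    summary = trafficking.trafficking_summary(
        tracks, config.total_axon_length_um, link_params)
    return summary, tracks, truth


def analyze_movie_batch(stage: str | ScenarioConfig, n_movies: int,
                        base_seed: int = 0,
                        link_params: LinkingParams | None = None):
    """Trafficking summaries over a batch of movies."""
    config = (stage if isinstance(stage, ScenarioConfig)
              else scenario_defaults(stage))
    link_params = link_params or LinkingParams()
    summaries, all_motile = [], []
    for i in range(n_movies):
        summary, tracks, _ = analyze_movie(config, base_seed + i + 1,
                                           link_params=link_params)
        summaries.append(summary)
        all_motile.extend(
            t for t in tracks
            if t.motile and t.frames[0] <= link_params.start_window_frames
            and t.n_frames >= link_params.min_track_frames)
    return summaries, all_motile


def recover_endpoints(seed: int = 0, n_fields: int = 12, n_movies: int = 6,
                      n_rostral_movies: int = 10, n_corr_fields: int = 30,
                      n_corr_reps: int = 5, stages=None) -> dict:
    """Re-derive every study endpoint from freshly simulated scenarios.

    All randomness descends from ``seed``.  Returns a flat dict of the
    recovered endpoints (keys of :data:`PUBLISHED_ENDPOINTS`) plus the
    per-stage pooled capacity indices under ``capacity_index_<stage>``.
    """
    base = int(seed) * 100_000
    out: dict[str, float] = {}

    batches = {
        s: analyze_batch(s, n_fields, base_seed=base)
        for s in ("naive", "adjuvant", "asymptomatic", "onset",
                  "remission", "relapse")
    }
    asym, onset = batches["asymptomatic"], batches["onset"]
    out["small_depolarized_asymptomatic_pct"] = \
        asym.pooled_small_depolarized_pct()
    out["mass_depolarized_asymptomatic_pct"] = \
        asym.pooled_depolarized_mass_pct()
    out["mass_depolarized_onset_pct"] = onset.pooled_depolarized_mass_pct()
    out["intensity_decrease_asymptomatic_pct"] = stats.percent_change(
        asym.pooled_intensity(), batches["adjuvant"].pooled_intensity())
    out["capacity_decrease_onset_vs_naive_pct"] = stats.percent_change(
        onset.pooled_capacity(), batches["naive"].pooled_capacity())
    out["capacity_remission_pct_of_normal"] = 100.0 * (
        batches["remission"].pooled_capacity()
        / batches["naive"].pooled_capacity())
    out["small_count_increase_onset_pct"] = 100.0 * (
        onset.small_per_100um() / batches["adjuvant"].small_per_100um() - 1.0)
    for s, b in batches.items():
        out[f"capacity_index_{s}"] = b.pooled_capacity()

    # trafficking
    naive_cfg = scenario_defaults("naive")
    naive_sums, naive_motile = analyze_movie_batch(
        "naive", n_rostral_movies, base_seed=base)
    out["motile_per_100um_naive"] = float(np.mean(
        [s.motile_per_100um for s in naive_sums[:n_movies]]))
    onset_sums, _ = analyze_movie_batch("onset", n_movies, base_seed=base)
    out["motile_per_100um_onset"] = float(np.mean(
        [s.motile_per_100um for s in onset_sums]))
    n_rostral = sum(t.direction == trafficking.ROSTRAL for t in naive_motile)
    out["rostral_fraction_controls_pct"] = \
        100.0 * n_rostral / len(naive_motile)
    out["mean_speed_um_s_naive"] = float(np.mean(
        [t.mean_speed_um_s for t in naive_motile]))

    # infiltrate correlation at onset, averaged over replicate field sets
    r2 = []
    for rep in range(n_corr_reps):
        rep_seed = base + 10_000 * (rep + 1)
        b = analyze_batch("onset", n_corr_fields, base_seed=rep_seed)
        res = stats.infiltrate_correlation(b.summaries, "intensity_mean")
        r2.append(res.r_squared)
    out["infiltrate_r2_onset"] = float(np.mean(r2))
    return out


def endpoint_table(recovered: dict) -> pd.DataFrame:
    """Juxtapose recovered endpoints with the published values."""
    rows = []
    for name, published in PUBLISHED_ENDPOINTS.items():
        rows.append({"endpoint": name, "recovered": recovered.get(name),
                     "published": published})
    return pd.DataFrame(rows)
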