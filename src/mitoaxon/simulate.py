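"""Synthetic two-channel confocal field and time-lapse generator.

Renders dorsal-column axons lying horizontally across a 512 x 512 field
(0.2 um/px).  The CFP channel shows every axonal mitochondrion as a
~0.5 um wide capsule; the TMRM channel shows diffuse tissue fluorescence,
bright signal over polarized mitochondria only, a dark blood vessel, and
TMRM-bright perivascular infiltrating cells.  A Gaussian PSF and mixed
Poisson/Gaussian noise are applied after composing the clean scene; the
returned ground truth describes the scene before blur and noise.

Rostral is +x by convention.  Time-lapses move a configured subset of
polarized mitochondria along their axon at per-track speeds; stationary
mitochondria jitter by at most 0.1 um per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .scenarios import (
    FRAME_INTERVAL_S,
    N_FRAMES,
    LengthDistribution,
    ScenarioConfig,
    assign_depolarized,
    sample_field_placement,
)

# Rendering amplitudes (arbitrary detector units).  Only ratios matter
# downstream; the TMRM mitochondrial amplitude is scaled per stage.
CFP_OFFSET = 3.0
CFP_AXOPLASM = 8.0
CFP_MITO_AMP = 120.0
TMRM_OFFSET = 2.0
TMRM_TISSUE = 15.0
TMRM_MITO_AMP = 100.0
TMRM_INFILTRATE_AMP = 150.0
VESSEL_ATTENUATION = 0.05

MITO_WIDTH_UM = 0.5
AXON_HALFWIDTH_UM = 0.8
VESSEL_HALFWIDTH_UM = 2.5
SOMA_RADIUS_UM = 2.2
STATIONARY_JITTER_SD_UM = 0.03
STATIONARY_JITTER_MAX_UM = 0.1


@dataclass
class ImagingField:
    """One two-channel still: CFP and TMRM rasters plus calibration."""

    channels: dict
    pixel_size_um: float
    stage: str
    seed: int

    def __post_init__(self) -> None:
        cfp, tmrm = self.channels["CFP"], self.channels["TMRM"]
        if cfp.shape != tmrm.shape:
            raise ValueError("CFP and TMRM rasters must share a shape")

    @property
    def shape(self):
        return self.channels["CFP"].shape


@dataclass
class TimeLapse:
    """Ordered frames at a fixed interval (default 50 frames / 98.5 s)."""

    frames: list
    frame_interval_s: float

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a time-lapse needs at least two frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_span_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class GroundTruth:
    """Exact scene description, recorded before PSF blur and noise."""

    mitochondria: pd.DataFrame
    infiltrates: pd.DataFrame
    vessel_mask: np.ndarray
    axon_y_um: np.ndarray
    infiltrate_count: int
    intensity_multiplier: float
    median_multiplier: float
    config: ScenarioConfig
    seed: int
    positions: pd.DataFrame | None = None  # per (frame, mito) axial x, movies


# --------------------------------------------------------------------------
# painting primitives
# --------------------------------------------------------------------------

def _paint_capsule(img, x_um, y_um, length_um, amp, pixel_size):
    """Add a horizontal capsule (antialiased edges) onto ``img``."""
    w2 = MITO_WIDTH_UM / 2.0
    half_seg = max(length_um / 2.0 - w2, 0.0)
    ny, nx = img.shape
    margin = w2 + 2 * pixel_size
    c0 = max(int((x_um - half_seg - margin) / pixel_size), 0)
    c1 = min(int((x_um + half_seg + margin) / pixel_size) + 2, nx)
    r0 = max(int((y_um - margin) / pixel_size), 0)
    r1 = min(int((y_um + margin) / pixel_size) + 2, ny)
    if c0 >= c1 or r0 >= r1:
        return
    xs = (np.arange(c0, c1) + 0.5) * pixel_size
    ys = (np.arange(r0, r1) + 0.5) * pixel_size
    dx = np.maximum(np.abs(xs - x_um) - half_seg, 0.0)
    dist = np.hypot(dx[None, :], (ys - y_um)[:, None])
    cover = np.clip((w2 - dist) / pixel_size + 0.5, 0.0, 1.0)
    img[r0:r1, c0:c1] += amp * cover


def _paint_disc(img, x_um, y_um, radius_um, amp, pixel_size):
    ny, nx = img.shape
    margin = radius_um + 2 * pixel_size
    c0 = max(int((x_um - margin) / pixel_size), 0)
    c1 = min(int((x_um + margin) / pixel_size) + 2, nx)
    r0 = max(int((y_um - margin) / pixel_size), 0)
    r1 = min(int((y_um + margin) / pixel_size) + 2, ny)
    if c0 >= c1 or r0 >= r1:
        return
    xs = (np.arange(c0, c1) + 0.5) * pixel_size
    ys = (np.arange(r0, r1) + 0.5) * pixel_size
    dist = np.hypot((xs - x_um)[None, :], (ys - y_um)[:, None])
    cover = np.clip((radius_um - dist) / pixel_size + 0.5, 0.0, 1.0)
    img[r0:r1, c0:c1] += amp * cover


def _axon_tube_mask(shape, axon_y_um, pixel_size,
                    halfwidth_um=AXON_HALFWIDTH_UM):
    ys = (np.arange(shape[0]) + 0.5) * pixel_size
    mask = np.zeros(shape, dtype=bool)
    for y in axon_y_um:
        mask[np.abs(ys - y) <= halfwidth_um, :] = True
    return mask


# --------------------------------------------------------------------------
# scene construction
# --------------------------------------------------------------------------

def _scene_geometry(config: ScenarioConfig, rng):
    ny, nx = config.field_shape
    height_um = ny * config.pixel_size_um
    spacing = height_um / config.n_axons
    if spacing < 2 * AXON_HALFWIDTH_UM + 1.0:
        raise ValueError(
            f"field of {height_um:.0f} um is too small for "
            f"{config.n_axons} axons")
    jitter = rng.uniform(-0.8, 0.8, size=config.n_axons)
    axon_y = (np.arange(config.n_axons) + 0.5) * spacing + jitter
    vessel_x = rng.uniform(15.0, config.axon_length_um - 15.0)
    return axon_y, vessel_x


def _vessel_mask(shape, vessel_x_um, pixel_size):
    xs = (np.arange(shape[1]) + 0.5) * pixel_size
    mask = np.zeros(shape, dtype=bool)
    mask[:, np.abs(xs - vessel_x_um) <= VESSEL_HALFWIDTH_UM] = True
    return mask


def _place_infiltrates(config, rng, axon_y, vessel_x, n_cells):
    """Perivascular somata between axons, non-overlapping."""
    height_um = config.field_shape[0] * config.pixel_size_um
    rows = np.concatenate(([axon_y[0] - (axon_y[1] - axon_y[0]) / 2],
                           (axon_y[:-1] + axon_y[1:]) / 2,
                           [axon_y[-1] + (axon_y[-1] - axon_y[-2]) / 2]))
    rows = rows[(rows > SOMA_RADIUS_UM + 0.5)
                & (rows < height_um - SOMA_RADIUS_UM - 0.5)]
    edge = VESSEL_HALFWIDTH_UM + SOMA_RADIUS_UM + 0.8
    offsets = edge + 5.0 * np.arange(3)
    slots = []
    for y in rows:
        for off in offsets:
            for sgn in (-1.0, 1.0):
                x = vessel_x + sgn * off
                if SOMA_RADIUS_UM < x < config.axon_length_um - SOMA_RADIUS_UM:
                    slots.append((x, y))
    n = min(n_cells, len(slots))
    if n == 0:
        return pd.DataFrame(columns=["x_um", "y_um"])
    chosen = rng.choice(len(slots), size=n, replace=False)
    pts = np.asarray(slots)[chosen] + rng.uniform(-0.8, 0.8, size=(n, 2))
    return pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})


def _build_mito_table(config, rng, axon_y, median_multiplier,
                      intensity_multiplier):
    d = config.length_distribution
    dist = LengthDistribution(
        float(np.clip(d.median_um * median_multiplier,
                      1.05 * d.min_um, 0.5 * d.max_um)),
        d.sigma_log, d.min_um, d.max_um)
    x, lengths, axon_id = sample_field_placement(
        rng, dist, config.mass_per_100um, config.axon_length_um,
        config.n_axons, config.min_gap_um, config.occupancy_correction)
    depol = assign_depolarized(rng, lengths, config.frac_small_depolarized,
                               config.depolarized_other_prob)
    y = axon_y[axon_id] + rng.uniform(-0.15, 0.15, size=x.size)
    # per-mitochondrion brightness heterogeneity around the stage scale
    amp = (TMRM_MITO_AMP * config.polarized_intensity_scale
           * intensity_multiplier * np.exp(rng.normal(0.0, 0.08, size=x.size)))
    amp[depol] = 0.0
    return pd.DataFrame({
        "id": np.arange(x.size),
        "axon_id": axon_id,
        "x_um": x,
        "y_um": y,
        "length_um": lengths,
        "polarized": ~depol,
        "tmrm_amp": amp,
        "motile": False,
        "direction": pd.array([None] * x.size, dtype="object"),
        "speed_um_s": 0.0,
    })


def _field_multipliers(config, rng, n_infiltrates):
    """Per-field couplings between infiltration and the TMRM scene."""
    lam = max(config.infiltrate_density, 1.0)
    z = (n_infiltrates - config.infiltrate_density) / np.sqrt(lam)
    intensity = 1.0
    median = 1.0
    if config.intensity_coupling_amp > 0 or config.intensity_coupling_sd > 0:
        intensity = max(0.2, 1.0 - config.intensity_coupling_amp * z
                        + rng.normal(0.0, config.intensity_coupling_sd))
    if config.length_coupling_amp > 0 or config.length_coupling_sd > 0:
        median = float(np.clip(1.0 - config.length_coupling_amp * z
                               + rng.normal(0.0, config.length_coupling_sd),
                               0.6, 1.6))
    return intensity, median


def _render_clean_static(config, axon_y, vessel_mask, infiltrates, rng):
    """Clean CFP/TMRM background layers common to every frame."""
    shape = config.field_shape
    px = config.pixel_size_um
    cfp = np.full(shape, CFP_OFFSET, dtype=np.float64)
    cfp[_axon_tube_mask(shape, axon_y, px)] += CFP_AXOPLASM
    tmrm = np.full(shape, TMRM_OFFSET, dtype=np.float64)
    tissue = np.full(shape, TMRM_TISSUE * config.axoplasm_intensity_scale)
    tissue[vessel_mask] *= VESSEL_ATTENUATION
    tmrm += tissue
    for row in infiltrates.itertuples():
        _paint_disc(tmrm, row.x_um, row.y_um, SOMA_RADIUS_UM,
                    TMRM_INFILTRATE_AMP * np.exp(rng.normal(0.0, 0.1)), px)
    return cfp, tmrm


def _render_mito_layers(config, mitos, x_positions):
    shape = config.field_shape
    px = config.pixel_size_um
    cfp = np.zeros(shape, dtype=np.float64)
    tmrm = np.zeros(shape, dtype=np.float64)
    for x, y, length, amp in zip(x_positions, mitos["y_um"].to_numpy(),
                                 mitos["length_um"].to_numpy(),
                                 mitos["tmrm_amp"].to_numpy()):
        _paint_capsule(cfp, x, y, length, CFP_MITO_AMP, px)
        if amp > 0:
            _paint_capsule(tmrm, x, y, length, amp, px)
    return cfp, tmrm


def _blur(img, config):
    sigma_px = config.psf_sigma_um / config.pixel_size_um
    return gaussian_filter(img, sigma_px) if sigma_px > 0 else img


def _add_noise(img, config, rng):
    gain = config.poisson_gain
    if gain > 0:
        img = rng.poisson(np.maximum(img, 0.0) / gain) * gain
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    return img.astype(np.float32)


def _apply_optics_and_noise(clean, config, rng):
    return _add_noise(_blur(clean, config), config, rng)


# --------------------------------------------------------------------------
# public generators
# --------------------------------------------------------------------------

def _make_scene(config: ScenarioConfig, seed: int):
    """Everything deterministic that stills and movies share."""
    ss = np.random.SeedSequence((config.seed, int(seed)))
    rng_scene, rng_noise, rng_motion = [
        np.random.default_rng(s) for s in ss.spawn(3)]
    axon_y, vessel_x = _scene_geometry(config, rng_scene)
    n_inf = int(rng_scene.poisson(config.infiltrate_density))
    infiltrates = _place_infiltrates(config, rng_scene, axon_y, vessel_x,
                                     n_inf)
    n_inf = len(infiltrates)
    mult_int, mult_med = _field_multipliers(config, rng_scene, n_inf)
    mitos = _build_mito_table(config, rng_scene, axon_y, mult_med, mult_int)
    vessel = _vessel_mask(config.field_shape, vessel_x, config.pixel_size_um)
    cfp0, tmrm0 = _render_clean_static(config, axon_y, vessel, infiltrates,
                                       rng_scene)
    truth = GroundTruth(
        mitochondria=mitos, infiltrates=infiltrates, vessel_mask=vessel,
        axon_y_um=axon_y, infiltrate_count=n_inf,
        intensity_multiplier=mult_int, median_multiplier=mult_med,
        config=config, seed=int(seed))
    return truth, (cfp0, tmrm0), rng_noise, rng_motion


def generate_field(config: ScenarioConfig, seed: int = 0):
    """Render one still field.

    Returns
    -------
    (ImagingField, GroundTruth)
        The noisy two-channel raster and the exact pre-noise scene.
    """
    truth, (cfp0, tmrm0), rng_noise, _ = _make_scene(config, seed)
    mito_cfp, mito_tmrm = _render_mito_layers(
        config, truth.mitochondria, truth.mitochondria["x_um"].to_numpy())
    field_img = ImagingField(
        channels={
            "CFP": _apply_optics_and_noise(cfp0 + mito_cfp, config, rng_noise),
            "TMRM": _apply_optics_and_noise(tmrm0 + mito_tmrm, config,
                                            rng_noise),
        },
        pixel_size_um=config.pixel_size_um,
        stage=config.stage_name,
        seed=int(seed),
    )
    return field_img, truth


def _select_motile(config, mitos, rng):
    """Choose the motile subset: polarized only, biased toward short."""
    polarized = np.flatnonzero(mitos["polarized"].to_numpy())
    target = (config.motile_density_per_100um
              * config.total_axon_length_um / 100.0)
    n = int(target) + (rng.uniform() < (target - int(target)))
    n = min(n, polarized.size)
    if n == 0:
        return np.empty(0, dtype=int)
    lengths = mitos["length_um"].to_numpy()[polarized]
    w = np.exp(-(lengths - lengths.min()) / 1.5)
    # weighted sampling without replacement (exponential sort trick)
    keys = rng.exponential(size=polarized.size) / w
    return polarized[np.argsort(keys)[:n]]


def generate_timelapse(config: ScenarioConfig, seed: int = 0,
                       n_frames: int = N_FRAMES,
                       frame_interval_s: float = FRAME_INTERVAL_S):
    """Render a time-lapse movie with trafficking ground truth.

    Motile mitochondria (always polarized, preferentially short) advance
    along their axon at a per-track speed drawn from the configured
    normal distribution, rostral (+x) with the configured probability;
    stationary ones only jitter.  Ground truth includes per-frame axial
    positions for every mitochondrion.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    truth, (cfp0, tmrm0), rng_noise, rng_motion = _make_scene(config, seed)
    mitos = truth.mitochondria
    motile_idx = _select_motile(config, mitos, rng_motion)
    motile = np.zeros(len(mitos), dtype=bool)
    motile[motile_idx] = True
    direction = np.where(
        rng_motion.uniform(size=len(mitos)) < config.rostral_fraction,
        1.0, -1.0)
    speed = np.clip(
        rng_motion.normal(config.speed_mean_um_s, config.speed_sd_um_s,
                          size=len(mitos)), 0.05, None)
    speed[~motile] = 0.0
    mitos["motile"] = motile
    mitos["direction"] = np.where(
        motile, np.where(direction > 0, "rostral", "caudal"), None)
    mitos["speed_um_s"] = speed

    x0 = mitos["x_um"].to_numpy()
    jitter = np.clip(
        rng_motion.normal(0.0, STATIONARY_JITTER_SD_UM,
                          size=(n_frames, len(mitos))),
        -STATIONARY_JITTER_MAX_UM, STATIONARY_JITTER_MAX_UM)
    t = np.arange(n_frames)[:, None] * frame_interval_s
    x_t = x0[None, :] + motile[None, :] * direction[None, :] * speed[None, :] * t
    x_t = x_t + jitter

    cfp0_b, tmrm0_b = _blur(cfp0, config), _blur(tmrm0, config)
    frames = []
    pos_records = []
    for f in range(n_frames):
        mito_cfp, mito_tmrm = _render_mito_layers(config, mitos, x_t[f])
        frames.append(ImagingField(
            channels={
                "CFP": _add_noise(cfp0_b + _blur(mito_cfp, config), config,
                                  rng_noise),
                "TMRM": _add_noise(tmrm0_b + _blur(mito_tmrm, config), config,
                                   rng_noise),
            },
            pixel_size_um=config.pixel_size_um,
            stage=config.stage_name,
            seed=int(seed),
        ))
        pos_records.append(pd.DataFrame({
            "frame": f, "id": mitos["id"], "x_um": x_t[f]}))
    truth.positions = pd.concat(pos_records, ignore_index=True)
    movie = TimeLapse(frames=frames, frame_interval_s=frame_interval_s)
    return movie, truth
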