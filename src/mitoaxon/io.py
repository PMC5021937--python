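"""File formats: multi-page TIFF with calibration metadata, ground-truth
CSV/JSON, and YAML scenario configs.

Rasters travel as multi-page TIFF with the channel axis (CFP, TMRM) and,
for movies, the time axis; pixel size and frame interval are stored as a
JSON document in the TIFF image description and, redundantly, in a
sidecar ``<name>.json`` for readers without metadata support.  Round
trips are lossless (float32 data, exact metadata).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .scenarios import LengthDistribution, ScenarioConfig
from .simulate import ImagingField, TimeLapse

CHANNELS = ("CFP", "TMRM")


def _sidecar(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_field(path, field: ImagingField) -> None:
    """Write one two-channel field as a CYX TIFF with metadata."""
    data = np.stack([field.channels[c] for c in CHANNELS])
    meta = {
        "axes": "CYX",
        "channels": list(CHANNELS),
        "pixel_size_um": field.pixel_size_um,
        "stage": field.stage,
        "seed": field.seed,
    }
    tifffile.imwrite(path, data.astype(np.float32),
                     description=json.dumps(meta))
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _read_meta(path, tif) -> dict:
    desc = tif.pages[0].description
    if desc:
        try:
            meta = json.loads(desc)
            if "pixel_size_um" in meta:
                return meta
        except json.JSONDecodeError:
            pass
    side = _sidecar(path)
    if side.exists():
        return json.loads(side.read_text())
    raise ValueError(
        f"{path}: no calibration metadata in TIFF description and no "
        f"sidecar {side.name}; refusing to guess a pixel size")


def read_field(path) -> ImagingField:
    """Read a field written by :func:`write_field` (or a foreign CYX
    TIFF accompanied by a JSON sidecar with ``pixel_size_um``)."""
    with tifffile.TiffFile(path) as tif:
        meta = _read_meta(path, tif)
        data = tif.asarray()
    channels = meta.get("channels", list(CHANNELS))
    if data.ndim != 3 or data.shape[0] != len(channels):
        raise ValueError(f"{path}: expected CYX data with "
                         f"{len(channels)} channels, got {data.shape}")
    return ImagingField(
        channels={c: data[i] for i, c in enumerate(channels)},
        pixel_size_um=float(meta["pixel_size_um"]),
        stage=meta.get("stage", "unknown"),
        seed=int(meta.get("seed", -1)),
    )


def write_timelapse(path, movie: TimeLapse) -> None:
    """Write a movie as a TCYX TIFF with frame-interval metadata."""
    data = np.stack([
        np.stack([f.channels[c] for c in CHANNELS]) for f in movie.frames])
    first = movie.frames[0]
    meta = {
        "axes": "TCYX",
        "channels": list(CHANNELS),
        "pixel_size_um": first.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "stage": first.stage,
        "seed": first.seed,
    }
    tifffile.imwrite(path, data.astype(np.float32),
                     description=json.dumps(meta))
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_timelapse(path) -> TimeLapse:
    with tifffile.TiffFile(path) as tif:
        meta = _read_meta(path, tif)
        data = tif.asarray()
    if "frame_interval_s" not in meta:
        raise ValueError(f"{path}: metadata lacks frame_interval_s")
    channels = meta.get("channels", list(CHANNELS))
    if data.ndim != 4:
        raise ValueError(f"{path}: expected TCYX data, got {data.shape}")
    frames = [
        ImagingField(
            channels={c: data[t, i] for i, c in enumerate(channels)},
            pixel_size_um=float(meta["pixel_size_um"]),
            stage=meta.get("stage", "unknown"),
            seed=int(meta.get("seed", -1)),
        ) for t in range(data.shape[0])]
    return TimeLapse(frames=frames,
                     frame_interval_s=float(meta["frame_interval_s"]))


def write_ground_truth(directory, truth, prefix: str = "field") -> None:
    """Ground truth as CSV tables plus a JSON field manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.mitochondria.to_csv(directory / f"{prefix}_mitochondria.csv",
                              index=False)
    truth.infiltrates.to_csv(directory / f"{prefix}_infiltrates.csv",
                             index=False)
    if truth.positions is not None:
        truth.positions.to_csv(directory / f"{prefix}_positions.csv",
                               index=False)
    manifest = {
        "stage": truth.config.stage_name,
        "seed": truth.seed,
        "infiltrate_count": int(truth.infiltrate_count),
        "intensity_multiplier": truth.intensity_multiplier,
        "median_multiplier": truth.median_multiplier,
        "axon_y_um": [float(y) for y in truth.axon_y_um],
        "n_axons": int(truth.config.n_axons),
        "axon_length_um": truth.config.axon_length_um,
    }
    (directory / f"{prefix}_manifest.json").write_text(
        json.dumps(manifest, indent=1))


def config_to_yaml(config: ScenarioConfig) -> str:
    d = dataclasses.asdict(config)
    d["length_distribution"] = dataclasses.asdict(config.length_distribution)
    d["field_shape"] = list(config.field_shape)
    return yaml.safe_dump(d, sort_keys=False)


def config_from_yaml(text: str) -> ScenarioConfig:
    d = yaml.safe_load(text)
    d["length_distribution"] = LengthDistribution(**d["length_distribution"])
    d["field_shape"] = tuple(d["field_shape"])
    return ScenarioConfig(**d)
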