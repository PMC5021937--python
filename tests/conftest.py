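import numpy as np
import pandas as pd
import pytest

from mitoaxon import scenario_defaults
from mitoaxon.morphometry import segment_mitochondria
from mitoaxon.simulate import generate_field, generate_timelapse
from mitoaxon.trafficking import link_tracks, segment_timelapse


@pytest.fixture(scope="session")
def onset_still():
    """One segmented onset field with its ground truth."""
    config = scenario_defaults("onset")
    field, truth = generate_field(config, seed=1)
    objects, labels = segment_mitochondria(field, axon_y_um=truth.axon_y_um)
    return config, field, truth, objects, labels


@pytest.fixture(scope="session")
def naive_still():
    config = scenario_defaults("naive")
    field, truth = generate_field(config, seed=1)
    objects, labels = segment_mitochondria(field, axon_y_um=truth.axon_y_um)
    return config, field, truth, objects, labels


def _movie_bundle(stage, seed):
    config = scenario_defaults(stage)
    movie, truth = generate_timelapse(config, seed)
    per_frame = segment_timelapse(movie, axon_y_um=truth.axon_y_um)
    tracks = link_tracks(per_frame, movie.frame_interval_s)
    return config, movie, truth, tracks


@pytest.fixture(scope="session")
def onset_movie():
    return _movie_bundle("onset", 1)


@pytest.fixture(scope="session")
def naive_movie():
    return _movie_bundle("naive", 1)


def match_to_ground_truth(track, truth):
    """Ground-truth mitochondrion id whose trajectory a track follows."""
    pos = truth.positions.pivot(index="frame", columns="id", values="x_um")
    m = truth.mitochondria.set_index("id")
    ids = m.index[m["axon_id"].values == track.axon_id]
    err = (pos.loc[track.frames, ids]
           .sub(pd.Series(track.x_um, index=track.frames), axis=0)
           .abs().mean())
    return err.idxmin(), m


def matched_length_errors(objects, truth, max_dist_um=1.0):
    """Signed length errors of segmented objects matched to ground truth."""
    errs, gt_lengths = [], []
    for row in truth.mitochondria.itertuples():
        d = np.hypot(objects["centroid_x_um"] - row.x_um,
                     objects["centroid_y_um"] - row.y_um)
        if len(d) == 0:
            continue
        i = int(np.argmin(d.values))
        if d.values[i] <= max_dist_um:
            errs.append(objects["length_um"].iloc[i] - row.length_um)
            gt_lengths.append(row.length_um)
    return np.asarray(errs), np.asarray(gt_lengths)
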