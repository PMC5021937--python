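"""Mitochondrial trafficking: track linking and motility statistics.

Mitochondria are tracked along their axon's axis across the frames of a
time-lapse (default 50 frames spanning 98.5 s).  Linking is per-axon
nearest-neighbour assignment with constant-velocity prediction, solved
optimally per frame, with gap closing across several missed frames;
gaps arise routinely when a moving mitochondrion passes a stationary
one and the two transiently merge into a single blob.  A track is
*motile* when its net axial displacement over the movie reaches the
motility threshold (default 2 um, well above accumulated stationary
jitter); rostral is +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .morphometry import SegmentationParams, segment_mitochondria

ROSTRAL, CAUDAL = "rostral", "caudal"


@dataclass(frozen=True)
class LinkingParams:
    """Tracker configuration.

    max_step_um gates the per-frame displacement (about 1 um/s at the
    default frame interval, comfortably above modelled speeds);
    length_weight converts length dissimilarity (um) into position cost
    for tie-breaking; tracks missing longer than max_gap_frames are
    closed; tracks observed in fewer than min_track_frames frames are
    dropped from summaries (edge-entering or fragmented).
    """

    max_step_um: float = 2.0
    gate_cap_um: float = 4.0
    max_gap_frames: int = 25
    min_track_frames: int = 6
    motility_threshold_um: float = 2.0
    length_weight: float = 0.6
    merge_reject_um: float = 1.0
    repair: bool = True
    moving_step_um: float = 0.25
    chain_tolerance_um: float = 2.5
    chain_velocity_tol: float = 0.35
    start_window_frames: int = 5
    smooth_window: int = 5


@dataclass
class MotilityTrack:
    """One mitochondrion's linked positions along its axon."""

    track_id: int
    axon_id: int
    frames: np.ndarray
    x_um: np.ndarray
    length_um: float
    tmrm_mean: float
    frame_interval_s: float
    motile: bool = False

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    @property
    def net_displacement_um(self) -> float:
        return float(self.x_um[-1] - self.x_um[0])

    def _smoothed(self, window: int = 5) -> np.ndarray:
        if self.x_um.size < window:
            return self.x_um
        # local-linear smoothing suppresses centroid jitter in the path
        # integral without shortening the ends of a moving track
        from scipy.signal import savgol_filter
        return savgol_filter(self.x_um, window, 1, mode="interp")

    @property
    def path_length_um(self) -> float:
        path = float(np.abs(np.diff(self._smoothed())).sum())
        # smoothing can undershoot a straight run; the path can never be
        # shorter than the net displacement
        return max(path, abs(self.net_displacement_um))

    @property
    def elapsed_s(self) -> float:
        return float((self.frames[-1] - self.frames[0])
                     * self.frame_interval_s)

    @property
    def mean_speed_um_s(self) -> float:
        """Path length over elapsed time; pauses are included."""
        return self.path_length_um / self.elapsed_s if self.elapsed_s else 0.0

    @property
    def direction(self) -> str | None:
        if not self.motile:
            return None
        return ROSTRAL if self.net_displacement_um > 0 else CAUDAL


class _Active:
    __slots__ = ("frames", "xs", "lengths", "tmrms", "axon_id", "missing")

    def __init__(self, frame, x, length, tmrm, axon_id):
        self.frames = [frame]
        self.xs = [x]
        self.lengths = [length]
        self.tmrms = [tmrm]
        self.axon_id = axon_id
        self.missing = 0

    @property
    def velocity(self):
        """Theil-Sen slope over the last few observations.

        The median of pairwise slopes is insensitive to a single
        mis-assigned position, which would poison a running-average
        velocity and send a coasting track's prediction far off.
        """
        k = min(len(self.xs), 5)
        if k < 2:
            return 0.0
        xs, fs = self.xs[-k:], self.frames[-k:]
        slopes = [(xs[j] - xs[i]) / (fs[j] - fs[i])
                  for i in range(k) for j in range(i + 1, k)]
        return float(np.median(slopes))

    def predict(self):
        return self.xs[-1] + self.velocity * (self.missing + 1)

    def update(self, frame, x, length, tmrm):
        self.frames.append(frame)
        self.xs.append(x)
        self.lengths.append(length)
        self.tmrms.append(tmrm)
        self.missing = 0


def plot_kymograph(per_frame_objects: pd.DataFrame, axon_id: int, path,
                   tracks: list[MotilityTrack] | None = None) -> None:
    """Render one axon's kymograph (time vs axial position) to a PNG.

    Detections are plotted as dots sized by object length; linked motile
    tracks, if given, are overlaid as lines.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = per_frame_objects[per_frame_objects["axon_id"] == axon_id]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(df["centroid_x_um"], df["frame"],
               s=4 * df["length_um"], c="0.4", lw=0)
    if tracks:
        for t in tracks:
            if t.axon_id == axon_id and t.motile:
                ax.plot(t.x_um, t.frames, lw=1.2)
    ax.set_xlabel("axial position (um, rostral ->)")
    ax.set_ylabel("frame")
    ax.invert_yaxis()
    ax.set_title(f"axon {axon_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def segment_timelapse(timelapse, params: SegmentationParams | None = None,
                      axon_y_um=None) -> pd.DataFrame:
    """Per-frame object tables for a movie, concatenated with a frame
    column."""
    tables = []
    for f, frame in enumerate(timelapse.frames):
        objects, _ = segment_mitochondria(frame, params, axon_y_um=axon_y_um)
        objects.insert(0, "frame", f)
        tables.append(objects)
    return pd.concat(tables, ignore_index=True)


def link_tracks(per_frame_objects: pd.DataFrame,
                frame_interval_s: float,
                params: LinkingParams | None = None) -> list[MotilityTrack]:
    """Link per-frame detections into tracks, one axon at a time.

    ``per_frame_objects`` needs columns frame, axon_id, centroid_x_um,
    length_um and (optionally) tmrm_mean; objects without an axon
    assignment (axon_id < 0) are ignored.
    """
    if frame_interval_s is None or frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be a positive number")
    params = params or LinkingParams()
    df = per_frame_objects
    if "tmrm_mean" not in df.columns:
        df = df.assign(tmrm_mean=np.nan)
    tracks: list[MotilityTrack] = []
    counter = 0
    for axon_id, axon_df in df[df["axon_id"] >= 0].groupby("axon_id"):
        finished: list[_Active] = []
        active: list[_Active] = []
        by_frame = dict(tuple(axon_df.groupby("frame")))
        n_frames = int(df["frame"].max()) + 1
        for f in range(n_frames):
            dets = by_frame.get(f)
            if dets is None:
                xs = np.empty(0)
            else:
                xs = dets["centroid_x_um"].to_numpy()
                lengths = dets["length_um"].to_numpy()
                tmrms = dets["tmrm_mean"].to_numpy()
            assigned_det = np.zeros(xs.size, dtype=bool)
            if active and xs.size:
                cost = np.full((len(active), xs.size), 1e6)
                for i, tr in enumerate(active):
                    gate = min(params.max_step_um * (tr.missing + 1),
                               params.gate_cap_um)
                    d = np.abs(xs - tr.predict())
                    # a detection much longer than the track is two
                    # objects transiently merged into one blob: treat it
                    # as an occlusion and let the track coast instead of
                    # swallowing it
                    ok = (d <= gate) & (
                        lengths - tr.lengths[-1] <= params.merge_reject_um)
                    cost[i, ok] = (d[ok] + params.length_weight
                                   * np.abs(lengths[ok] - tr.lengths[-1]))
                rows, cols = linear_sum_assignment(cost)
                for i, j in zip(rows, cols):
                    if cost[i, j] < 1e5:
                        active[i].update(f, xs[j], lengths[j], tmrms[j])
                        assigned_det[j] = True
            still_active = []
            for tr in active:
                if tr.frames[-1] == f:
                    still_active.append(tr)
                else:
                    tr.missing += 1
                    if tr.missing > params.max_gap_frames:
                        finished.append(tr)
                    else:
                        still_active.append(tr)
            active = still_active
            for j in np.flatnonzero(~assigned_det):
                active.append(_Active(f, xs[j], lengths[j], tmrms[j],
                                      int(axon_id)))
        finished.extend(active)
        for tr in finished:
            tracks.append(MotilityTrack(
                track_id=counter,
                axon_id=tr.axon_id,
                frames=np.asarray(tr.frames),
                x_um=np.asarray(tr.xs),
                length_um=float(np.median(tr.lengths)),
                tmrm_mean=float(np.nanmean(tr.tmrms)),
                frame_interval_s=frame_interval_s,
            ))
            counter += 1
    if params.repair:
        tracks = repair_tracks(tracks, params)
    for tr in tracks:
        tr.motile = classify_motile(tr, params)
    _demote_anchor_huggers(tracks, params)
    return tracks


def _demote_anchor_huggers(tracks, params):
    """Un-flag motile tracks that hug a stationary object throughout.

    A transiently merged blob (mover passing a stationary mitochondrion)
    can survive as its own track with an apparent displacement of a few
    um; unlike a true mover it spends its whole life within the merge
    zone around the stationary partner's anchor position.
    """
    anchors: dict[int, list[float]] = {}
    for t in tracks:
        if (t.n_frames >= params.min_track_frames
                and abs(t.net_displacement_um) < 1.0):
            anchors.setdefault(t.axon_id, []).append(float(np.median(t.x_um)))
    for t in tracks:
        if not t.motile:
            continue
        pos = anchors.get(t.axon_id)
        if not pos:
            continue
        near = np.abs(t.x_um[:, None] - np.asarray(pos)[None, :]) <= 2.5
        if near.mean(axis=0).max() > 0.7:
            t.motile = False


def classify_motile(track: MotilityTrack,
                    params: LinkingParams | None = None) -> bool:
    """Motile iff net displacement reaches the threshold (inclusive)."""
    params = params or LinkingParams()
    if track.n_frames < params.min_track_frames:
        return False
    return abs(track.net_displacement_um) >= params.motility_threshold_um


# --------------------------------------------------------------------------
# track repair: exchange-aware chaining of moving segments
# --------------------------------------------------------------------------

def _local_velocity(frames, xs):
    """Centred-difference velocity per observation (um/frame)."""
    v = np.empty(xs.size)
    if xs.size == 1:
        return np.zeros(1)
    v[1:-1] = (xs[2:] - xs[:-2]) / (frames[2:] - frames[:-2])
    v[0] = (xs[1] - xs[0]) / (frames[1] - frames[0])
    v[-1] = (xs[-1] - xs[-2]) / (frames[-1] - frames[-2])
    return v


def repair_tracks(tracks: list[MotilityTrack],
                  params: LinkingParams | None = None
                  ) -> list[MotilityTrack]:
    """Resolve identity exchanges at crossings by velocity-line chaining.

    When a moving mitochondrion passes a stationary one, the two blobs
    transiently merge and the linker can hand the mover's tail to the
    stationary track (and vice versa).  In kymograph terms every true
    mover traces one straight streak, so the repair extracts maximal
    *moving* segments from all tracks of an axon and re-chains segments
    that continue each other's line (consistent position extrapolation
    and velocity, same direction).  Each chain becomes one track; the
    stationary residues of contributing tracks stay behind as separate
    tracks.  Double counting of fragmented movers and spurious motility
    of theft victims are both removed by construction.
    """
    params = params or LinkingParams()
    out: list[MotilityTrack] = []
    by_axon: dict[int, list[MotilityTrack]] = {}
    for t in tracks:
        by_axon.setdefault(t.axon_id, []).append(t)
    counter = 0
    for axon_id, axon_tracks in sorted(by_axon.items()):
        segments = []  # (f0, f1, x0, x1, v, frames, xs, length, tmrm)
        for t in axon_tracks:
            if t.n_frames < 2:
                out.append(t)
                continue
            moving = np.abs(_local_velocity(t.frames, t.x_um)) \
                >= params.moving_step_um
            # split into runs of constant state
            idx = np.flatnonzero(np.diff(moving.astype(int)) != 0) + 1
            runs = np.split(np.arange(t.n_frames), idx)
            residual = []
            for run in runs:
                seg_f, seg_x = t.frames[run], t.x_um[run]
                if (moving[run[0]] and run.size >= 3
                        and abs(seg_x[-1] - seg_x[0]) >= 0.8):
                    v = (seg_x[-1] - seg_x[0]) / (seg_f[-1] - seg_f[0])
                    segments.append([seg_f, seg_x, v, t])
                else:
                    residual.extend(run)
            if residual:
                residual = np.asarray(residual)
                out.append(MotilityTrack(
                    track_id=-1, axon_id=axon_id,
                    frames=t.frames[residual], x_um=t.x_um[residual],
                    length_um=t.length_um, tmrm_mean=t.tmrm_mean,
                    frame_interval_s=t.frame_interval_s))
        # chain segments along consistent velocity lines
        segments.sort(key=lambda s: s[0][0])
        used = [False] * len(segments)
        for i, seg in enumerate(segments):
            if used[i]:
                continue
            used[i] = True
            chain = [seg]
            while True:
                tail_f, tail_x, tail_v, _ = chain[-1]
                best = None
                for j, cand in enumerate(segments):
                    if used[j]:
                        continue
                    f, x, v, _ = cand
                    if f[0] < tail_f[-1] - 2:
                        continue
                    if np.sign(v) != np.sign(tail_v):
                        continue
                    if abs(v - tail_v) > params.chain_velocity_tol:
                        continue
                    predicted = tail_x[-1] + tail_v * (f[0] - tail_f[-1])
                    miss = abs(x[0] - predicted)
                    if miss <= params.chain_tolerance_um and (
                            best is None or miss < best[0]):
                        best = (miss, j)
                if best is None:
                    break
                used[best[1]] = True
                chain.append(segments[best[1]])
            frames = np.concatenate([c[0] for c in chain])
            xs = np.concatenate([c[1] for c in chain])
            order = np.argsort(frames)
            frames, xs = frames[order], xs[order]
            frames, keep = np.unique(frames, return_index=True)
            src = chain[0][3]
            out.append(MotilityTrack(
                track_id=-1, axon_id=axon_id, frames=frames, x_um=xs[keep],
                length_um=float(np.median([c[3].length_um for c in chain])),
                tmrm_mean=float(np.mean([c[3].tmrm_mean for c in chain])),
                frame_interval_s=src.frame_interval_s))
        counter += 1
    for i, t in enumerate(out):
        t.track_id = i
    return out


@dataclass
class TraffickingSummary:
    """Motility statistics of one movie (or pooled movies)."""

    motile_per_100um: float
    rostral_fraction: float | None
    mean_speed_um_s: float | None
    n_motile: int
    n_tracks: int
    motile_lengths_um: np.ndarray = field(default_factory=lambda: np.empty(0))


def trafficking_summary(tracks: list[MotilityTrack],
                        total_axon_length_um: float,
                        params: LinkingParams | None = None
                        ) -> TraffickingSummary:
    """Density of motile mitochondria, direction balance and speed.

    Tracks observed in fewer than ``min_track_frames`` frames are
    excluded.  Motile tracks are counted only if first observed within
    ``start_window_frames`` of the movie start: every mitochondrion
    present in the field produces a track from the first frames, so a
    motile track born mid-movie is a fragment or crossing artifact of an
    already-counted object, not a new mitochondrion.  With zero motile
    tracks the direction fraction and speed are None.
    """
    if total_axon_length_um <= 0:
        raise ValueError("total_axon_length_um must be positive")
    params = params or LinkingParams()
    kept = [t for t in tracks if t.n_frames >= params.min_track_frames]
    motile = [t for t in kept
              if t.motile and t.frames[0] <= params.start_window_frames]
    n = len(motile)
    rostral = None
    speed = None
    if n:
        rostral = sum(t.direction == ROSTRAL for t in motile) / n
        speed = float(np.mean([t.mean_speed_um_s for t in motile]))
    return TraffickingSummary(
        motile_per_100um=100.0 * n / total_axon_length_um,
        rostral_fraction=rostral,
        mean_speed_um_s=speed,
        n_motile=n,
        n_tracks=len(kept),
        motile_lengths_um=np.array([t.length_um for t in motile]),
    )
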