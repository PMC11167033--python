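"""Frame-to-frame linking, gap closing and trajectory statistics.

Per-frame detections are linked into tracklets by optimal assignment
(squared-distance cost with a hard distance cap, solved as a linear
assignment problem), then tracklet ends are joined to later tracklet
starts across short detection dropouts ("gap closing") under a distance
and frame-gap cap.  Defaults reproduce the tracker configuration used
for regulatory-T-cell movies: 36 µm linking radius, 12 µm gap-closing
radius, at most 5 skipped frames.

The frame-pair matching maximizes the number of links admissible under
the cap and, among those, minimizes the total squared distance; gap
closing is greedy by ascending distance (adequate at the cell densities
of these movies, and deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spot_detection import Spot

__all__ = [
    "LinkingParams",
    "Track",
    "TrajectoryStats",
    "default_linking_params",
    "link_frame_pair",
    "build_tracklets",
    "close_gaps",
    "trajectory_stats",
    "save_trajectory_plot",
]


@dataclass(frozen=True)
class LinkingParams:
    """Linking caps in micrometres / frames (defaults: 36 µm, 12 µm, 5 frames)."""

    link_max_um: float = 36.0
    gap_max_um: float = 12.0
    gap_max_frames: int = 5

    def __post_init__(self) -> None:
        if not self.link_max_um > 0:
            raise ValueError("link_max_um must be > 0")
        if not self.gap_max_um > 0:
            raise ValueError("gap_max_um must be > 0")
        if self.gap_max_frames < 0 or int(self.gap_max_frames) != self.gap_max_frames:
            raise ValueError("gap_max_frames must be an integer >= 0")


def default_linking_params() -> LinkingParams:
    return LinkingParams()


@dataclass
class Track:
    """An ordered trajectory; ``gap_closed`` flags spots that follow a closed gap."""

    track_id: int
    spots: list[Spot] = field(default_factory=list)
    gap_closed: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b >= a for a, b in zip(frames[1:], frames[:-1])):
            raise ValueError("spot frames must be strictly increasing")
        if not self.gap_closed:
            self.gap_closed = [False] * len(self.spots)

    @property
    def start_frame(self) -> int:
        return self.spots[0].frame

    @property
    def end_frame(self) -> int:
        return self.spots[-1].frame


@dataclass(frozen=True)
class TrajectoryStats:
    track_id: int
    path_length_um: float
    net_displacement_um: float
    confinement_ratio: float
    duration_min: float
    n_spots: int


def link_frame_pair(
    spots_a: list[Spot],
    spots_b: list[Spot],
    link_max_um: float,
    pixel_size_um: float,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two consecutive frames.

    Returns index pairs (i, j) into ``spots_a``/``spots_b``.  Among all
    partial matchings whose every link spans <= ``link_max_um``
    (boundary inclusive), the result has maximal cardinality and, among
    those, minimal total squared distance.
    """
    na, nb = len(spots_a), len(spots_b)
    if na == 0 or nb == 0:
        return []
    cap_px = link_max_um / pixel_size_um
    ax = np.array([[s.x_px, s.y_px] for s in spots_a])
    bx = np.array([[s.x_px, s.y_px] for s in spots_b])
    d2 = ((ax[:, None, :] - bx[None, :, :]) ** 2).sum(axis=2)
    feasible = d2 <= cap_px**2 + 1e-9
    if not feasible.any():
        return []

    # big-M augmentation: unmatch cost M dominates any total link cost,
    # so cardinality is maximized first, then total squared distance.
    m_unmatch = cap_px**2 * (min(na, nb) + 1) + 1.0
    big = m_unmatch * (na + nb + 2) * 10.0
    cost = np.full((na + nb, nb + na), big)
    cost[:na, :nb] = np.where(feasible, d2, big)
    cost[np.arange(na), nb + np.arange(na)] = m_unmatch  # a_i unmatched
    cost[na + np.arange(nb), np.arange(nb)] = m_unmatch  # b_j unmatched
    cost[na:, nb:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < na and j < nb and feasible[i, j]
    ]


def _spot_sort_key(s: Spot) -> tuple:
    return (s.frame, s.x_px, s.y_px, -s.quality)


def build_tracklets(
    detections: dict[int, list[Spot]] | list[list[Spot]],
    params: LinkingParams,
    pixel_size_um: float,
) -> list[Track]:
    """Chain frame-pair matchings into maximal tracklets.

    Every detection belongs to exactly one tracklet (possibly of length
    one); a tracklet ends as soon as its last spot finds no admissible
    partner in the next frame.
    """
    if isinstance(detections, dict):
        by_frame = {f: sorted(sp, key=_spot_sort_key) for f, sp in detections.items()}
    else:
        by_frame = {f: sorted(sp, key=_spot_sort_key) for f, sp in enumerate(detections)}
    frames = sorted(by_frame)
    tracks: list[Track] = []
    prev_open: dict[int, int] = {}  # index into previous frame's list -> track index
    prev_spots: list[Spot] = []
    prev_frame: int | None = None
    for f in frames:
        cur = by_frame[f]
        cur_open: dict[int, int] = {}
        if prev_frame == f - 1 and prev_spots and cur:
            matches = link_frame_pair(prev_spots, cur, params.link_max_um, pixel_size_um)
        else:
            matches = []
        matched_b = set()
        for i, j in matches:
            ti = prev_open[i]
            tracks[ti].spots.append(cur[j])
            tracks[ti].gap_closed.append(False)
            cur_open[j] = ti
            matched_b.add(j)
        for j, s in enumerate(cur):
            if j not in matched_b:
                tracks.append(Track(track_id=len(tracks), spots=[s]))
                cur_open[j] = len(tracks) - 1
        prev_open, prev_spots, prev_frame = cur_open, cur, f
    # deterministic ids by (first frame, x, y)
    tracks.sort(key=lambda t: (t.spots[0].frame, t.spots[0].x_px, t.spots[0].y_px))
    out = []
    for tid, tr in enumerate(tracks):
        out.append(Track(track_id=tid, spots=tr.spots, gap_closed=tr.gap_closed))
    return out


def close_gaps(
    tracklets: list[Track],
    params: LinkingParams,
    pixel_size_um: float,
) -> list[Track]:
    """Join tracklet ends to later tracklet starts across detection dropouts.

    A join is admissible when 1 <= skipped frames <= ``gap_max_frames``
    and the end-to-start distance is <= ``gap_max_um``.  Candidates are
    applied greedily by ascending distance (ties by end frame, then
    position); each end and each start is used at most once.  Gap
    closing never increases the track count.
    """
    n = len(tracklets)
    cands: list[tuple[float, tuple, int, int]] = []
    for i, ta in enumerate(tracklets):
        ea = ta.spots[-1]
        for j, tb in enumerate(tracklets):
            if i == j:
                continue
            sb = tb.spots[0]
            skipped = sb.frame - ea.frame - 1
            if not (1 <= skipped <= params.gap_max_frames):
                continue
            dist_um = math.hypot(sb.x_px - ea.x_px, sb.y_px - ea.y_px) * pixel_size_um
            if dist_um <= params.gap_max_um + 1e-9:
                tie = (ea.frame, ea.x_px, ea.y_px, sb.x_px, sb.y_px)
                cands.append((dist_um, tie, i, j))
    cands.sort(key=lambda c: (c[0], c[1]))

    successor = [-1] * n
    has_pred = [False] * n
    end_used = [False] * n
    for _, _, i, j in cands:
        if end_used[i] or has_pred[j]:
            continue
        successor[i] = j
        end_used[i] = True
        has_pred[j] = True

    merged: list[Track] = []
    for i in range(n):
        if has_pred[i]:
            continue
        spots = list(tracklets[i].spots)
        flags = list(tracklets[i].gap_closed)
        k = i
        while successor[k] != -1:
            k = successor[k]
            seg = tracklets[k]
            spots.extend(seg.spots)
            flags.extend([True] + seg.gap_closed[1:])
        merged.append(Track(track_id=0, spots=spots, gap_closed=flags))
    merged.sort(key=lambda t: (t.spots[0].frame, t.spots[0].x_px, t.spots[0].y_px))
    return [
        Track(track_id=tid, spots=t.spots, gap_closed=t.gap_closed)
        for tid, t in enumerate(merged)
    ]


def trajectory_stats(
    track: Track, pixel_size_um: float, frame_interval_min: float
) -> TrajectoryStats:
    """Path length, net displacement, confinement ratio and duration.

    Path length sums distances between consecutive observed spots (a
    closed gap contributes the straight step across it); duration spans
    (last - first + 1) frames times the frame interval; confinement
    ratio is net/path, defined as 0 for a zero-length path.
    """
    if not track.spots:
        raise ValueError("track must contain at least one spot")
    pos = np.array([[s.x_px, s.y_px] for s in track.spots]) * pixel_size_um
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path = float(steps.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    ratio = net / path if path > 0 else 0.0
    n_span = track.end_frame - track.start_frame + 1
    return TrajectoryStats(
        track_id=track.track_id,
        path_length_um=path,
        net_displacement_um=net,
        confinement_ratio=ratio,
        duration_min=n_span * frame_interval_min,
        n_spots=len(track.spots),
    )


def save_trajectory_plot(
    tracks: list[Track], path, pixel_size_um: float = 1.0, origin_centered: bool = True
) -> None:
    """Rose plot of trajectories (each track translated to a common origin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for tr in tracks:
        xs = np.array([s.x_px for s in tr.spots]) * pixel_size_um
        ys = np.array([s.y_px for s in tr.spots]) * pixel_size_um
        if origin_centered and len(xs):
            xs, ys = xs - xs[0], ys - ys[0]
        ax.plot(xs, ys, lw=0.7, alpha=0.7)
    ax.set_xlabel("x (\u00b5m)")
    ax.set_ylabel("y (\u00b5m)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
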