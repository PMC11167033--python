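"""CAF-Treg contact decision, episode extraction and condition comparison.

A tracked cell is "in contact" in a frame when the Euclidean distance
from its center to the nearest stromal-foreground pixel is at most the
contact radius (default: the cell radius, half the detection diameter);
ties count as contact.  Contact episodes are maximal runs of
consecutive in-contact frames; runs shorter than ``min_episode_frames``
(default 2, i.e. a 10-minute window at 5-minute sampling) are
discarded, and an episode's duration is ``n_frames x frame_interval``
(a 2-frame contact at 5-minute sampling lasts 10 minutes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .segmentation import SegmentationMask
from .spot_detection import Spot
from .tracking import Track

__all__ = [
    "ContactParams",
    "ContactEpisode",
    "in_contact",
    "contact_timeline",
    "extract_episodes",
    "arrest_coefficient",
    "compare_conditions",
    "nearest_foreground_distance_px",
    "save_violin_plot",
]


@dataclass(frozen=True)
class ContactParams:
    """Contact rule parameters.

    contact_radius_um defaults to 4 µm (half the 8 µm detection
    diameter); min_episode_frames defaults to 2; frame_interval_min to
    5.  bridge_max_frames > 0 would bridge short non-contact gaps
    inside a timeline; the default (0) keeps strict runs.
    """

    contact_radius_um: float = 4.0
    min_episode_frames: int = 2
    frame_interval_min: float = 5.0
    bridge_max_frames: int = 0

    def __post_init__(self) -> None:
        if self.contact_radius_um < 0:
            raise ValueError("contact_radius_um must be >= 0")
        if self.min_episode_frames < 1:
            raise ValueError("min_episode_frames must be >= 1")
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be > 0")


@dataclass(frozen=True)
class ContactEpisode:
    """Maximal run of in-contact frames for one track (end inclusive)."""

    track_id: int
    start_frame: int
    end_frame: int
    n_frames: int
    duration_min: float


def nearest_foreground_distance_px(
    mask: np.ndarray, x_px: float, y_px: float,
    edt_indices: np.ndarray | None = None,
) -> float:
    """Distance (px) from a point to the nearest foreground pixel center.

    Uses the Euclidean distance transform's nearest-foreground index at
    the point's grid cell, then measures the exact distance from the
    real-valued point to that pixel.  Returns +inf for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return math.inf
    if edt_indices is None:
        edt_indices = ndi.distance_transform_edt(
            ~mask, return_distances=False, return_indices=True
        )
    yi = int(np.clip(round(y_px), 0, mask.shape[0] - 1))
    xi = int(np.clip(round(x_px), 0, mask.shape[1] - 1))
    ny, nx = edt_indices[0][yi, xi], edt_indices[1][yi, xi]
    return math.hypot(x_px - nx, y_px - ny)


def in_contact(
    spot: Spot,
    mask: SegmentationMask | np.ndarray,
    contact_radius_um: float,
    pixel_size_um: float,
) -> bool:
    """True iff the spot center is within ``contact_radius_um`` of the
    stromal foreground (boundary inclusive).  An empty mask gives False."""
    arr = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    d_px = nearest_foreground_distance_px(arr, spot.x_px, spot.y_px)
    return d_px * pixel_size_um <= contact_radius_um + 1e-9


def contact_timeline(
    track: Track,
    masks: Mapping[int, SegmentationMask | np.ndarray],
    params: ContactParams,
    pixel_size_um: float,
    edt_cache: dict[int, np.ndarray] | None = None,
) -> list[bool]:
    """Per-observed-frame contact flags for one track.

    ``masks`` maps frame index to the stromal mask of that frame; a
    missing frame raises.  Frames skipped by gap closing are simply not
    represented (the timeline is aligned with ``track.spots``).  An
    ``edt_cache`` dict may be shared across calls to reuse each
    frame's distance transform.
    """
    flags: list[bool] = []
    if edt_cache is None:
        edt_cache = {}
    for s in track.spots:
        if s.frame not in masks:
            raise KeyError(f"no stromal mask for frame {s.frame}")
        m = masks[s.frame]
        arr = m.mask if isinstance(m, SegmentationMask) else np.asarray(m, bool)
        if not arr.any():
            flags.append(False)
            continue
        if s.frame not in edt_cache:
            edt_cache[s.frame] = ndi.distance_transform_edt(
                ~arr, return_distances=False, return_indices=True
            )
        d_px = nearest_foreground_distance_px(
            arr, s.x_px, s.y_px, edt_indices=edt_cache[s.frame]
        )
        flags.append(d_px * pixel_size_um <= params.contact_radius_um + 1e-9)
    return flags


def extract_episodes(
    timeline: Sequence[bool],
    params: ContactParams,
    frames: Sequence[int] | None = None,
    track_id: int = 0,
) -> list[ContactEpisode]:
    """Maximal runs of consecutive true flags, filtered at min length.

    ``frames`` gives the frame index of each flag (default 0,1,2,...);
    a jump in frame numbers breaks a run even if both flags are true
    (no bridging across unobserved frames).  With
    ``params.bridge_max_frames`` > 0, false gaps of at most that many
    observed frames are bridged first.
    """
    flags = [bool(f) for f in timeline]
    if frames is None:
        frames = list(range(len(flags)))
    if len(frames) != len(flags):
        raise ValueError("frames and timeline must have equal length")

    if params.bridge_max_frames > 0 and flags:
        runs_false: list[tuple[int, int]] = []
        i = 0
        while i < len(flags):
            if not flags[i]:
                j = i
                while j + 1 < len(flags) and not flags[j + 1]:
                    j += 1
                runs_false.append((i, j))
                i = j + 1
            else:
                i += 1
        for a, b in runs_false:
            interior = a > 0 and b < len(flags) - 1
            contiguous = frames[b + 1] - frames[a - 1] == (b + 1) - (a - 1) if interior else False
            if interior and contiguous and (b - a + 1) <= params.bridge_max_frames:
                for k in range(a, b + 1):
                    flags[k] = True

    episodes: list[ContactEpisode] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while (
                j + 1 < n
                and flags[j + 1]
                and frames[j + 1] == frames[j] + 1
            ):
                j += 1
            n_frames = frames[j] - frames[i] + 1
            if n_frames >= params.min_episode_frames:
                episodes.append(
                    ContactEpisode(
                        track_id=track_id,
                        start_frame=int(frames[i]),
                        end_frame=int(frames[j]),
                        n_frames=n_frames,
                        duration_min=n_frames * params.frame_interval_min,
                    )
                )
            i = j + 1
        else:
            i += 1
    return episodes


def arrest_coefficient(timeline: Sequence[bool]) -> float:
    """Fraction of observed frames spent in contact."""
    if len(timeline) == 0:
        raise ValueError("timeline must be non-empty")
    return float(np.mean([bool(f) for f in timeline]))


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration of group labelings.

    Average ranks are used for ties; the two-sided p-value is the
    fraction of labelings whose rank-sum deviates from its mean by at
    least the observed deviation.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_tot = len(a), len(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n_tot + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-12
    count = 0
    total = 0
    for combo in itertools.combinations(range(n_tot), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev:
            count += 1
    return float(w_obs), count / total


def compare_conditions(
    durations_a: Sequence[float],
    durations_b: Sequence[float],
    test: str = "ranksum",
) -> tuple[float, float]:
    """Two-sample comparison of per-episode durations across conditions.

    "ranksum": Wilcoxon rank-sum; exact by full enumeration when both
    samples have n <= 8 (statistic = rank-sum of sample a), otherwise
    the tie-corrected normal approximation.  "t": unpaired two-tailed
    t-test.  Returns (statistic, two-sided p).
    """
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if test == "ranksum":
        if len(a) <= 8 and len(b) <= 8:
            return _exact_ranksum_p(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        # report the rank-sum of sample a (U + n_a(n_a+1)/2)
        w = res.statistic + len(a) * (len(a) + 1) / 2.0
        return float(w), float(res.pvalue)
    if test == "t":
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("degenerate: both samples have zero variance")
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def save_violin_plot(durations_by_condition: Mapping[str, Sequence[float]], path) -> None:
    """Violin plot of per-episode contact durations, one violin per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = list(durations_by_condition)
    data = [list(durations_by_condition[c]) for c in conditions]
    fig, ax = plt.subplots(figsize=(1.6 * len(conditions) + 1.5, 4.0))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(conditions) + 1), conditions)
    ax.set_ylabel("contact duration (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
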