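"""Synthetic microscopy data with exact ground truth.

Three generators emulate the imaging experiments the pipeline analyses:

* :func:`generate_movie` — dual-channel time-lapse movies of spot-like
  motile lymphocytes (Gaussian blobs) diffusing over a field containing
  textured stromal (fibroblast) patches.  Cell motion follows a
  two-state model: free isotropic Gaussian steps, and "arrest" (much
  smaller steps) that can only be entered while the cell is inside the
  contact zone (the stromal mask dilated by the cell radius, the same
  rule the analysis applies).  Antigen-loaded vs control stromal cells
  are emulated by different arrest entry/exit rates.
* :func:`generate_if_field` — two-channel immunofluorescence fields
  with a marker-positive area of prescribed fraction and countable
  nuclei placed inside (rich) and outside (poor) the marker region.
* :func:`generate_puncta_image` — cells with a known number of small
  bright puncta over a dim cytoplasm disk, for puncta-per-cell counts.

Each generator consumes one seeded NumPy Generator, so identical seeds
give bit-identical outputs, and emits a :class:`GroundTruth` holding
the exact tracks, masks, contact states, episodes and counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .contact_analysis import ContactEpisode
from .io_config import Movie
from .tracking import Track

__all__ = [
    "MotilityModel",
    "GroundTruth",
    "antigen_model",
    "control_model",
    "generate_movie",
    "simulate_tracks",
    "generate_if_field",
    "generate_puncta_image",
    "truth_episodes_from_contact",
    "match_tracks_to_truth",
    "episode_recovery_scores",
    "OvercrowdingError",
]


class OvercrowdingError(RuntimeError):
    """Raised when requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class MotilityModel:
    """Two-state (free / arrested) random-walk motility.

    Step standard deviations are per axis, in µm per frame.  ``p_on``
    is the per-frame probability of entering arrest while inside the
    contact zone; ``p_off`` the per-frame probability of leaving it.
    """

    step_sd_free_um: float = 6.0
    step_sd_arrest_um: float = 0.5
    p_on: float = 0.6
    p_off: float = 0.05
    condition: str = "antigen"

    def __post_init__(self) -> None:
        for p, name in ((self.p_on, "p_on"), (self.p_off, "p_off")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.step_sd_arrest_um < self.step_sd_free_um:
            raise ValueError("step_sd_arrest_um must be < step_sd_free_um")


def antigen_model() -> MotilityModel:
    """Frequent, long-lived arrest (antigen-loaded stromal cells)."""
    return MotilityModel(p_on=0.6, p_off=0.05, condition="antigen")


def control_model() -> MotilityModel:
    """Rare, short-lived arrest (unloaded stromal cells)."""
    return MotilityModel(p_on=0.1, p_off=0.5, condition="control")


@dataclass
class GroundTruth:
    """Exact simulator state: what a perfect analysis would recover."""

    positions_px: np.ndarray | None = None  # (n_cells, n_frames, 2) as (x, y)
    mask: np.ndarray | None = None  # (H, W) bool, static stromal mask
    contact: np.ndarray | None = None  # (n_cells, n_frames) bool
    arrested: np.ndarray | None = None  # (n_cells, n_frames) bool
    episodes: list[ContactEpisode] = field(default_factory=list)
    # field / puncta generators:
    marker_mask: np.ndarray | None = None
    marker_area_fraction: float | None = None
    centers_rich: np.ndarray | None = None
    centers_poor: np.ndarray | None = None
    cell_count_rich: int = 0
    cell_count_poor: int = 0
    puncta_counts: list[int] = field(default_factory=list)
    cell_centers_px: np.ndarray | None = None
    cell_radii_px: np.ndarray | None = None

    def tracks(self) -> list[Track]:
        """Truth positions as Track objects (one per cell, every frame)."""
        from .spot_detection import Spot

        out = []
        for c in range(self.positions_px.shape[0]):
            spots = [
                Spot(frame=t, x_px=float(x), y_px=float(y), quality=math.inf)
                for t, (x, y) in enumerate(self.positions_px[c])
            ]
            out.append(Track(track_id=c, spots=spots))
        return out


def truth_episodes_from_contact(
    contact: np.ndarray, frame_interval_min: float
) -> list[ContactEpisode]:
    """Maximal runs of the per-cell contact state (no minimum length)."""
    episodes = []
    for c in range(contact.shape[0]):
        flags = contact[c]
        t = 0
        n = len(flags)
        while t < n:
            if flags[t]:
                j = t
                while j + 1 < n and flags[j + 1]:
                    j += 1
                episodes.append(
                    ContactEpisode(
                        track_id=c,
                        start_frame=t,
                        end_frame=j,
                        n_frames=j - t + 1,
                        duration_min=(j - t + 1) * frame_interval_min,
                    )
                )
                t = j + 1
            else:
                t += 1
    return episodes


# --------------------------------------------------------------------------
# stromal mask rendering
# --------------------------------------------------------------------------


def _render_mask(
    mask_spec: dict | None,
    shape: tuple[int, int],
    pixel_size_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render the true stromal mask from a small spec dict.

    Supported kinds: "disks" (n random non-overlapping disks of
    radius_um), "disk" (one centered disk), "none".  Default: 20 disks
    of radius 30 µm in the 512 µm field (~22% coverage), emulating the
    surface coverage of a few thousand spread fibroblasts seeded in a
    1 cm^2 chamber well.
    """
    if mask_spec is None:
        mask_spec = {"kind": "disks", "n": 20, "radius_um": 30.0}
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    kind = mask_spec.get("kind", "disks")
    if kind == "none":
        return np.zeros(shape, dtype=bool)
    if kind == "disk":
        r = mask_spec["radius_um"] / pixel_size_um
        cy, cx = mask_spec.get("center_px", (h / 2, w / 2))
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if kind == "disks":
        n = int(mask_spec.get("n", 6))
        r = mask_spec["radius_um"] / pixel_size_um
        margin = r + 8
        centers: list[tuple[float, float]] = []
        tries = 0
        while len(centers) < n:
            tries += 1
            if tries > 20000:
                raise OvercrowdingError("cannot place stromal patches")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all((cy - a) ** 2 + (cx - b) ** 2 >= (2 * r + 8) ** 2 for a, b in centers):
                centers.append((cy, cx))
        mask = np.zeros(shape, dtype=bool)
        for cy, cx in centers:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        return mask
    raise ValueError(f"unknown mask kind {kind!r}")


# --------------------------------------------------------------------------
# blob rendering
# --------------------------------------------------------------------------


def _add_gaussian_blob(
    frame: np.ndarray, x: float, y: float, sigma_px: float, amplitude: float
) -> None:
    """Accumulate one Gaussian blob into a frame (windowed at 4 sigma)."""
    h, w = frame.shape
    r = int(math.ceil(4 * sigma_px))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    ys = np.arange(y0, y1)[:, None]
    xs = np.arange(x0, x1)[None, :]
    frame[y0:y1, x0:x1] += amplitude * np.exp(
        -((ys - y) ** 2 + (xs - x) ** 2) / (2 * sigma_px**2)
    )


def _reflect(v: float, lo: float, hi: float) -> float:
    # reflect into [lo, hi]; period 2*(hi-lo)
    if hi <= lo:
        return lo
    span = hi - lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return v + lo


# --------------------------------------------------------------------------
# time-lapse movie generator
# --------------------------------------------------------------------------


def _resolve_overlaps(xy: np.ndarray, min_sep_px: float, w: float, h: float) -> np.ndarray:
    """Push cell centers apart until pairwise separations reach min_sep_px.

    Excluded volume: lymphocyte bodies cannot interpenetrate, so any
    pair closer than the minimal separation is moved symmetrically
    apart along its axis (a few fixed-point iterations; coincident
    pairs get a deterministic axis).  Positions stay inside the field.
    """
    n = xy.shape[0]
    if n < 2 or min_sep_px <= 0:
        return xy
    xy = xy.copy()
    for _ in range(25):
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                d = xy[j] - xy[i]
                dist = math.hypot(d[0], d[1])
                if dist >= min_sep_px:
                    continue
                if dist < 1e-9:
                    d = np.array([1.0, 0.0])
                    dist = 1e-9
                push = (min_sep_px - dist) / 2.0
                shift = d / dist * push
                xy[i] -= shift
                xy[j] += shift
                moved = True
        if not moved:
            break
    xy[:, 0] = np.clip(xy[:, 0], 0.0, w - 1.0)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, h - 1.0)
    return xy


def simulate_tracks(
    n_cells: int,
    n_frames: int,
    model: MotilityModel,
    mask: np.ndarray,
    rng: np.random.Generator,
    pixel_size_um: float = 1.0,
    cell_radius_um: float = 4.0,
    min_separation_um: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate positions, arrest states and geometric contact states.

    Returns (positions_px (n_cells, n_frames, 2) as (x, y), arrested,
    contact), where contact is the analysis-side rule applied to the
    true mask: distance from the cell center to the nearest mask pixel
    <= cell radius.  Arrest entry is only possible while in contact
    (the contact zone is the mask dilated by the cell radius); exits
    occur with ``p_off`` regardless of position.  Per-frame transition
    uniforms and per-frame steps are always drawn, so different rate
    parameters consume identical random streams (monotone coupling).
    Boundaries reflect, and cell bodies keep a minimal pairwise
    separation (excluded volume).
    """
    h, w = mask.shape
    r_px = cell_radius_um / pixel_size_um
    if mask.any():
        dist_px = ndi.distance_transform_edt(~mask)
        zone = dist_px <= r_px + 1e-9
    else:
        zone = np.zeros_like(mask)

    pos = np.empty((n_cells, n_frames, 2))
    arrested = np.zeros((n_cells, n_frames), dtype=bool)
    contact = np.zeros((n_cells, n_frames), dtype=bool)

    xy = rng.uniform([0, 0], [w - 1, h - 1], size=(n_cells, 2))
    u_on = rng.uniform(size=(n_frames, n_cells))
    u_off = rng.uniform(size=(n_frames, n_cells))
    steps = rng.normal(size=(n_frames, n_cells, 2))

    sd_free = model.step_sd_free_um / pixel_size_um
    sd_arr = model.step_sd_arrest_um / pixel_size_um
    min_sep_px = min_separation_um / pixel_size_um

    xy = _resolve_overlaps(xy, min_sep_px, w, h)
    state = np.zeros(n_cells, dtype=bool)
    for t in range(n_frames):
        yi = np.clip(np.rint(xy[:, 1]).astype(int), 0, h - 1)
        xi = np.clip(np.rint(xy[:, 0]).astype(int), 0, w - 1)
        in_zone = zone[yi, xi]
        leave = state & (u_off[t] < model.p_off)
        enter = ~state & in_zone & (u_on[t] < model.p_on)
        state = (state & ~leave) | enter
        pos[:, t] = xy
        arrested[:, t] = state
        contact[:, t] = in_zone
        sd = np.where(state, sd_arr, sd_free)
        xy = xy + steps[t] * sd[:, None]
        xy[:, 0] = [_reflect(v, 0.0, w - 1.0) for v in xy[:, 0]]
        xy[:, 1] = [_reflect(v, 0.0, h - 1.0) for v in xy[:, 1]]
        xy = _resolve_overlaps(xy, min_sep_px, w, h)
    return pos, arrested, contact


def generate_movie(
    n_cells: int = 40,
    n_frames: int = 90,
    model: MotilityModel | None = None,
    mask_spec: dict | None = None,
    noise_sd: float = 1.5,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 1.0,
    frame_interval_min: float = 5.0,
    cell_diameter_um: float = 8.0,
    cell_amplitude: float = 150.0,
) -> tuple[Movie, GroundTruth]:
    """Render a dual-channel time-lapse movie with full ground truth.

    The tracked-cell channel ("treg") holds Gaussian blobs (sigma =
    diameter / (2*sqrt(2)), matching the detector's blob-scale
    relation) over a dark background; the stromal channel ("caf")
    holds a static speckle texture (mean-matched to its background, so
    only local contrast distinguishes it) inside the true mask.  Read
    noise of ``noise_sd`` is added independently per frame.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("image dimensions must be positive")
    if model is None:
        model = antigen_model()
    rng = np.random.default_rng(seed)

    mask = _render_mask(mask_spec, shape, pixel_size_um, rng)
    cell_radius_um = cell_diameter_um / 2.0
    if n_cells > 0:
        pos, arrested, contact = simulate_tracks(
            n_cells, n_frames, model, mask, rng, pixel_size_um, cell_radius_um
        )
    else:
        pos = np.zeros((0, n_frames, 2))
        arrested = np.zeros((0, n_frames), dtype=bool)
        contact = np.zeros((0, n_frames), dtype=bool)

    # stromal texture: background 100, uniform +-28 speckle inside the mask
    # (contrast sigma/mu ~ 0.16, twice the default segmentation epsilon)
    caf_base = np.full(shape, 100.0)
    texture = rng.uniform(-28.0, 28.0, size=shape)
    caf_base[mask] += texture[mask]

    sigma_px = (cell_diameter_um / pixel_size_um) / (2.0 * math.sqrt(2.0))
    treg = np.empty((n_frames, h, w), dtype=np.float64)
    caf = np.empty((n_frames, h, w), dtype=np.float64)
    for t in range(n_frames):
        frame = np.full(shape, 10.0)
        for c in range(n_cells):
            x, y = pos[c, t]
            _add_gaussian_blob(frame, x, y, sigma_px, cell_amplitude)
        treg[t] = frame + rng.normal(0.0, noise_sd, size=shape)
        caf[t] = caf_base + rng.normal(0.0, noise_sd, size=shape)

    movie = Movie(
        channels={"treg": treg, "caf": caf},
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
    )
    truth = GroundTruth(
        positions_px=pos,
        mask=mask,
        contact=contact,
        arrested=arrested,
        episodes=truth_episodes_from_contact(contact, frame_interval_min),
    )
    return movie, truth


# --------------------------------------------------------------------------
# immunofluorescence field generator
# --------------------------------------------------------------------------


def _place_points(
    allowed: np.ndarray,
    n: int,
    min_sep_px: float,
    rng: np.random.Generator,
    max_tries: int = 20000,
) -> np.ndarray:
    """Sample n points (x, y) on allowed pixels with minimal separation."""
    ys, xs = np.nonzero(allowed)
    if ys.size == 0 and n > 0:
        raise OvercrowdingError("no admissible area to place cells")
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise OvercrowdingError(
                f"placed only {len(pts)} of {n} cells without overlap"
            )
        k = rng.integers(0, ys.size)
        x, y = float(xs[k]), float(ys[k])
        if all((x - a) ** 2 + (y - b) ** 2 >= min_sep_px**2 for a, b in pts):
            pts.append((x, y))
    return np.array(pts).reshape(-1, 2)


def generate_if_field(
    n_cells_rich_region: int,
    n_cells_poor_region: int,
    marker_area_fraction: float,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.5,
    nucleus_diameter_um: float = 8.0,
    nucleus_amplitude: float = 120.0,
    noise_sd: float = 1.5,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render a two-channel IF field: nuclei + marker.

    The marker-positive region is a smoothed random field thresholded
    at the quantile matching ``marker_area_fraction`` (exact to one
    pixel in the histogram); nuclei are Gaussian blobs placed well
    inside (rich) or well outside (poor) the marker region with a
    minimal separation of 1.5 nucleus diameters.
    """
    if not 0.0 <= marker_area_fraction <= 1.0:
        raise ValueError("marker_area_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape

    if marker_area_fraction == 0.0:
        marker_mask = np.zeros(shape, dtype=bool)
    elif marker_area_fraction == 1.0:
        marker_mask = np.ones(shape, dtype=bool)
    else:
        g = ndi.gaussian_filter(rng.normal(size=shape), 24.0, mode="reflect")
        thr = np.quantile(g, 1.0 - marker_area_fraction)
        marker_mask = g > thr

    d_px = nucleus_diameter_um / pixel_size_um
    margin_px = d_px / 2.0 + 2.0
    sep_px = 1.5 * d_px
    if marker_mask.any():
        edt_in = ndi.distance_transform_edt(marker_mask)
        edt_out = ndi.distance_transform_edt(~marker_mask)
    else:
        edt_in = np.zeros(shape)
        edt_out = np.full(shape, np.inf)
    border = np.zeros(shape, dtype=bool)
    b = int(math.ceil(margin_px))
    border[b:-b, b:-b] = True

    rich = _place_points(border & (edt_in >= margin_px), n_cells_rich_region, sep_px, rng)
    poor = _place_points(border & (edt_out >= margin_px), n_cells_poor_region, sep_px, rng)

    sigma_px = d_px / (2.0 * math.sqrt(2.0))
    nuclei = np.full(shape, 5.0)
    for x, y in np.vstack([rich, poor]) if (len(rich) or len(poor)) else []:
        _add_gaussian_blob(nuclei, x, y, sigma_px, nucleus_amplitude)
    nuclei += rng.normal(0.0, noise_sd, size=shape)

    marker = np.full(shape, 5.0)
    marker[marker_mask] += 80.0
    marker = ndi.gaussian_filter(marker, 1.0, mode="reflect")
    marker += rng.normal(0.0, noise_sd, size=shape)

    truth = GroundTruth(
        marker_mask=marker_mask,
        marker_area_fraction=float(marker_mask.mean()),
        centers_rich=rich,
        centers_poor=poor,
        cell_count_rich=n_cells_rich_region,
        cell_count_poor=n_cells_poor_region,
    )
    return {"nuclei": nuclei, "marker": marker}, truth


# --------------------------------------------------------------------------
# puncta image generator
# --------------------------------------------------------------------------


def generate_puncta_image(
    cells: Sequence[tuple[tuple[float, float], float, int]],
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.2,
    punctum_diameter_um: float = 0.8,
    punctum_amplitude: float = 100.0,
    noise_sd: float = 1.0,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render nuclei / cytoplasm / puncta channels for listed cells.

    ``cells`` entries are ((x_um, y_um), radius_um, n_puncta).  Puncta
    are small bright Gaussians placed inside the cell radius with a
    minimal separation of two punctum diameters; the cytoplasm is a
    smooth-edged dim disk, the nucleus a central blob.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]

    cyto = np.zeros(shape)
    nuclei = np.full(shape, 2.0)
    puncta = np.full(shape, 2.0)
    counts: list[int] = []
    centers = []
    radii = []

    p_sigma = (punctum_diameter_um / pixel_size_um) / (2.0 * math.sqrt(2.0))
    p_sep = 2.0 * punctum_diameter_um / pixel_size_um

    for (x_um, y_um), radius_um, n_puncta in cells:
        if n_puncta < 0:
            raise ValueError("puncta count must be >= 0")
        cx, cy = x_um / pixel_size_um, y_um / pixel_size_um
        r_px = radius_um / pixel_size_um
        margin = punctum_diameter_um / pixel_size_um
        if n_puncta > 0 and r_px <= margin:
            raise ValueError("puncta do not fit inside the cell radius")
        cyto += ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2) * 35.0
        _add_gaussian_blob(nuclei, cx, cy, max(2.0, r_px / 4.0), 100.0)

        pts: list[tuple[float, float]] = []
        tries = 0
        while len(pts) < n_puncta:
            tries += 1
            if tries > 10000:
                raise OvercrowdingError("cannot place puncta without overlap")
            rad = (r_px - margin) * math.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * math.pi)
            px_, py_ = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
            if all((px_ - a) ** 2 + (py_ - b) ** 2 >= p_sep**2 for a, b in pts):
                pts.append((px_, py_))
        for px_, py_ in pts:
            _add_gaussian_blob(puncta, px_, py_, p_sigma, punctum_amplitude)
        counts.append(int(n_puncta))
        centers.append((cx, cy))
        radii.append(r_px)

    cyto = ndi.gaussian_filter(cyto, 2.0, mode="reflect") + 5.0
    for arr in (cyto, nuclei, puncta):
        arr += rng.normal(0.0, noise_sd, size=shape)

    truth = GroundTruth(
        puncta_counts=counts,
        cell_centers_px=np.array(centers).reshape(-1, 2),
        cell_radii_px=np.array(radii),
    )
    return {"nuclei": nuclei, "cytoplasm": cyto, "puncta": puncta}, truth


# --------------------------------------------------------------------------
# recovery evaluation against ground truth
# --------------------------------------------------------------------------


def match_tracks_to_truth(
    tracks: Sequence[Track],
    truth: GroundTruth,
    pixel_size_um: float,
    max_dist_um: float = 8.0,
) -> dict[int, int]:
    """Map recovered track ids to true cell ids by per-frame proximity.

    For every observed spot, the nearest true cell at that frame within
    ``max_dist_um`` votes; the majority cell wins the track.  Tracks
    with no votes are unmapped.
    """
    pos = truth.positions_px  # (n_cells, n_frames, 2) as (x, y)
    n_frames = pos.shape[1]
    mapping: dict[int, int] = {}
    max_px = max_dist_um / pixel_size_um
    for tr in tracks:
        votes: dict[int, int] = {}
        for s in tr.spots:
            if not 0 <= s.frame < n_frames:
                continue
            d = np.hypot(pos[:, s.frame, 0] - s.x_px, pos[:, s.frame, 1] - s.y_px)
            if d.size == 0:
                continue
            c = int(np.argmin(d))
            if d[c] <= max_px:
                votes[c] = votes.get(c, 0) + 1
        if votes:
            mapping[tr.track_id] = max(sorted(votes), key=lambda k: votes[k])
    return mapping


def episode_cell_map(
    predicted: Sequence[ContactEpisode],
    tracks: Sequence[Track],
    truth: GroundTruth,
    pixel_size_um: float,
    max_dist_um: float = 8.0,
) -> dict[int, int]:
    """Attribute each predicted episode to a true cell.

    The nearest true cell within ``max_dist_um`` votes at every track
    spot inside the episode's frame span; the majority wins.  Using
    the episode's own frames (rather than the whole track) keeps the
    attribution correct even when a track swaps identity between two
    cells outside the episode.  Keys are indices into ``predicted``.
    """
    by_id = {tr.track_id: tr for tr in tracks}
    pos = truth.positions_px
    n_frames = pos.shape[1]
    max_px = max_dist_um / pixel_size_um
    out: dict[int, int] = {}
    for i, ep in enumerate(predicted):
        tr = by_id.get(ep.track_id)
        if tr is None:
            continue
        votes: dict[int, int] = {}
        for s in tr.spots:
            if not (ep.start_frame <= s.frame <= ep.end_frame) or not (
                0 <= s.frame < n_frames
            ):
                continue
            d = np.hypot(pos[:, s.frame, 0] - s.x_px, pos[:, s.frame, 1] - s.y_px)
            if d.size == 0:
                continue
            c = int(np.argmin(d))
            if d[c] <= max_px:
                votes[c] = votes.get(c, 0) + 1
        if votes:
            out[i] = max(sorted(votes), key=lambda k: votes[k])
    return out


def episode_recovery_scores(
    predicted: Sequence[ContactEpisode],
    episode_cells: dict[int, int],
    truth_episodes: Sequence[ContactEpisode],
    min_frames: int = 2,
) -> tuple[float, float, float]:
    """Precision / recall / F1 of recovered episodes against truth.

    ``episode_cells`` maps predicted-episode index to the attributed
    true cell (see :func:`episode_cell_map`).  Truth episodes shorter
    than ``min_frames`` are dropped (the pipeline cannot report them).
    A predicted episode matches a truth episode when it is attributed
    to the truth cell and the frame intervals overlap; matching is
    one-to-one, greedy by overlap length.
    """
    truth_f = [e for e in truth_episodes if e.n_frames >= min_frames]
    cands = []
    for i, p in enumerate(predicted):
        cell = episode_cells.get(i)
        if cell is None:
            continue
        for j, t in enumerate(truth_f):
            if t.track_id != cell:
                continue
            ov = min(p.end_frame, t.end_frame) - max(p.start_frame, t.start_frame) + 1
            if ov >= 1:
                cands.append((ov, i, j))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = 0
    for _, i, j in cands:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches += 1
    precision = matches / len(predicted) if predicted else (1.0 if not truth_f else 0.0)
    recall = matches / len(truth_f) if truth_f else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1
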