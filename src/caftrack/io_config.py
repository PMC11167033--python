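"""Image / table I/O, run configuration and the assembled movie pipeline.

The unit of time-lapse analysis is a :class:`Movie`: per-channel frame
stacks plus the physical metadata (µm per pixel, minutes per frame)
that every distance and duration in the pipeline is expressed through.
Multi-page TIFFs are read channel-interleaved (page i belongs to
channel i mod n_channels); tables are plain comma-separated UTF-8 with
a mandatory header, no index column and floats at 6 significant
digits, so a rewrite of identical results is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .contact_analysis import (
    ContactEpisode,
    ContactParams,
    arrest_coefficient,
    contact_timeline,
    extract_episodes,
)
from .segmentation import SegmentationMask, SegmentationParams, segment_texture
from .spot_detection import DetectionParams, Spot, detect_spots
from .tracking import (
    LinkingParams,
    Track,
    build_tracklets,
    close_gaps,
    trajectory_stats,
)

__all__ = [
    "Movie",
    "RunConfig",
    "SpatialParams",
    "PipelineStageError",
    "PipelineResult",
    "read_movie",
    "write_movie",
    "write_table",
    "write_mask_png",
    "run_pipeline",
    "write_pipeline_outputs",
]

logger = logging.getLogger("caftrack")

TRACKS_COLUMNS = ["track_id", "frame", "x_px", "y_px", "quality", "gap_closed"]
EPISODES_COLUMNS = ["track_id", "start_frame", "end_frame", "n_frames", "duration_min"]
STATS_COLUMNS = [
    "track_id",
    "path_length_um",
    "net_displacement_um",
    "confinement_ratio",
    "duration_min",
    "n_spots",
    "arrest_coefficient",
]
DETECTIONS_COLUMNS = ["frame", "x_px", "y_px", "quality"]
FIELDS_COLUMNS = [
    "field_id",
    "experiment_id",
    "marker_area_fraction",
    "region_class",
    "cell_count",
    "region_area_px",
    "density",
]
PUNCTA_COLUMNS = ["cell_id", "channel", "puncta_count", "cell_area_px"]


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------


@dataclass
class Movie:
    """Per-channel frame stacks with physical metadata.

    channels maps channel name to a (n_frames, H, W) float array; all
    channels share one shape; pixel size and frame interval are
    strictly positive.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    frame_interval_min: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("movie must have at least one channel")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one (T, H, W) shape")
        (shape,) = shapes
        if len(shape) != 3 or shape[0] < 1:
            raise ValueError("each channel must be a (n_frames>=1, H, W) stack")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be > 0")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]


def read_movie(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_min: float,
    channel_names: Sequence[str] = ("treg",),
) -> Movie:
    """Read a channel-interleaved multi-page TIFF into a Movie.

    The page count must be divisible by the channel count; page i is
    frame i // n_channels of channel i mod n_channels, in acquisition
    order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such movie file: {path}")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    if not frame_interval_min > 0:
        raise ValueError("frame_interval_min must be > 0")
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2-D pages, got shape {pages.shape}")
    n_ch = len(channel_names)
    if pages.shape[0] % n_ch != 0:
        raise ValueError(
            f"page count {pages.shape[0]} not divisible by channel count {n_ch}"
        )
    channels = {
        name: np.asarray(pages[i::n_ch], dtype=np.float64)
        for i, name in enumerate(channel_names)
    }
    return Movie(
        channels=channels,
        pixel_size_um=float(pixel_size_um),
        frame_interval_min=float(frame_interval_min),
    )


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a Movie as a channel-interleaved multi-page float32 TIFF."""
    names = movie.channel_names
    t, h, w = (movie.n_frames, *movie.frame_shape)
    pages = np.empty((t * len(names), h, w), dtype=np.float32)
    for i, name in enumerate(names):
        pages[i :: len(names)] = movie.channels[name]
    tifffile.imwrite(str(path), pages, photometric="minisblack")


def write_table(
    records: Sequence[Any], path: str | Path, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Write homogeneous records (dataclasses or dicts) as CSV.

    Column order is the dataclass field order unless ``columns`` is
    given; floats are rendered with 6 significant digits; an empty
    record list with explicit columns yields a header-only file.
    """
    rows = []
    for r in records:
        rows.append(dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r))
    if rows:
        inferred = list(rows[0].keys())
        df = pd.DataFrame(rows, columns=list(columns) if columns else inferred)
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
    return df


def write_mask_png(mask: np.ndarray | SegmentationMask, path: str | Path) -> None:
    import imageio.v3 as iio

    arr = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    iio.imwrite(str(path), (arr.astype(np.uint8) * 255))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialParams:
    """Spatial-density options: 0 = whole-field regions, n>0 = n x n tiling."""

    tile_grid: int = 0

    def __post_init__(self) -> None:
        if self.tile_grid < 0:
            raise ValueError("tile_grid must be >= 0")


def _params_from_dict(cls, d: Mapping[str, Any]):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of a pipeline run; round-trips through YAML."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    contact: ContactParams = field(default_factory=ContactParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    seed: int = 0
    outdir: str = "results"
    static_mask: bool = False  # segment the stromal channel once (frame 0)

    _BLOCKS = {
        "detection": DetectionParams,
        "linking": LinkingParams,
        "segmentation": SegmentationParams,
        "contact": ContactParams,
        "spatial": SpatialParams,
    }

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in self._BLOCKS:
            out[name] = dataclasses.asdict(getattr(self, name))
        out["seed"] = self.seed
        out["outdir"] = self.outdir
        out["static_mask"] = self.static_mask
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        scalars = {"seed", "outdir", "static_mask"}
        unknown = set(d) - set(cls._BLOCKS) - scalars
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, sub in cls._BLOCKS.items():
            if name in d:
                kwargs[name] = _params_from_dict(sub, d[name] or {})
        for name in scalars:
            if name in d:
                kwargs[name] = d[name]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping of parameter blocks")
        return cls.from_dict(data)


# --------------------------------------------------------------------------
# assembled pipeline
# --------------------------------------------------------------------------


class PipelineStageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    detections: dict[int, list[Spot]]
    masks: dict[int, SegmentationMask]
    tracks: list[Track]
    episodes: list[ContactEpisode]
    stats: list[dict[str, Any]]
    summary: dict[str, Any]


def run_pipeline(
    config: RunConfig,
    movie: Movie,
    tracked_channel: str = "treg",
    stromal_channel: str = "caf",
    masks: Mapping[int, SegmentationMask | np.ndarray] | None = None,
) -> PipelineResult:
    """Detect, track, segment and extract contact episodes for one movie.

    The movie must contain the tracked-cell channel and either the
    stromal channel or precomputed ``masks`` (frame -> boolean mask).
    The run is deterministic for a fixed config and input.
    """
    if tracked_channel not in movie.channels:
        raise ValueError(f"movie lacks tracked channel {tracked_channel!r}")
    if masks is None and stromal_channel not in movie.channels:
        raise ValueError(
            f"movie lacks stromal channel {stromal_channel!r} and no masks given"
        )
    logger.info("pipeline parameters: %s", config.to_dict())

    px = movie.pixel_size_um
    try:
        detections = {
            f: detect_spots(movie.channels[tracked_channel][f], config.detection, px, frame=f)
            for f in range(movie.n_frames)
        }
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineStageError("detection", e) from e

    try:
        if masks is not None:
            seg = {
                f: (m if isinstance(m, SegmentationMask) else SegmentationMask.from_array(m))
                for f, m in masks.items()
            }
        elif config.static_mask:
            m0 = segment_texture(movie.channels[stromal_channel][0], config.segmentation)
            seg = {f: m0 for f in range(movie.n_frames)}
        else:
            seg = {
                f: segment_texture(movie.channels[stromal_channel][f], config.segmentation)
                for f in range(movie.n_frames)
            }
    except Exception as e:
        raise PipelineStageError("segmentation", e) from e

    try:
        tracklets = build_tracklets(detections, config.linking, px)
        tracks = close_gaps(tracklets, config.linking, px)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineStageError("tracking", e) from e

    contact = dataclasses.replace(
        config.contact, frame_interval_min=movie.frame_interval_min
    )
    episodes: list[ContactEpisode] = []
    stats_rows: list[dict[str, Any]] = []
    edt_cache: dict[int, np.ndarray] = {}
    try:
        for tr in tracks:
            timeline = contact_timeline(tr, seg, contact, px, edt_cache=edt_cache)
            frames = [s.frame for s in tr.spots]
            episodes.extend(
                extract_episodes(timeline, contact, frames=frames, track_id=tr.track_id)
            )
            st = trajectory_stats(tr, px, movie.frame_interval_min)
            row = dataclasses.asdict(st)
            row["arrest_coefficient"] = arrest_coefficient(timeline) if timeline else 0.0
            stats_rows.append(row)
    except Exception as e:
        raise PipelineStageError("contact", e) from e

    durations = [e.duration_min for e in episodes]
    summary = {
        "n_tracks": len(tracks),
        "n_episodes": len(episodes),
        "mean_duration_min": float(np.mean(durations)) if durations else 0.0,
        "median_duration_min": float(np.median(durations)) if durations else 0.0,
        "mean_arrest_coefficient": (
            float(np.mean([r["arrest_coefficient"] for r in stats_rows]))
            if stats_rows
            else 0.0
        ),
    }
    return PipelineResult(
        detections=detections,
        masks=seg,
        tracks=tracks,
        episodes=episodes,
        stats=stats_rows,
        summary=summary,
    )


def tracks_to_records(tracks: Sequence[Track]) -> list[dict[str, Any]]:
    rows = []
    for tr in tracks:
        for s, gap in zip(tr.spots, tr.gap_closed):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": s.frame,
                    "x_px": s.x_px,
                    "y_px": s.y_px,
                    "quality": s.quality,
                    "gap_closed": int(gap),
                }
            )
    return rows


def write_pipeline_outputs(
    result: PipelineResult,
    config: RunConfig,
    outdir: str | Path,
    plots: bool = False,
    pixel_size_um: float = 1.0,
) -> None:
    """Write tracks/episodes/stats/summary CSVs, masks and the resolved config.

    With ``plots=True`` also writes a contact-duration violin and an
    origin-centered trajectory rose plot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    det_rows = [
        {"frame": s.frame, "x_px": s.x_px, "y_px": s.y_px, "quality": s.quality}
        for f in sorted(result.detections)
        for s in result.detections[f]
    ]
    write_table(det_rows, outdir / "detections.csv", columns=DETECTIONS_COLUMNS)
    write_table(tracks_to_records(result.tracks), outdir / "tracks.csv", columns=TRACKS_COLUMNS)
    write_table(result.episodes, outdir / "episodes.csv", columns=EPISODES_COLUMNS)
    write_table(result.stats, outdir / "stats.csv", columns=STATS_COLUMNS)
    write_table([result.summary], outdir / "summary.csv", columns=list(result.summary))
    maskdir = outdir / "masks"
    maskdir.mkdir(exist_ok=True)
    for f, m in sorted(result.masks.items()):
        write_mask_png(m, maskdir / f"mask_{f:04d}.png")
    config.to_yaml(outdir / "config_resolved.yaml")
    if plots:
        from .contact_analysis import save_violin_plot
        from .tracking import save_trajectory_plot

        durations = [e.duration_min for e in result.episodes]
        if durations:
            save_violin_plot({"all": durations}, outdir / "durations_violin.png")
        if result.tracks:
            save_trajectory_plot(
                result.tracks, outdir / "trajectories.png", pixel_size_um
            )
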