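"""CAF-rich vs CAF-poor classification and per-region cell densities.

Fields of view are classified within each experiment by comparing their
marker-positive (e.g. alpha-SMA) area fraction to the experiment median:
strictly above the median is "rich", at or below is "poor".  Cell counts
per region are automated spot detections whose centers fall inside the
region mask, and density is reported per 10^6 pixels of region area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spot_detection import DetectionParams, detect_spots

__all__ = [
    "FieldQuantification",
    "classify_fields",
    "count_cells_in_region",
    "density",
    "quantify_experiment",
]

CELLS_PER = 1_000_000  # density denominator: cells per 10^6 px


@dataclass(frozen=True)
class FieldQuantification:
    field_id: str
    experiment_id: str
    marker_area_fraction: float
    region_class: str  # "rich" | "poor"
    cell_count: int
    region_area_px: int
    density: float  # cells per 10^6 px


def classify_fields(
    fields: Sequence[tuple[str, float]],
) -> dict[str, str]:
    """Median-split one experiment's fields into "rich"/"poor".

    ``fields`` is (field_id, marker_area_fraction) pairs from a single
    experiment (>= 2 required).  Fractions strictly above the
    experiment median are "rich"; ties with the median go to "poor".
    """
    if len(fields) < 2:
        raise ValueError("need >= 2 fields per experiment to take a median")
    fractions = np.array([f for _, f in fields], dtype=float)
    med = float(np.median(fractions))
    return {fid: ("rich" if frac > med else "poor") for fid, frac in fields}


def count_cells_in_region(
    channel: np.ndarray,
    region_mask: np.ndarray,
    params: DetectionParams,
    pixel_size_um: float,
) -> int:
    """Count detected spots whose centers lie inside the region mask."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != channel.shape:
        raise ValueError("region mask and channel must share a shape")
    spots = detect_spots(channel, params, pixel_size_um)
    count = 0
    for s in spots:
        yi = int(np.clip(round(s.y_px), 0, region_mask.shape[0] - 1))
        xi = int(np.clip(round(s.x_px), 0, region_mask.shape[1] - 1))
        if region_mask[yi, xi]:
            count += 1
    return count


def density(cell_count: int, region_area_px: int) -> float:
    """Cells per 10^6 pixels of region area."""
    if region_area_px <= 0:
        raise ValueError("region_area_px must be > 0")
    return cell_count / region_area_px * CELLS_PER


def quantify_experiment(
    experiment_id: str,
    fields: Sequence[tuple[str, float, int, int]],
) -> list[FieldQuantification]:
    """Assemble per-field rows for one experiment.

    ``fields`` rows are (field_id, marker_area_fraction, cell_count,
    region_area_px); the rich/poor class is assigned by the experiment
    median of the fractions.
    """
    classes = classify_fields([(fid, frac) for fid, frac, _, _ in fields])
    out = []
    for fid, frac, count, area in fields:
        out.append(
            FieldQuantification(
                field_id=fid,
                experiment_id=experiment_id,
                marker_area_fraction=frac,
                region_class=classes[fid],
                cell_count=count,
                region_area_px=area,
                density=density(count, area),
            )
        )
    return out
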