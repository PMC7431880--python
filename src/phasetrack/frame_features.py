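"""Per-frame morphometric and QPI features and multivariate series assembly.

For every (cell, frame) pair the module computes nine scalar shape
features plus the centroid (kept aside for motion features) and seven
statistics of the phase values inside the cell footprint.  A complete
track then yields an n x d multivariate time series (n frames, d = 16
scalar features) — the object every time-lapse transform consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage.measure import regionprops

from .recon import PhaseImage
from .tracking import CellTrack

__all__ = [
    "MORPHOMETRIC_NAMES",
    "QPI_NAMES",
    "SERIES_FEATURE_NAMES",
    "FrameFeatureVector",
    "MultivariateSeries",
    "morphometric_features",
    "qpi_features",
    "frame_feature_table",
    "build_series",
]

MORPHOMETRIC_NAMES = (
    "footprint_area_um2",
    "perimeter_um",
    "convex_area_um2",
    "convex_perimeter_um",
    "solidity",
    "roundness",
    "indentation",
    "eccentricity",
    "extent",
)

QPI_NAMES = (
    "total_phase",
    "mean_phase",
    "median_phase",
    "phase_variance",
    "phase_std",
    "phase_skewness",
    "phase_kurtosis",
)

#: Column order of the multivariate series (centroid excluded; it feeds the
#: motion features instead).
SERIES_FEATURE_NAMES = MORPHOMETRIC_NAMES + QPI_NAMES


@dataclass
class FrameFeatureVector:
    cell_id: int
    frame_index: int
    morphometric: Dict[str, float]
    qpi: Dict[str, float]
    centroid_px: Tuple[float, float]


@dataclass
class MultivariateSeries:
    """n x d feature table of one cell over its observation window."""

    cell_id: int
    values: np.ndarray  # shape (n, d)
    feature_names: Tuple[str, ...]
    frame_interval_min: float
    centroids_px: np.ndarray  # shape (n, 2), (row, col)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("series values must be 2-D (frames x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains missing or non-finite entries")


def _region_of(labels: np.ndarray, label: int):
    props = regionprops((labels == label).astype(np.uint8))
    if not props:
        raise ValueError(f"empty region for label {label}")
    return props[0]


def morphometric_features(
    labels: np.ndarray, label: int, pixel_size_um: float = 1.0
) -> Tuple[Dict[str, float], Tuple[float, float]]:
    """Nine scalar shape features of one labelled region, plus its centroid.

    Areas scale with the pixel area, perimeters with the pixel pitch;
    solidity, roundness (4*pi*A/P^2), indentation (P/P_convex),
    eccentricity (from normalised second central moments) and extent are
    dimensionless.  The centroid is returned separately in pixel units,
    (row, col), 0-based.
    """
    region = _region_of(np.asarray(labels), label)
    px = pixel_size_um
    area = float(region.area) * px * px
    perimeter = float(region.perimeter) * px
    convex_area = float(region.area_convex) * px * px
    convex_perimeter = (
        float(regionprops(region.image_convex.astype(np.uint8))[0].perimeter) * px
    )
    feats = {
        "footprint_area_um2": area,
        "perimeter_um": perimeter,
        "convex_area_um2": convex_area,
        "convex_perimeter_um": convex_perimeter,
        "solidity": float(region.solidity),
        "roundness": 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else 0.0,
        "indentation": perimeter / convex_perimeter if convex_perimeter > 0 else 0.0,
        "eccentricity": float(region.eccentricity),
        "extent": float(region.extent),
    }
    return feats, (float(region.centroid[0]), float(region.centroid[1]))


def qpi_features(labels: np.ndarray, label: int, phase: PhaseImage) -> Dict[str, float]:
    """Seven statistics of the phase values inside one region.

    Variance and standard deviation are population moments; skewness and
    kurtosis are the standardised third and fourth central moments
    (kurtosis non-excess, i.e. 3 for a Gaussian).  Zero-variance regions
    report skewness and kurtosis of 0 by convention so series stay
    complete.
    """
    mask = np.asarray(labels) == label
    if not mask.any():
        raise ValueError(f"empty region for label {label}")
    vals = phase.values[mask].astype(float)
    var = float(np.var(vals))
    if var > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(sstats.skew(vals, bias=True))
            kurt = float(sstats.kurtosis(vals, fisher=False, bias=True))
        if not np.isfinite(skew):  # near-constant region: same convention
            skew = 0.0
        if not np.isfinite(kurt):
            kurt = 0.0
    else:
        skew = kurt = 0.0
    return {
        "total_phase": float(vals.sum()),
        "mean_phase": float(vals.mean()),
        "median_phase": float(np.median(vals)),
        "phase_variance": var,
        "phase_std": float(np.sqrt(var)),
        "phase_skewness": skew,
        "phase_kurtosis": kurt,
    }


def frame_feature_table(
    phase_frames: Sequence[PhaseImage],
    masks: Sequence[np.ndarray],
    tracks: Sequence[CellTrack],
) -> pd.DataFrame:
    """One row per (cell_id, frame) with all named feature columns."""
    rows: List[dict] = []
    for track in tracks:
        for frame_index, label, _ in track.frames:
            labels = masks[frame_index]
            phase = phase_frames[frame_index]
            morpho, centroid = morphometric_features(
                labels, label, phase.pixel_size_um
            )
            row = {"cell_id": track.cell_id, "frame": frame_index}
            row.update(morpho)
            row.update(qpi_features(labels, label, phase))
            row["centroid_row_px"] = centroid[0]
            row["centroid_col_px"] = centroid[1]
            rows.append(row)
    return pd.DataFrame(rows)


def build_series(
    track: CellTrack,
    feature_table: pd.DataFrame,
    frame_interval_min: float = 5.0,
) -> MultivariateSeries:
    """Assemble one cell's multivariate time series from the frame table.

    Requires a complete (gap-free) track; any missing frame raises.
    Row t holds the features at the track's t-th frame in the fixed
    :data:`SERIES_FEATURE_NAMES` column order.
    """
    sub = feature_table[feature_table["cell_id"] == track.cell_id].set_index("frame")
    idx = track.frame_indices
    if any(b - a != 1 for a, b in zip(idx, idx[1:])):
        raise ValueError("track has frame gaps; complete tracks only")
    missing = [t for t in idx if t not in sub.index]
    if missing:
        raise ValueError(f"missing frames {missing} for cell {track.cell_id}")
    sub = sub.loc[idx]
    values = sub[list(SERIES_FEATURE_NAMES)].to_numpy(dtype=float)
    centroids = sub[["centroid_row_px", "centroid_col_px"]].to_numpy(dtype=float)
    return MultivariateSeries(
        cell_id=track.cell_id,
        values=values,
        feature_names=SERIES_FEATURE_NAMES,
        frame_interval_min=frame_interval_min,
        centroids_px=centroids,
    )
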