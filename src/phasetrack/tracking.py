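"""Cell segmentation, ROI filtering, and frame-to-frame track linking.

Segmentation is marker-controlled watershed on the compensated phase:
foreground pixels lie above a phase threshold, markers are the connected
plateaus of the h-maxima of the Gaussian-smoothed phase, and the
watershed of the inverted smoothed phase splits touching cells along
their saddle.  ROI filtering drops regions on the image border and
regions whose solidity betrays an unresolved overlap.  Linking is greedy
mutual-nearest-centroid matching per frame pair with a maximum
displacement gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .recon import PhaseImage

__all__ = [
    "LabelMask",
    "CellTrack",
    "segment_frame",
    "filter_rois",
    "link_tracks",
    "select_complete_tracks",
    "track_purity",
]


@dataclass
class LabelMask:
    """Per-frame integer label map; 0 is background."""

    labels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer map")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def region_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[lab > 0]


@dataclass
class CellTrack:
    """One cell's identity through consecutive frames."""

    cell_id: int
    frames: List[Tuple[int, int, Tuple[float, float]]] = field(default_factory=list)
    # entries: (frame_index, region_label, centroid_px (row, col))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_indices(self) -> List[int]:
        return [f[0] for f in self.frames]

    @property
    def centroids(self) -> np.ndarray:
        return np.array([f[2] for f in self.frames], dtype=float)


def segment_frame(
    phase: PhaseImage,
    threshold: float = 0.1,
    min_area_px: int = 20,
    smooth_sigma: float = 2.0,
    marker_h: float = 0.3,
    frame_index: int = 0,
) -> LabelMask:
    """Marker-controlled watershed segmentation of a compensated phase frame.

    Parameters are in the units of the phase image (radians by default):
    ``threshold`` separates foreground from the ~zero background,
    ``marker_h`` is the minimum prominence of a marker plateau.
    """
    values = phase.values
    smoothed = ndi.gaussian_filter(values, smooth_sigma)
    # threshold the raw image: smoothing shifts the shallow footprint tail
    # outward, so the foreground contour comes from the unsmoothed phase
    foreground = values > threshold
    if not foreground.any():
        return LabelMask(np.zeros(values.shape, dtype=np.int32), frame_index)
    peaks = h_maxima(smoothed, marker_h)
    markers = cc_label(peaks & foreground, connectivity=1)
    if markers.max() == 0:
        markers = cc_label(foreground, connectivity=1)
    seg = watershed(-smoothed, markers=markers, mask=foreground, connectivity=1)
    # drop dust and relabel contiguously
    sizes = np.bincount(seg.ravel())
    keep = np.where(sizes >= min_area_px)[0]
    keep = keep[keep > 0]
    remap = np.zeros(sizes.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabelMask(remap[seg], frame_index)


def filter_rois(
    mask: LabelMask,
    overlap_flagged: Optional[Set[int]] = None,
    solidity_threshold: float = 0.8,
) -> LabelMask:
    """Drop border-touching regions and unresolved overlaps.

    A region counts as an unresolved overlap when its label is in
    ``overlap_flagged`` or its solidity falls below
    ``solidity_threshold``.  Idempotent.
    """
    labels = mask.labels
    drop: Set[int] = set(overlap_flagged or ())
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    drop.update(int(b) for b in border if b > 0)
    for region in regionprops(labels):
        if region.solidity < solidity_threshold:
            drop.add(int(region.label))
    if not drop:
        return LabelMask(labels.copy(), mask.frame_index)
    out = labels.copy()
    out[np.isin(out, list(drop))] = 0
    # relabel contiguously, preserving order
    remaining = np.unique(out)
    remaining = remaining[remaining > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    remap[remaining] = np.arange(1, remaining.size + 1, dtype=labels.dtype)
    return LabelMask(remap[out], mask.frame_index)


def _centroids(mask: LabelMask) -> Dict[int, Tuple[float, float]]:
    out: Dict[int, Tuple[float, float]] = {}
    for region in regionprops(mask.labels):
        out[int(region.label)] = (float(region.centroid[0]), float(region.centroid[1]))
    return out


def link_tracks(masks: Sequence[LabelMask], max_disp_px: float = 20.0) -> List[CellTrack]:
    """Link segmented cells across frames into tracks.

    Greedy mutual-nearest-centroid matching per consecutive frame pair:
    a link is kept only when the two regions are each other's nearest
    candidate and closer than ``max_disp_px``; a region claimed at equal
    distance by two cells is left unmatched (ambiguity), and unmatched
    regions open new tracks.  Equal-distance ties break towards the lower
    label index.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 frames to link")
    tracks: List[CellTrack] = []
    open_tracks: Dict[int, CellTrack] = {}  # keyed by current region label
    prev_cent = _centroids(masks[0])
    for lab in sorted(prev_cent):
        t = CellTrack(cell_id=len(tracks), frames=[(masks[0].frame_index, lab, prev_cent[lab])])
        tracks.append(t)
        open_tracks[lab] = t
    for mask in masks[1:]:
        cur_cent = _centroids(mask)
        prev_labels = sorted(prev_cent)
        cur_labels = sorted(cur_cent)
        matches: Dict[int, int] = {}
        if prev_labels and cur_labels:
            p = np.array([prev_cent[l] for l in prev_labels])
            c = np.array([cur_cent[l] for l in cur_labels])
            dist = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
            nearest_cur = dist.argmin(axis=1)  # argmin breaks ties to lower index
            nearest_prev = dist.argmin(axis=0)
            for i, lab_p in enumerate(prev_labels):
                j = int(nearest_cur[i])
                if int(nearest_prev[j]) != i:
                    continue  # not mutual (covers two-cells-one-region ambiguity)
                if dist[i, j] > max_disp_px:
                    continue
                matches[lab_p] = cur_labels[j]
        next_open: Dict[int, CellTrack] = {}
        for lab_p, lab_c in matches.items():
            track = open_tracks.get(lab_p)
            if track is None:
                continue
            track.frames.append((mask.frame_index, lab_c, cur_cent[lab_c]))
            next_open[lab_c] = track
        for lab_c in cur_labels:
            if lab_c not in next_open:
                t = CellTrack(
                    cell_id=len(tracks),
                    frames=[(mask.frame_index, lab_c, cur_cent[lab_c])],
                )
                tracks.append(t)
                next_open[lab_c] = t
        open_tracks = next_open
        prev_cent = cur_cent
    return tracks


def select_complete_tracks(
    tracks: Iterable[CellTrack], window_len: int = 30
) -> List[CellTrack]:
    """Keep tracks spanning at least ``window_len`` consecutive frames.

    Surviving tracks are trimmed to their first ``window_len`` frames.
    """
    out: List[CellTrack] = []
    for track in tracks:
        idx = track.frame_indices
        if len(idx) < window_len:
            continue
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            continue
        out.append(CellTrack(track.cell_id, track.frames[:window_len]))
    return out


def track_purity(
    tracks: Sequence[CellTrack], truth_masks: Sequence[np.ndarray]
) -> float:
    """Mean fraction of track frames assigned to the majority true cell.

    ``truth_masks`` are ground-truth label maps indexed by frame, with the
    true cell identity encoded in the label value.
    """
    purities = []
    for track in tracks:
        ids = []
        for frame_index, _, centroid in track.frames:
            truth = truth_masks[frame_index]
            r = int(round(centroid[0]))
            c = int(round(centroid[1]))
            r = min(max(r, 0), truth.shape[0] - 1)
            c = min(max(c, 0), truth.shape[1] - 1)
            ids.append(int(truth[r, c]))
        ids_arr = np.array(ids)
        majority = np.bincount(ids_arr[ids_arr > 0]).argmax() if (ids_arr > 0).any() else 0
        purities.append(float(np.mean(ids_arr == majority)) if majority else 0.0)
    return float(np.mean(purities)) if purities else 0.0
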