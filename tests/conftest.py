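"""Shared fixtures: one seeded synthetic experiment reused across tests."""

import numpy as np
import pytest

from phasetrack.synth import preset_config, simulate_timelapse
from phasetrack.tracking import (
    filter_rois,
    link_tracks,
    segment_frame,
    select_complete_tracks,
)


@pytest.fixture(scope="session")
def paper_sim_40():
    """Paper-like run with 40 cells (20 per class), 30 frames, seed 3."""
    cfg = preset_config("paper-like", seed=3, n_cells_per_class=(20, 20))
    return simulate_timelapse(cfg)


@pytest.fixture(scope="session")
def segmented_40(paper_sim_40):
    """Watershed masks and complete tracks recovered from the 40-cell run."""
    masks = [
        filter_rois(segment_frame(frame, frame_index=i))
        for i, frame in enumerate(paper_sim_40.phase_frames)
    ]
    tracks = select_complete_tracks(link_tracks(masks), window_len=30)
    return masks, tracks


def jaccard_per_truth_cell(seg_labels, truth_labels):
    """Best-overlap Jaccard of each ground-truth region."""
    out = []
    for lab in np.unique(truth_labels)[1:]:
        truth = truth_labels == lab
        seg_labs, counts = np.unique(seg_labels[truth], return_counts=True)
        nonzero = seg_labs > 0
        if not nonzero.any():
            out.append(0.0)
            continue
        best = seg_labs[nonzero][np.argmax(counts[nonzero])]
        seg = seg_labels == best
        out.append((truth & seg).sum() / (truth | seg).sum())
    return np.array(out)
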