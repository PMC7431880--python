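"""End-to-end pipeline: simulate -> [holograms -> reconstruct] -> segment
-> track -> featurize -> select -> classify -> report.

Every stage's inputs and outputs are persisted in plain, ubiquitous
formats (float32 TIFF stacks for images, uint16 TIFF for masks, CSV for
tables, JSON for reports, YAML for configuration), and the benchmark
report embeds the configuration hash, the seed, and the package version
so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .classify import BenchmarkReport, CLASSIFIER_NAMES, run_benchmark
from .frame_features import (
    SERIES_FEATURE_NAMES,
    build_series,
    frame_feature_table,
)
from .recon import (
    PhaseImage,
    ReconstructionConfig,
    compensate_background,
    reconstruct_wrapped_phase,
    unwrap_phase,
)
from .selection import (
    DEFAULT_K_FEATURE_BASED,
    DEFAULT_K_VALUE_BASED,
    pvalue_cdf,
    ttest_rank,
)
from .synth import (
    SimulationResult,
    preset_config,
    simulate_timelapse,
    synthesize_hologram,
)
from .timelapse import (
    TransformConfig,
    assemble_feature_based,
    assemble_value_based,
    flatten_series,
)
from .tracking import (
    CellTrack,
    LabelMask,
    filter_rois,
    link_tracks,
    segment_frame,
    select_complete_tracks,
)

logger = logging.getLogger("phasetrack")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "save_report", "featurize"]


@dataclass
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through YAML."""

    preset: str = "paper-like"
    seed: int = 0
    n_cells_per_class: Tuple[int, int] = (95, 85)
    n_frames: int = 30
    window_len: int = 30
    mode: str = "nested"  # "nested" | "paper"
    use_ground_truth_masks: bool = False
    include_holograms: bool = False
    noise_sd_rad: float = 0.02
    pixel_size_um: float = 1.0
    segmentation_threshold: float = 0.1
    min_area_px: int = 20
    marker_h: float = 0.3
    solidity_threshold: float = 0.8
    max_disp_px: float = 20.0
    top_k_feature_based: int = DEFAULT_K_FEATURE_BASED
    top_k_value_based: int = DEFAULT_K_VALUE_BASED
    top_k_static: int = DEFAULT_K_FEATURE_BASED
    folds: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("nested", "paper"):
            raise ValueError("mode must be 'nested' or 'paper'")

    def to_yaml(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_cells_per_class" in raw:
            raw["n_cells_per_class"] = tuple(raw["n_cells_per_class"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    simulation: SimulationResult
    tracks: List[CellTrack]
    labels: np.ndarray  # class name per kept track, aligned with matrices
    matrices: Dict[str, np.ndarray]
    feature_names: Dict[str, Tuple[str, ...]]
    series_flat: np.ndarray
    benchmark: BenchmarkReport
    selection: dict


def save_phase_stack(frames: Sequence[PhaseImage], path: Path) -> None:
    stack = np.stack([f.values for f in frames]).astype(np.float32)
    meta = {"units": frames[0].units, "pixel_size_um": frames[0].pixel_size_um}
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def save_masks(masks: Sequence[np.ndarray], path: Path) -> None:
    tifffile.imwrite(path, np.stack(masks).astype(np.uint16))


def _assign_identity(
    track: CellTrack, truth_masks: Sequence[np.ndarray]
) -> Optional[int]:
    """Majority ground-truth cell id under the track centroids, or None."""
    votes: List[int] = []
    for frame_index, _, centroid in track.frames:
        truth = truth_masks[frame_index]
        r = min(max(int(round(centroid[0])), 0), truth.shape[0] - 1)
        c = min(max(int(round(centroid[1])), 0), truth.shape[1] - 1)
        v = int(truth[r, c])
        if v > 0:
            votes.append(v - 1)
    if not votes:
        return None
    return int(np.bincount(votes).argmax())


def featurize(
    phase_frames: Sequence[PhaseImage],
    masks: Sequence[np.ndarray],
    tracks: Sequence[CellTrack],
    frame_interval_min: float = 5.0,
    transform: Optional[TransformConfig] = None,
    static_frame: str | int = "middle",
) -> Tuple[pd.DataFrame, Dict[str, np.ndarray], Dict[str, Tuple[str, ...]], np.ndarray]:
    """Frame table plus the three representation matrices for a track set.

    Returns (frame_table, matrices, feature_names, series_flat) with
    matrices keyed ``static`` (single-frame features), ``value_based`` and
    ``feature_based`` (without the PCA block, which the benchmark fits
    per training fold).  ``static_frame`` picks the snapshot used for the
    static approach: a window row index, ``"middle"`` (an arbitrary-stage
    representative snapshot, the default) or ``"last"``.
    """
    transform = transform or TransformConfig()
    table = frame_feature_table(phase_frames, masks, tracks)
    px = phase_frames[0].pixel_size_um
    static_rows, value_rows, feature_rows, flat_rows = [], [], [], []
    names: Dict[str, Tuple[str, ...]] = {}
    for track in tracks:
        series = build_series(track, table, frame_interval_min)
        n_rows = series.values.shape[0]
        if static_frame == "middle":
            static_idx = n_rows // 2
        elif static_frame == "last":
            static_idx = n_rows - 1
        else:
            static_idx = int(static_frame)
        static_rows.append(series.values[static_idx])
        vb = assemble_value_based(series)
        fb = assemble_feature_based(series, transform, pixel_size_um=px)
        value_rows.append(vb.values)
        feature_rows.append(fb.values)
        flat_rows.append(flatten_series(series))
        names.setdefault("value_based", vb.names)
        names.setdefault("feature_based", fb.names)
    names["static"] = SERIES_FEATURE_NAMES
    matrices = {
        "static": np.array(static_rows),
        "value_based": np.array(value_rows),
        "feature_based": np.array(feature_rows),
    }
    return table, matrices, names, np.array(flat_rows)


def run_pipeline(cfg: RunConfig, outdir: Optional[Path] = None) -> PipelineResult:
    """Execute the full pipeline; artifacts are written when ``outdir`` is
    given."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = preset_config(
        cfg.preset,
        seed=cfg.seed,
        n_cells_per_class=cfg.n_cells_per_class,
        n_frames=cfg.n_frames,
        noise_sd_rad=cfg.noise_sd_rad,
        pixel_size_um=cfg.pixel_size_um,
    )
    logger.info("simulating preset %s (%s cells, %d frames)",
                cfg.preset, cfg.n_cells_per_class, cfg.n_frames)
    sim = simulate_timelapse(sim_cfg)

    phase_frames = sim.phase_frames
    if cfg.include_holograms:
        logger.info("synthesizing and reconstructing holograms")
        # diagonal carrier maximises sideband bandwidth; apodization tames
        # ringing around steep cell phase gradients
        recon_cfg = ReconstructionConfig(apodize=True)
        rng = np.random.default_rng(cfg.seed + 7919)
        reconstructed = []
        for frame in phase_frames:
            holo = synthesize_hologram(frame, carrier=(0.25, 0.25), rng=rng)
            wrapped = reconstruct_wrapped_phase(holo, recon_cfg)
            unwrapped = unwrap_phase(wrapped)
            reconstructed.append(
                compensate_background(unwrapped, recon_cfg.compensation_degree)
            )
        phase_frames = reconstructed

    if cfg.use_ground_truth_masks:
        masks = [m.astype(np.int32) for m in sim.label_masks]
        label_masks = [LabelMask(m, i) for i, m in enumerate(masks)]
    else:
        logger.info("segmenting %d frames", len(phase_frames))
        label_masks = [
            filter_rois(
                segment_frame(
                    frame,
                    threshold=cfg.segmentation_threshold,
                    min_area_px=cfg.min_area_px,
                    marker_h=cfg.marker_h,
                    frame_index=i,
                ),
                solidity_threshold=cfg.solidity_threshold,
            )
            for i, frame in enumerate(phase_frames)
        ]
    tracks = select_complete_tracks(
        link_tracks(label_masks, cfg.max_disp_px), cfg.window_len
    )
    logger.info("kept %d complete tracks", len(tracks))

    class_by_cell = dict(zip(sim.labels["cell_id"], sim.labels["class"]))
    kept_tracks, labels = [], []
    for track in tracks:
        identity = _assign_identity(track, sim.label_masks)
        if identity is None:
            continue
        kept_tracks.append(track)
        labels.append(class_by_cell[identity])
    labels = np.array(labels)

    mask_arrays = [np.asarray(m.labels) for m in label_masks]
    table, matrices, names, series_flat = featurize(
        phase_frames, mask_arrays, kept_tracks, sim_cfg.frame_interval_min
    )

    logger.info("benchmarking %d classifiers x 3 approaches (%s mode)",
                len(CLASSIFIER_NAMES), cfg.mode)
    benchmark = run_benchmark(
        matrices,
        labels,
        top_k={
            "static": cfg.top_k_static,
            "value_based": cfg.top_k_value_based,
            "feature_based": cfg.top_k_feature_based,
        },
        folds=cfg.folds,
        seed=cfg.seed,
        mode=cfg.mode,
        series_flat=series_flat,
    )

    # global selection diagnostics on the feature-based matrix
    from .timelapse import fit_apply_normalization

    scaled, _, _ = fit_apply_normalization(matrices["feature_based"])
    report = ttest_rank(scaled, labels, list(names["feature_based"]))
    cdf = pvalue_cdf(report.p_values)
    selection = {
        "ranking": report.feature_names[:50],
        "p_values": [float(p) for p in report.p_values[:50]],
        "ecdf_at_0_05": float(
            cdf.loc[np.isclose(cdf["p"], 0.05), "ecdf"].iloc[0]
        ),
    }

    result = PipelineResult(
        config=cfg,
        simulation=sim,
        tracks=kept_tracks,
        labels=labels,
        matrices=matrices,
        feature_names=names,
        series_flat=series_flat,
        benchmark=benchmark,
        selection=selection,
    )
    if outdir is not None:
        _write_artifacts(result, table, outdir)
    return result


def _write_artifacts(result: PipelineResult, table: pd.DataFrame, outdir: Path) -> None:
    cfg = result.config
    cfg.to_yaml(outdir / "config.yaml")
    save_phase_stack(result.simulation.phase_frames, outdir / "phase.tif")
    save_masks(result.simulation.label_masks, outdir / "truth_masks.tif")
    result.simulation.tracks.to_csv(outdir / "tracks.csv", index=False)
    result.simulation.labels.to_csv(outdir / "labels.csv", index=False)
    table.to_csv(outdir / "frame_features.csv", index=False)
    for approach, matrix in result.matrices.items():
        pd.DataFrame(matrix, columns=list(result.feature_names[approach])).assign(
            cell_id=[t.cell_id for t in result.tracks]
        ).to_csv(outdir / f"timelapse_features_{approach}.csv", index=False)
    (outdir / "selection_report.json").write_text(
        json.dumps(result.selection, indent=2, sort_keys=True)
    )
    save_report(result.benchmark, cfg, outdir / "benchmark_report.json")


def save_report(benchmark: BenchmarkReport, cfg: RunConfig, path: Path) -> None:
    """Serialise a benchmark report with provenance, deterministically."""
    payload = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "metrics": {
            f"{approach}|{classifier}": {
                m: repr(float(v)) for m, v in row.items()
            }
            for (approach, classifier), row in benchmark.metrics.iterrows()
        },
        "comparisons": [
            {k: (repr(float(v)) if isinstance(v, float) else v) for k, v in row.items()}
            for row in (
                benchmark.comparisons.to_dict("records")
                if benchmark.comparisons is not None
                else []
            )
        ],
        "summary": [
            {k: (repr(float(v)) if isinstance(v, float) else v) for k, v in row.items()}
            for row in benchmark.summary().to_dict("records")
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
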