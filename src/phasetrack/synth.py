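"""Ground-truthed synthetic time-lapse QPI generator for two phenotypes.

The generator emulates the observable contrast between two cell classes in
an epithelial-mesenchymal transition experiment: epithelial cells remain
rounded and compact with a centre-peaked dry-mass profile and low
motility, while mesenchymal cells elongate, grow their footprint area,
redistribute dry mass towards a uniform profile, and migrate farther.
Each cell is rendered as a smooth elliptical dome whose integrated
dry-mass density equals its prescribed total dry mass; the dome is
converted to phase radians through the inverse of the dry-mass relation
and observed with additive Gaussian phase noise.

Dynamics are per-frame interpolation between a per-cell start and end
morphology drawn from class distributions, with per-cell random onset and
completion times (rate jitter), so temporal features (trend, entropy,
spectra) carry class signal beyond any single frame.  Motion is a
persistent random walk with per-class step scale and persistence.

Presets
-------
``paper-like``
    Classes differ in both final morphology and dynamics (the default).
``temporal-only``
    Final-frame morphology marginals are identical across classes; only
    the trajectories differ.  The honest testbed for the claim that
    time-lapse features beat static ones.
``static-only``
    Classes differ in (constant) morphology but share identical dynamics
    and motility: a negative control where temporal features add nothing.
``null``
    All class-difference parameters equal; classifiers should sit at
    chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .recon import (
    DEFAULT_GAMMA_ML_PER_G,
    DEFAULT_WAVELENGTH_UM,
    Hologram,
    PhaseImage,
    RADIANS,
    dry_mass_to_phase,
)

__all__ = [
    "CellState",
    "CellClassParams",
    "SimulationConfig",
    "SimulationResult",
    "CrowdingError",
    "simulate_timelapse",
    "render_phase_frame",
    "synthesize_hologram",
    "preset_config",
    "PRESETS",
]

CENTER_PEAKED = "center_peaked"
UNIFORM = "uniform"


class CrowdingError(ValueError):
    """Requested cell count cannot be placed without overlap."""


@dataclass
class CellState:
    """Geometry and dry-mass content of one cell at one frame."""

    centroid_um: Tuple[float, float]
    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float
    total_dry_mass_pg: float
    #: 0 -> centre-peaked dome, 1 -> uniform plateau; intermediate values
    #: blend the two profiles.
    profile_flatness: float = 0.0

    def __post_init__(self) -> None:
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise ValueError("require major >= minor > 0")
        if self.total_dry_mass_pg <= 0:
            raise ValueError("total dry mass must be positive")
        if not (0.0 <= self.profile_flatness <= 1.0):
            raise ValueError("profile_flatness must be in [0, 1]")

    @property
    def mass_concentration_profile(self) -> str:
        return UNIFORM if self.profile_flatness >= 0.5 else CENTER_PEAKED

    @property
    def eccentricity(self) -> float:
        q = self.major_axis_um / self.minor_axis_um
        return float(np.sqrt(1.0 - 1.0 / q ** 2))


@dataclass
class CellClassParams:
    """Distributional parameters of one phenotype.

    ``*_start``/``*_end`` pairs are (mean, sd) of per-cell draws; each cell
    interpolates between its own start and end values with a random onset/
    completion schedule.  Units: areas in um^2, mass in pg, steps in um per
    frame interval.
    """

    area_start_um2: Tuple[float, float] = (150.0, 30.0)
    area_end_um2: Tuple[float, float] = (170.0, 45.0)
    aspect_start: Tuple[float, float] = (1.25, 0.15)
    aspect_end: Tuple[float, float] = (1.4, 0.35)
    flatness_start: Tuple[float, float] = (0.15, 0.08)
    flatness_end: Tuple[float, float] = (0.3, 0.18)
    mass_start_pg: Tuple[float, float] = (250.0, 40.0)
    mass_end_pg: Tuple[float, float] = (260.0, 50.0)
    step_um: float = 0.25
    persistence: float = 0.3
    #: frame-to-frame morphodynamic fluctuation (AR(1), relative sd for
    #: area/aspect/mass, absolute for flatness and orientation in rad)
    jitter_sd: float = 0.10
    jitter_corr: float = 0.2
    #: morphology-ramp schedule in units of the observation window: the
    #: per-cell transition starts at t_on ~ U(onset_range) and lasts
    #: U(duration_range); negative onsets mean the transition began before
    #: the window opened, onsets near 1 that it barely starts within it.
    onset_range: Tuple[float, float] = (0.0, 0.2)
    duration_range: Tuple[float, float] = (0.6, 0.9)


#: Paper-like mesenchymal phenotype: starts epithelial-like, elongates,
#: grows its footprint, flattens its mass profile, and migrates with high
#: persistence.  Observation windows catch cells at random transition
#: stages (onsets may precede the window; some cells are still mid-ramp at
#: its end), as happens when fixed-length windows are cut from a long
#: recording of an asynchronous population.
_MESENCHYMAL = CellClassParams(
    area_start_um2=(155.0, 30.0),
    area_end_um2=(240.0, 55.0),
    aspect_start=(1.3, 0.15),
    aspect_end=(2.7, 0.6),
    flatness_start=(0.2, 0.08),
    flatness_end=(0.75, 0.15),
    mass_start_pg=(255.0, 40.0),
    mass_end_pg=(290.0, 50.0),
    step_um=0.6,
    persistence=0.75,
    onset_range=(-0.5, 0.7),
    duration_range=(1.0, 1.5),
)

_EPITHELIAL = CellClassParams()

# temporal-only: identical end-state distributions, class B reaches it by a
# pronounced ramp while class A sits at the end state from frame 1.
_SHARED_END = dict(
    area_end_um2=(200.0, 45.0),
    aspect_end=(2.0, 0.45),
    flatness_end=(0.5, 0.15),
    mass_end_pg=(270.0, 45.0),
)
_TEMPORAL_A = CellClassParams(
    area_start_um2=_SHARED_END["area_end_um2"],
    aspect_start=_SHARED_END["aspect_end"],
    flatness_start=_SHARED_END["flatness_end"],
    mass_start_pg=_SHARED_END["mass_end_pg"],
    step_um=0.25,
    persistence=0.3,
    **_SHARED_END,
)
_TEMPORAL_B = CellClassParams(
    area_start_um2=(140.0, 30.0),
    aspect_start=(1.1, 0.08),
    flatness_start=(0.1, 0.05),
    mass_start_pg=(235.0, 35.0),
    step_um=0.6,
    persistence=0.75,
    # every transition completes inside the window so the final-frame
    # morphology marginals match class A exactly
    onset_range=(0.0, 0.1),
    duration_range=(0.5, 0.7),
    **_SHARED_END,
)

# static-only: distinct constant morphologies, identical motility/dynamics.
_STATIC_A = CellClassParams(
    area_start_um2=(160.0, 35.0),
    area_end_um2=(160.0, 35.0),
    aspect_start=(1.3, 0.2),
    aspect_end=(1.3, 0.2),
    flatness_start=(0.25, 0.1),
    flatness_end=(0.25, 0.1),
    mass_start_pg=(250.0, 40.0),
    mass_end_pg=(250.0, 40.0),
    step_um=0.4,
    persistence=0.5,
)
_STATIC_B = CellClassParams(
    area_start_um2=(230.0, 50.0),
    area_end_um2=(230.0, 50.0),
    aspect_start=(2.4, 0.6),
    aspect_end=(2.4, 0.6),
    flatness_start=(0.65, 0.15),
    flatness_end=(0.65, 0.15),
    mass_start_pg=(280.0, 50.0),
    mass_end_pg=(280.0, 50.0),
    step_um=0.4,
    persistence=0.5,
)

PRESETS: Dict[str, Tuple[CellClassParams, CellClassParams]] = {
    "paper-like": (_EPITHELIAL, _MESENCHYMAL),
    "temporal-only": (_TEMPORAL_A, _TEMPORAL_B),
    "static-only": (_STATIC_A, _STATIC_B),
    "null": (_EPITHELIAL, _EPITHELIAL),
}

CLASS_NAMES = ("epithelial", "mesenchymal")


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic experiment.

    Defaults follow the acquisition the generator emulates: 30 frames at
    5-minute intervals, 95 epithelial and 85 mesenchymal cells.
    """

    n_frames: int = 30
    frame_interval_min: float = 5.0
    n_cells_per_class: Tuple[int, int] = (95, 85)
    pixel_size_um: float = 1.0
    image_size_px: Optional[Tuple[int, int]] = None
    class_params: Tuple[CellClassParams, CellClassParams] = (
        _EPITHELIAL,
        _MESENCHYMAL,
    )
    noise_sd_rad: float = 0.02
    wavelength_um: float = DEFAULT_WAVELENGTH_UM
    gamma_ml_per_g: float = DEFAULT_GAMMA_ML_PER_G
    #: noiseless phase level (rad) defining the ground-truth footprint mask
    mask_threshold_rad: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval_min <= 0 or self.pixel_size_um <= 0:
            raise ValueError("intervals and pixel size must be positive")
        if min(self.n_cells_per_class) < 0 or sum(self.n_cells_per_class) == 0:
            raise ValueError("invalid cell counts")


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a named phenotype preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SimulationConfig(class_params=PRESETS[name], **overrides)


@dataclass
class SimulationResult:
    """Everything downstream stages need, with full ground truth."""

    config: SimulationConfig
    phase_frames: List[PhaseImage]
    label_masks: List[np.ndarray]  # uint16, label = cell_id + 1
    tracks: pd.DataFrame  # cell_id, frame, x_px (col), y_px (row)
    labels: pd.DataFrame  # cell_id, class
    states: List[List[CellState]]  # [frame][cell]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _profile(u2: np.ndarray, flatness: float) -> np.ndarray:
    """Radial dry-mass profile on the unit ellipse (u2 = squared radius)."""
    inside = u2 < 1.0
    dome = np.where(inside, (1.0 - u2) ** 2, 0.0)
    # plateau with a smooth cosine rolloff from u = 0.75 to 1
    u = np.sqrt(np.clip(u2, 0.0, None))
    roll = np.where(
        u <= 0.75, 1.0, np.where(inside, 0.5 + 0.5 * np.cos(np.pi * (u - 0.75) / 0.25), 0.0)
    )
    return (1.0 - flatness) * dome + flatness * roll


def _render_cell_patch(
    state: CellState, cfg: SimulationConfig
) -> Tuple[slice, slice, np.ndarray]:
    """Density patch (pg/um^2) of one cell and the slices placing it."""
    px = cfg.pixel_size_um
    a = state.major_axis_um / 2.0 / px  # semi-axes in px
    b = state.minor_axis_um / 2.0 / px
    cr = state.centroid_um[0] / px
    cc = state.centroid_um[1] / px
    half = int(np.ceil(max(a, b))) + 2
    r0, c0 = int(np.floor(cr)) - half, int(np.floor(cc)) - half
    n = 2 * half + 1
    rows = (np.arange(r0, r0 + n)[:, None] - cr) * px
    cols = (np.arange(c0, c0 + n)[None, :] - cc) * px
    ct, st = np.cos(state.orientation_rad), np.sin(state.orientation_rad)
    xp = rows * ct + cols * st  # along major axis (um)
    yp = -rows * st + cols * ct
    u2 = (xp / (state.major_axis_um / 2.0)) ** 2 + (yp / (state.minor_axis_um / 2.0)) ** 2
    prof = _profile(u2, state.profile_flatness)
    total = prof.sum() * px * px
    if total <= 0:
        raise ValueError("degenerate cell profile")
    density = prof * (state.total_dry_mass_pg / total)
    return slice(r0, r0 + n), slice(c0, c0 + n), density


def render_phase_frame(
    states: Sequence[CellState],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> PhaseImage:
    """Render one noisy phase frame (radians) from cell states.

    Each cell is an elliptical dome/plateau whose integrated dry-mass
    density equals its ``total_dry_mass_pg`` (exact on the render grid);
    densities convert to phase through the inverse dry-mass relation, and
    Gaussian phase noise of sd ``cfg.noise_sd_rad`` is added when an RNG is
    supplied.
    """
    shape = _image_shape(cfg, states)
    density = np.zeros(shape, dtype=float)
    for state in states:
        rs, cs, patch = _render_cell_patch(state, cfg)
        if rs.start < 0 or cs.start < 0 or rs.stop > shape[0] or cs.stop > shape[1]:
            raise ValueError("cell out of image bounds")
        density[rs, cs] += patch
    phase = dry_mass_to_phase(density, cfg.wavelength_um, cfg.gamma_ml_per_g)
    if rng is not None and cfg.noise_sd_rad > 0:
        phase = phase + rng.normal(0.0, cfg.noise_sd_rad, size=shape)
    return PhaseImage(
        phase.astype(float),
        units=RADIANS,
        wavelength_um=cfg.wavelength_um,
        pixel_size_um=cfg.pixel_size_um,
    )


def _ground_truth_mask(
    states: Sequence[CellState], cfg: SimulationConfig, shape: Tuple[int, int]
) -> np.ndarray:
    """Label mask: pixels whose noiseless phase exceeds the mask threshold."""
    mask = np.zeros(shape, dtype=np.uint16)
    thr_density = (
        cfg.mask_threshold_rad * cfg.wavelength_um / (2.0 * np.pi * cfg.gamma_ml_per_g)
    )
    for i, state in enumerate(states):
        rs, cs, patch = _render_cell_patch(state, cfg)
        sub = mask[rs, cs]
        sub[patch > thr_density] = i + 1
    return mask


def _max_extent_px(params: CellClassParams, cfg: SimulationConfig) -> float:
    """Conservative major-axis diameter bound (px) for grid spacing."""
    area = max(params.area_start_um2[0] + 3 * params.area_start_um2[1],
               params.area_end_um2[0] + 3 * params.area_end_um2[1])
    aspect = max(params.aspect_start[0] + 3 * params.aspect_start[1],
                 params.aspect_end[0] + 3 * params.aspect_end[1])
    # area = pi * a * b, a = aspect * b -> major diameter 2a; inflate for
    # the multiplicative AR(1) morphodynamic jitter
    b = np.sqrt(area / (np.pi * aspect))
    return 2.0 * aspect * b * np.exp(3.0 * params.jitter_sd) / cfg.pixel_size_um


def _grid_layout(cfg: SimulationConfig) -> Tuple[float, Tuple[int, int], int, int]:
    n_total = sum(cfg.n_cells_per_class)
    extent = max(_max_extent_px(p, cfg) for p in cfg.class_params)
    travel = max(
        p.step_um * cfg.n_frames * max(p.persistence, 0.35) for p in cfg.class_params
    ) / cfg.pixel_size_um
    spacing = extent + 2.0 * travel + 6.0
    n_cols = int(np.ceil(np.sqrt(n_total)))
    n_rows = int(np.ceil(n_total / n_cols))
    margin = int(np.ceil(spacing / 2.0)) + 2
    if cfg.image_size_px is None:
        shape = (
            int(np.ceil(n_rows * spacing)) + 2 * margin,
            int(np.ceil(n_cols * spacing)) + 2 * margin,
        )
    else:
        shape = cfg.image_size_px
        if n_rows * spacing + 2 * margin > shape[0] or n_cols * spacing + 2 * margin > shape[1]:
            raise CrowdingError(
                f"{n_total} cells do not fit in {shape} without overlap"
            )
    return spacing, shape, n_rows, n_cols


def _image_shape(cfg: SimulationConfig, states: Sequence[CellState]) -> Tuple[int, int]:
    if cfg.image_size_px is not None:
        return cfg.image_size_px
    if not states:
        return (64, 64)
    _, shape, _, _ = _grid_layout(cfg)
    return shape


def _draw(rng: np.random.Generator, mean_sd: Tuple[float, float], lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(*mean_sd), lo, hi))


def _cell_trajectory(
    rng: np.random.Generator,
    params: CellClassParams,
    cfg: SimulationConfig,
    origin_px: Tuple[float, float],
    spacing: float,
) -> List[CellState]:
    """States of one cell across all frames (morphology ramp + walk)."""
    area0 = _draw(rng, params.area_start_um2, 40.0, 1e4)
    area1 = _draw(rng, params.area_end_um2, 40.0, 1e4)
    asp0 = _draw(rng, params.aspect_start, 1.0, 8.0)
    asp1 = _draw(rng, params.aspect_end, 1.0, 8.0)
    flat0 = _draw(rng, params.flatness_start, 0.0, 1.0)
    flat1 = _draw(rng, params.flatness_end, 0.0, 1.0)
    mass0 = _draw(rng, params.mass_start_pg, 50.0, 2e3)
    mass1 = _draw(rng, params.mass_end_pg, 50.0, 2e3)
    theta = rng.uniform(0.0, np.pi)
    t_on = rng.uniform(*params.onset_range)
    t_off = t_on + rng.uniform(*params.duration_range)

    def ar1(sd: float) -> np.ndarray:
        # stationary AR(1) fluctuations around 0 with marginal sd `sd`
        rho = params.jitter_corr
        eps = rng.normal(0.0, sd * np.sqrt(1 - rho ** 2), size=cfg.n_frames)
        out = np.empty(cfg.n_frames)
        out[0] = rng.normal(0.0, sd)
        for i in range(1, cfg.n_frames):
            out[i] = rho * out[i - 1] + eps[i]
        return out

    jit_area = ar1(params.jitter_sd)
    jit_aspect = ar1(params.jitter_sd)
    jit_flat = ar1(params.jitter_sd)
    jit_mass = ar1(0.25 * params.jitter_sd)  # mass nearly conserved
    jit_theta = ar1(params.jitter_sd)
    # persistent random walk, confined to the cell's grid territory
    px = cfg.pixel_size_um
    max_r = max(spacing / 2.0 * px - np.sqrt(max(area0, area1) / np.pi) * max(asp0, asp1) ** 0.5 - 2 * px, 2 * px)
    heading = rng.uniform(0.0, 2 * np.pi)
    pos = np.array([origin_px[0] * px, origin_px[1] * px])
    origin_um = pos.copy()
    states: List[CellState] = []
    for t in range(cfg.n_frames):
        frac = _smoothstep(
            np.array((t / max(cfg.n_frames - 1, 1) - t_on) / max(t_off - t_on, 1e-6))
        ).item()
        area = (area0 + (area1 - area0) * frac) * np.exp(jit_area[t])
        aspect = max((asp0 + (asp1 - asp0) * frac) * np.exp(jit_aspect[t]), 1.0)
        flat = float(np.clip(flat0 + (flat1 - flat0) * frac + jit_flat[t], 0.0, 1.0))
        mass = (mass0 + (mass1 - mass0) * frac) * np.exp(jit_mass[t])
        b = np.sqrt(area / (np.pi * aspect))
        states.append(
            CellState(
                centroid_um=(float(pos[0]), float(pos[1])),
                major_axis_um=2.0 * aspect * b,
                minor_axis_um=2.0 * b,
                orientation_rad=theta + jit_theta[t],
                total_dry_mass_pg=mass,
                profile_flatness=flat,
            )
        )
        heading = params.persistence * heading + rng.normal(
            0.0, (1.0 - params.persistence) * np.pi
        )
        step = rng.rayleigh(params.step_um * np.sqrt(2.0 / np.pi))
        proposal = pos + step * np.array([np.sin(heading), np.cos(heading)])
        disp = proposal - origin_um
        r = np.linalg.norm(disp)
        if r > max_r:  # reflect back into the territory
            proposal = origin_um + disp * (max_r / r) * 0.95
            heading = heading + np.pi
        pos = proposal
    return states


def simulate_timelapse(cfg: SimulationConfig) -> SimulationResult:
    """Simulate a full two-class time-lapse experiment with ground truth.

    Returns noisy phase frames, per-frame ground-truth label masks
    (non-overlapping by construction), a track table and class labels.
    Fully deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    spacing, shape, n_rows, n_cols = _grid_layout(cfg)
    n_total = sum(cfg.n_cells_per_class)
    margin = spacing / 2.0 + 2
    # jittered grid sites, shuffled so classes interleave spatially
    sites = [
        (
            margin + (i + 0.5) * spacing + rng.uniform(-2, 2),
            margin + (j + 0.5) * spacing + rng.uniform(-2, 2),
        )
        for i in range(n_rows)
        for j in range(n_cols)
    ]
    order = rng.permutation(len(sites))[:n_total]
    class_of = np.repeat([0, 1], cfg.n_cells_per_class)
    cells = [
        _cell_trajectory(rng, cfg.class_params[class_of[k]], cfg, sites[order[k]], spacing)
        for k in range(n_total)
    ]
    run_cfg = replace(cfg, image_size_px=shape)
    phase_frames: List[PhaseImage] = []
    label_masks: List[np.ndarray] = []
    states_by_frame: List[List[CellState]] = []
    rows = []
    for t in range(cfg.n_frames):
        frame_states = [cells[k][t] for k in range(n_total)]
        states_by_frame.append(frame_states)
        phase_frames.append(render_phase_frame(frame_states, run_cfg, rng))
        label_masks.append(_ground_truth_mask(frame_states, run_cfg, shape))
        for k, s in enumerate(frame_states):
            rows.append(
                {
                    "cell_id": k,
                    "frame": t,
                    "x_px": s.centroid_um[1] / cfg.pixel_size_um,
                    "y_px": s.centroid_um[0] / cfg.pixel_size_um,
                }
            )
    tracks = pd.DataFrame(rows)
    labels = pd.DataFrame(
        {
            "cell_id": np.arange(n_total),
            "class": [CLASS_NAMES[c] for c in class_of],
        }
    )
    return SimulationResult(
        config=run_cfg,
        phase_frames=phase_frames,
        label_masks=label_masks,
        tracks=tracks,
        labels=labels,
        states=states_by_frame,
    )


def synthesize_hologram(
    phase: PhaseImage,
    carrier: Tuple[float, float] = (0.25, 0.0),
    object_amplitude: float = 1.0,
    reference_amplitude: float = 1.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Hologram:
    """Forward off-axis fringe model.

    I = A_o^2 + A_r^2 + 2 A_o A_r cos(2 pi f . x + phi), with optional
    additive Gaussian intensity noise (clipped at zero to stay physical).
    """
    mag = float(np.hypot(*carrier))
    if not (0.0 < mag < 0.5):
        raise ValueError("carrier magnitude must be in (0, 0.5) cycles/px")
    shape = phase.values.shape
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    fringe = 2.0 * np.pi * (carrier[0] * rows + carrier[1] * cols) + phase.values
    intensity = (
        object_amplitude ** 2
        + reference_amplitude ** 2
        + 2.0 * object_amplitude * reference_amplitude * np.cos(fringe)
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        intensity = intensity + rng.normal(0.0, noise_sd, size=shape)
    intensity = np.clip(intensity, 0.0, None)
    return Hologram(
        intensity,
        carrier_frequency=carrier if mag > 0 else None,
        pixel_size_um=phase.pixel_size_um,
    )
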