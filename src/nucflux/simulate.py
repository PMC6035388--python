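"""Forward simulators for every input the analysis pipeline consumes.

All simulators take explicit ground-truth parameters and a seed and are
bit-reproducible.  Noise is additive Gaussian on normalized intensity
(default sd 0.02); acquisition decay is multiplicative.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import flip as _flip
from .datatypes import CellGeometry, FlipMovie, RecoveryCurve
from .frap import RadialReactionDiffusion, diffusion_curve, reaction_curve
from .geometry import GeometrySpec, make_geometry  # noqa: F401 (re-export)
from .postbleach import bleach_profile
from .rates import RateSet

DEFAULT_NOISE_SD = 0.02


@dataclass
class FrapProtocol:
    """Acquisition settings: 3 prebleach frames, a 2.9 s bleach, then a
    frame every 60 ms for up to 18 s (48 s / 100 s for slow conditions)."""
    frame_interval: float = 0.06
    duration: float = 18.0
    n_prebleach: int = 3
    bleach_duration: float = 2.9


@dataclass
class FlipProtocol:
    """150 frames every 2 s with the ROI bleached 2 s between frames."""
    frame_interval: float = 2.0
    n_frames: int = 150
    n_prebleach: int = 3
    bleach_duration: float = 2.0
    # "interleaved" applies the sink for bleach_duration out of each
    # interval; "continuous" keeps it on throughout
    bleach_mode: str = "interleaved"


@dataclass
class GroundTruth:
    """Unified simulation parameters across FRAP and FLIP models."""
    model_id: str = "single_reaction"
    rates: RateSet = field(default_factory=lambda: RateSet(
        k1=0.25, k_off=0.39, k2=0.018, k_im=0.017, eta=1.5))
    amplitudes: tuple = (0.8,)       # reaction-model amplitudes
    reaction_rates: tuple = (0.39,)  # reaction-model recovery rates, 1/s
    t0: float = 0.0
    K: float = 1.0                   # bleach depth
    r_e: float = 1.5                 # effective radius, um
    r_n: float = 1.232               # nominal bleach radius, um
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0


def simulate_postbleach_profile(K, r_e, geometry: CellGeometry,
                                noise_sd=DEFAULT_NOISE_SD, seed=0,
                                bleach_center=None) -> np.ndarray:
    """First postbleach frame: exponential-of-Gaussian dip about the
    bleach center inside the nucleus, unbleached (1) elsewhere."""
    if K <= 0 or r_e <= 0:
        raise ValueError("K and r_e must be positive")
    rng = np.random.default_rng(seed)
    h, w = geometry.frame_shape
    if bleach_center is None:
        bleach_center = geometry.bleach_center()
    rr, cc = np.mgrid[0:h, 0:w]
    r_um = np.hypot(rr - bleach_center[0], cc - bleach_center[1]) \
        * geometry.pixel_size
    frame = np.ones((h, w))
    nuc = geometry.analysis_nucleus_mask
    frame[nuc] = bleach_profile(r_um[nuc], K, r_e)
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, frame.shape)
    return frame


def _protocol_times(protocol: FrapProtocol):
    n_post = int(round(protocol.duration / protocol.frame_interval)) + 1
    post = np.arange(n_post) * protocol.frame_interval
    pre = -protocol.bleach_duration \
        - protocol.frame_interval * np.arange(protocol.n_prebleach, 0, -1)
    times = np.concatenate([pre, post])
    is_pre = np.zeros(len(times), dtype=bool)
    is_pre[:protocol.n_prebleach] = True
    return times, is_pre


def simulate_frap_curve(truth: GroundTruth,
                        protocol: FrapProtocol | None = None
                        ) -> RecoveryCurve:
    """Noisy recovery curve under the chosen generating model.

    ``diffusion`` and the reaction models use their closed forms; the
    reaction-diffusion model runs the radial PDE oracle.  Prebleach
    points are 1 + noise.
    """
    protocol = protocol or FrapProtocol()
    times, is_pre = _protocol_times(protocol)
    t_post = times[~is_pre]
    if truth.model_id == "diffusion":
        Q = diffusion_curve(t_post, truth.rates.D, truth.K, truth.r_e,
                            truth.r_n)
    elif truth.model_id in ("single_reaction", "double_reaction"):
        Q = reaction_curve(t_post, truth.amplitudes, truth.reaction_rates,
                           truth.t0)
    elif truth.model_id == "reaction_diffusion":
        oracle = RadialReactionDiffusion(truth.K, truth.r_e, truth.r_n)
        Q = oracle.curve(t_post, truth.rates.k1, truth.rates.k_off,
                         truth.rates.D)
    else:
        raise ValueError(f"unknown model_id {truth.model_id!r}")
    intensity = np.empty(len(times))
    intensity[is_pre] = 1.0
    intensity[~is_pre] = Q
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        intensity = intensity + rng.normal(0, truth.noise_sd, len(times))
    return RecoveryCurve(times=times, intensity=intensity,
                         is_prebleach=is_pre,
                         bleach_duration=protocol.bleach_duration,
                         r_n=truth.r_n)


def simulate_flip_movie(truth: GroundTruth, geometry: CellGeometry,
                        protocol: FlipProtocol | None = None,
                        sim_cell_px: int | None = None) -> FlipMovie:
    """FLIP movie from the compartmental reaction-diffusion model.

    The PDE is solved on a lattice finer than the fitting grid (default
    a quarter of the bleach-ROI side) and painted back onto the pixel
    raster by area-weighted assignment, then Gaussian noise is added.
    The initial state is the compartmental steady state.
    """
    protocol = protocol or FlipProtocol()
    if geometry.bleach_roi is None or not geometry.bleach_roi.any():
        raise ValueError("geometry lacks a bleach ROI")
    rr, cc = np.nonzero(geometry.bleach_roi)
    roi_px = rr.max() - rr.min() + 1
    if sim_cell_px is None:
        sim_cell_px = max(roi_px // 4, 1)
    grid = _flip.discretize(geometry, cell_px=sim_cell_px)

    n = protocol.n_frames
    times = np.arange(n) * protocol.frame_interval
    if protocol.bleach_mode == "continuous":
        sched = np.full(n, protocol.frame_interval)
    else:
        sched = np.full(n, min(protocol.bleach_duration,
                               protocol.frame_interval))
    G = _flip.solve_forward(truth.rates, grid, times, sched)

    frames = _paint(grid, geometry, G)
    pre = np.repeat(frames[:1], protocol.n_prebleach, axis=0)
    frames = np.concatenate([pre, frames], axis=0)
    full_sched = np.concatenate([np.zeros(protocol.n_prebleach), sched])
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        frames = frames + rng.normal(0, truth.noise_sd, frames.shape)
    return FlipMovie(frames=frames,
                     frame_interval=protocol.frame_interval,
                     bleach_schedule=full_sched)


def _paint(grid, geometry: CellGeometry, G: np.ndarray) -> np.ndarray:
    """Paint lattice values back onto the pixel raster (in-mask pixels)."""
    h, w = geometry.frame_shape
    frames = np.zeros((G.shape[0], h, w))
    masks = {True: geometry.analysis_nucleus_mask,
             False: geometry.cytoplasm_mask}
    cells = np.vstack([grid.nuc_cells, grid.cyt_cells])
    for k, ij in enumerate(cells):
        box = grid.pixel_box(ij)
        m = (masks[k < grid.n_nuc][box]
             | masks[not (k < grid.n_nuc)][box])
        sub = frames[:, box[0], box[1]]
        sub[:, m] = G[:, k][:, None]
        frames[:, box[0], box[1]] = sub
    return frames


# ------------------------------------------------------------- tracking

@dataclass
class TrackingSpec:
    n_cells: int = 3
    n_frames: int = 30
    frame_shape: tuple[int, int] = (128, 128)
    cell_radius: float = 9.0        # cytoplasm disc radius, px
    nucleus_radius: float = 4.0
    step_sd: float = 1.0            # random-walk step, px/frame
    # (cell index, frame) events
    divisions: tuple = ()           # cell divides at frame
    exits: tuple = ()               # cell walks off the border at frame


def simulate_tracking_movie(spec: TrackingSpec, seed: int = 0,
                            centers0=None, velocities=None):
    """Label-mask movie of motile cells with known ground-truth tracks.

    Returns (nuclei_masks, cytoplasm_masks, truth) where the masks are
    boolean (T, H, W) foreground stacks and ``truth`` is a list of dicts
    per frame mapping cell id -> (row, col) center, including touching
    events, divisions and border exits.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.frame_shape
    if centers0 is None:
        margin = spec.cell_radius + 12
        centers0 = [(rng.uniform(margin, h - margin),
                     rng.uniform(margin, w - margin))
                    for _ in range(spec.n_cells)]
    cells = {i: {"center": np.array(c, dtype=float),
                 "vel": (np.array(velocities[i]) if velocities
                         else np.zeros(2))}
             for i, c in enumerate(centers0)}
    next_id = spec.n_cells
    divisions = dict(spec.divisions)
    exits = dict(spec.exits)

    nuc = np.zeros((spec.n_frames, h, w), dtype=bool)
    cyt = np.zeros((spec.n_frames, h, w), dtype=bool)
    truth = []
    yy, xx = np.mgrid[0:h, 0:w]
    for f in range(spec.n_frames):
        # events
        for cid in [c for c, fr in exits.items() if fr == f]:
            cells.pop(cid, None)
        for cid in [c for c, fr in divisions.items() if fr == f]:
            if cid in cells:
                parent = cells.pop(cid)
                for off in (-1.2 * spec.nucleus_radius,
                            1.2 * spec.nucleus_radius):
                    cells[next_id] = {
                        "center": parent["center"] + np.array([0.0, off]),
                        "vel": parent["vel"].copy()}
                    next_id += 1
        frame_truth = {}
        for cid, st in cells.items():
            c = st["center"]
            d2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
            cyt[f] |= d2 <= spec.cell_radius ** 2
            nuc[f] |= d2 <= spec.nucleus_radius ** 2
            frame_truth[cid] = (float(c[0]), float(c[1]))
        truth.append(frame_truth)
        for st in cells.values():
            st["center"] = st["center"] + st["vel"] \
                + rng.normal(0, spec.step_sd, 2)
    return nuc, cyt, truth
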