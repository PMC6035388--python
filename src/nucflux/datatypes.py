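"""Core data containers shared across the FRAP and FLIP pipelines.

Conventions: rasters are 0-based row-major numpy arrays with pixel centers at
integer coordinates; times are seconds; intensities are arbitrary detector
units before normalization and dimensionless afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Back-calculated defaults: the acquisition reports ROI areas, not pixel
# sizes.  An 8x8 px FLIP square at 0.264 um/px covers 4.46 um^2; an 11 px
# diameter FRAP circle at 0.181 um/px covers ~3.1 um^2.
FLIP_PIXEL_SIZE = 0.264
FRAP_PIXEL_SIZE = 0.181


@dataclass
class CellGeometry:
    """Pixel-resolved compartment masks for a single cell.

    Parameters
    ----------
    pixel_size : float
        Physical size of one pixel in um.
    nucleus_mask : ndarray of bool
        Nucleus including nucleoli.
    nucleoli_mask : ndarray of bool
        Subset of the nucleus excluded from analysis (dense chromatin
        packing excludes the reporter and distorts diffusion).
    cytoplasm_mask : ndarray of bool
        Analysed cytoplasm; disjoint from the nucleus.  Thin regions
        (e.g. lamellipodia) are expected to be pre-excluded.
    bleach_roi : ndarray of bool or None
        Bleached region: a circle of nominal radius r_n for FRAP, a square
        for FLIP.  Must lie entirely inside one compartment.
    """

    pixel_size: float
    nucleus_mask: np.ndarray
    nucleoli_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    bleach_roi: np.ndarray | None = None

    def __post_init__(self):
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        self.nucleoli_mask = np.asarray(self.nucleoli_mask, dtype=bool)
        self.cytoplasm_mask = np.asarray(self.cytoplasm_mask, dtype=bool)
        if self.bleach_roi is not None:
            self.bleach_roi = np.asarray(self.bleach_roi, dtype=bool)
        self.validate()

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.nucleus_mask.shape

    @property
    def analysis_nucleus_mask(self) -> np.ndarray:
        """Nucleus minus nucleoli: the region used in every computation."""
        return self.nucleus_mask & ~self.nucleoli_mask

    def validate(self) -> None:
        if not (self.nucleus_mask.shape == self.nucleoli_mask.shape
                == self.cytoplasm_mask.shape):
            raise ValueError("compartment masks must share a frame shape")
        if np.any(self.nucleoli_mask & ~self.nucleus_mask):
            raise ValueError("nucleoli_mask must be a subset of nucleus_mask")
        if np.any(self.nucleus_mask & self.cytoplasm_mask):
            raise ValueError("nucleus and cytoplasm masks overlap")
        if self.bleach_roi is not None and self.bleach_roi.any():
            in_nuc = np.all(self.analysis_nucleus_mask[self.bleach_roi])
            in_cyt = np.all(self.cytoplasm_mask[self.bleach_roi])
            if not (in_nuc or in_cyt):
                raise ValueError(
                    "bleach ROI must lie entirely inside one compartment")

    @property
    def bleach_compartment(self) -> str:
        if self.bleach_roi is None or not self.bleach_roi.any():
            raise ValueError("geometry has no bleach ROI")
        if np.all(self.analysis_nucleus_mask[self.bleach_roi]):
            return "nucleus"
        return "cytoplasm"

    def bleach_center(self) -> tuple[float, float]:
        """(row, col) centroid of the bleach ROI, pixels."""
        rr, cc = np.nonzero(self.bleach_roi)
        return float(rr.mean()), float(cc.mean())


@dataclass
class RecoveryCurve:
    """A normalized FRAP recovery time series.

    ``times`` is a uniform grid in seconds with prebleach frames flagged in
    ``is_prebleach``; t = 0 at the first postbleach frame.  ``intensity`` is
    the background-subtracted, acquisition-decay-corrected, prebleach-
    normalized signal so that the prebleach mean f_i is ~1.
    """

    times: np.ndarray
    intensity: np.ndarray
    is_prebleach: np.ndarray
    bleach_duration: float = 2.9
    roi_area: float | None = None
    r_n: float | None = None  # nominal bleach radius, um

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.is_prebleach = np.asarray(self.is_prebleach, dtype=bool)
        if not (len(self.times) == len(self.intensity)
                == len(self.is_prebleach)):
            raise ValueError("times/intensity/is_prebleach length mismatch")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    @property
    def f_i(self) -> float:
        """Mean prebleach intensity (close to 1 after normalization)."""
        return float(self.intensity[self.is_prebleach].mean())

    @property
    def post_times(self) -> np.ndarray:
        return self.times[~self.is_prebleach]

    @property
    def post_intensity(self) -> np.ndarray:
        return self.intensity[~self.is_prebleach]

    @property
    def S0(self) -> float:
        """First postbleach intensity S(0)."""
        return float(self.post_intensity[0])

    def f_oo(self, tail_fraction: float = 0.1) -> float:
        """Mean intensity over the final ``tail_fraction`` of the recovery."""
        post = self.post_intensity
        n = max(1, int(round(tail_fraction * len(post))))
        return float(post[-n:].mean())

    def mobile_fraction(self) -> float:
        """R = (f_oo - f0) / (f_i - f0)."""
        f0 = self.S0
        return (self.f_oo() - f0) / (self.f_i - f0)


@dataclass
class FlipMovie:
    """An intensity movie from a fluorescence-loss-in-photobleaching run.

    ``frames`` has shape (T, H, W).  ``bleach_schedule`` gives the bleach
    duration (s) applied *after* each frame; prebleach frames carry 0.
    """

    frames: np.ndarray
    frame_interval: float = 2.0
    bleach_schedule: np.ndarray | None = None
    bit_depth: int = 12
    control_normalization: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T>=2, H, W)")
        if self.bleach_schedule is None:
            self.bleach_schedule = np.full(self.n_frames, self.frame_interval)
        self.bleach_schedule = np.asarray(self.bleach_schedule, dtype=float)
        if len(self.bleach_schedule) != self.n_frames:
            raise ValueError("bleach_schedule length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def is_prebleach(self) -> np.ndarray:
        return self.bleach_schedule == 0.0


@dataclass
class FitResult:
    """Serializable record of one model fit."""

    model_id: str
    parameters: dict
    units: dict = field(default_factory=dict)
    weighted_sse: float = np.nan
    aic: float = np.nan
    akaike_weight: float = np.nan
    plausible: bool = True
    discard_reason: str | None = None
    noisy: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "units": dict(self.units),
            "weighted_sse": float(self.weighted_sse),
            "aic": float(self.aic),
            "akaike_weight": float(self.akaike_weight),
            "plausible": bool(self.plausible),
            "discard_reason": self.discard_reason,
            "noisy": bool(self.noisy),
            "extra": self.extra,
        }
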