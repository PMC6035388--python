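"""Intensity-normalization conventions for FRAP, FLIP and N/C-ratio data.

FRAP: background-subtract every ROI trace, divide by the whole-field decay
(continual acquisition bleaches the entire field), then divide by the mean
of the >=3 prebleach frames so the prebleach level is ~1.

FLIP: background-subtract, then divide each frame by the mean of two
control ROIs measured in an unbleached cell at that frame.

N/C ratio: (nuclear - background) / (cytoplasmic - background) from two
equal ROIs placed equidistant from the nuclear boundary, avoiding nucleoli.
"""
from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CellGeometry, FlipMovie, RecoveryCurve


def normalize_frap_curve(times, raw_roi, background_roi, whole_field,
                         is_prebleach, bleach_duration: float = 2.9,
                         roi_area: float | None = None,
                         r_n: float | None = None) -> RecoveryCurve:
    """Normalize a raw FRAP ROI trace to a :class:`RecoveryCurve`.

    All series must share one uniform time grid.  Negative values after
    background subtraction are clipped to zero with a warning.
    """
    times = np.asarray(times, dtype=float)
    raw = np.asarray(raw_roi, dtype=float)
    bg = np.asarray(background_roi, dtype=float)
    wf = np.asarray(whole_field, dtype=float)
    is_prebleach = np.asarray(is_prebleach, dtype=bool)
    if not (len(times) == len(raw) == len(bg) == len(wf)
            == len(is_prebleach)):
        raise ValueError("all series must share the time grid")
    dt = np.diff(times)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform time grid")
    if is_prebleach.sum() < 3:
        raise ValueError("need >=3 prebleach frames")

    sig = raw - bg
    field = wf - bg
    n_clipped = int((sig < 0).sum())
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative intensities to 0")
        sig = np.clip(sig, 0.0, None)
    if np.any(field <= 0):
        raise ValueError("whole-field signal not above background")

    # acquisition-decay correction: divide by the whole-field trajectory
    # relative to its prebleach level
    field_ref = field[is_prebleach].mean()
    corrected = sig / (field / field_ref)
    pre = corrected[is_prebleach].mean()
    if pre <= 0:
        raise ValueError("prebleach signal not above background")
    intensity = corrected / pre
    return RecoveryCurve(times=times, intensity=intensity,
                         is_prebleach=is_prebleach,
                         bleach_duration=bleach_duration,
                         roi_area=roi_area, r_n=r_n)


def normalize_flip_movie(movie: FlipMovie, control_nuc, control_cyt,
                         background) -> FlipMovie:
    """Normalize a FLIP movie by unbleached-control-cell intensity."""
    cn = np.asarray(control_nuc, dtype=float)
    cc = np.asarray(control_cyt, dtype=float)
    bg = np.asarray(background, dtype=float)
    if not (len(cn) == len(cc) == len(bg) == movie.n_frames):
        raise ValueError("control/background series must match frame count")
    control = 0.5 * ((cn - bg) + (cc - bg))
    if np.any(control <= 0):
        raise ValueError("control intensity <= background: cannot normalize")
    frames = (movie.frames - bg[:, None, None]) / control[:, None, None]
    return FlipMovie(frames=frames, frame_interval=movie.frame_interval,
                     bleach_schedule=movie.bleach_schedule.copy(),
                     bit_depth=movie.bit_depth,
                     control_normalization=control)


def _square_roi_mean(frame: np.ndarray, center_rc, side: int) -> float:
    r0 = int(round(center_rc[0] - side / 2))
    c0 = int(round(center_rc[1] - side / 2))
    patch = frame[r0:r0 + side, c0:c0 + side]
    if patch.size != side * side:
        raise ValueError("ROI extends outside the frame")
    return float(patch.mean())


def nc_ratio(frame: np.ndarray, geometry: CellGeometry, nuclear_center,
             cytoplasm_center, roi_side: int = 8,
             background: float = 0.0) -> float:
    """Nuclear-to-cytoplasmic intensity ratio from two placed square ROIs.

    ROI placement is supplied by the caller (equidistant from the nuclear
    boundary, nucleoli avoided); this function only checks compartment
    membership and computes the background-subtracted ratio.
    """
    frame = np.asarray(frame, dtype=float)
    nuc = _square_roi_mean(frame, nuclear_center, roi_side) - background
    cyt = _square_roi_mean(frame, cytoplasm_center, roi_side) - background
    r, c = (int(round(x)) for x in nuclear_center)
    if not geometry.analysis_nucleus_mask[r, c]:
        raise ValueError("nuclear ROI center not inside the nucleus mask")
    r, c = (int(round(x)) for x in cytoplasm_center)
    if not geometry.cytoplasm_mask[r, c]:
        raise ValueError("cytoplasmic ROI center not inside the cytoplasm")
    if cyt <= 0:
        raise ValueError("cytoplasmic intensity <= background")
    return nuc / cyt


def log2_nc_ratio(*args, **kwargs) -> float:
    """log2 of :func:`nc_ratio`, the scale used for localization plots."""
    return float(np.log2(nc_ratio(*args, **kwargs)))
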