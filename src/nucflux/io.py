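"""Readers and writers for curves, movies, masks, fit results and configs.

Formats: curves as CSV (time_s, intensity, is_prebleach); movies and label
masks as multi-page TIFF; fit results as JSON; configuration as YAML.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import CellGeometry, FitResult, FlipMovie, RecoveryCurve


def write_curve(curve: RecoveryCurve, path) -> None:
    df = pd.DataFrame({
        "time_s": curve.times,
        "intensity": curve.intensity,
        "is_prebleach": curve.is_prebleach.astype(int),
    })
    df.to_csv(path, index=False)


def read_curve(path, bleach_duration: float = 2.9,
               roi_area: float | None = None,
               r_n: float | None = None) -> RecoveryCurve:
    df = pd.read_csv(path)
    return RecoveryCurve(
        times=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        is_prebleach=df["is_prebleach"].to_numpy().astype(bool),
        bleach_duration=bleach_duration, roi_area=roi_area, r_n=r_n)


def write_movie(frames: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(frames))


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def write_flip_movie(movie: FlipMovie, path, meta_path=None) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    if meta_path is not None:
        meta = {"frame_interval": movie.frame_interval,
                "bleach_schedule": movie.bleach_schedule.tolist(),
                "bit_depth": movie.bit_depth}
        with open(meta_path, "w") as fh:
            json.dump(meta, fh)


def read_flip_movie(path, meta_path=None, frame_interval: float = 2.0,
                    n_prebleach: int = 3) -> FlipMovie:
    frames = tifffile.imread(path).astype(float)
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        return FlipMovie(frames, frame_interval=meta["frame_interval"],
                         bleach_schedule=np.asarray(meta["bleach_schedule"]),
                         bit_depth=meta.get("bit_depth", 12))
    sched = np.full(frames.shape[0], frame_interval)
    sched[:n_prebleach] = 0.0
    return FlipMovie(frames, frame_interval=frame_interval,
                     bleach_schedule=sched)


# Geometry is stored as a single 8-bit label TIFF: 0 background,
# 1 cytoplasm, 2 nucleus, 3 nucleoli, 4 bleach ROI (over nucleus),
# 5 bleach ROI (over cytoplasm).
_LABELS = dict(background=0, cytoplasm=1, nucleus=2, nucleoli=3,
               bleach_nuc=4, bleach_cyt=5)


def write_geometry(geom: CellGeometry, path) -> None:
    lab = np.zeros(geom.frame_shape, dtype=np.uint8)
    lab[geom.cytoplasm_mask] = _LABELS["cytoplasm"]
    lab[geom.nucleus_mask] = _LABELS["nucleus"]
    lab[geom.nucleoli_mask] = _LABELS["nucleoli"]
    if geom.bleach_roi is not None and geom.bleach_roi.any():
        code = (_LABELS["bleach_nuc"]
                if geom.bleach_compartment == "nucleus"
                else _LABELS["bleach_cyt"])
        lab[geom.bleach_roi] = code
    tifffile.imwrite(path, lab)


def read_geometry(path, pixel_size: float) -> CellGeometry:
    lab = tifffile.imread(path)
    bleach_nuc = lab == _LABELS["bleach_nuc"]
    bleach_cyt = lab == _LABELS["bleach_cyt"]
    nucleus = (lab == _LABELS["nucleus"]) | (lab == _LABELS["nucleoli"]) \
        | bleach_nuc
    cytoplasm = (lab == _LABELS["cytoplasm"]) | bleach_cyt
    bleach = bleach_nuc | bleach_cyt
    return CellGeometry(
        pixel_size=pixel_size, nucleus_mask=nucleus,
        nucleoli_mask=lab == _LABELS["nucleoli"], cytoplasm_mask=cytoplasm,
        bleach_roi=bleach if bleach.any() else None)


def write_fit_result(result: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, default=float)


def read_fit_result(path) -> FitResult:
    with open(path) as fh:
        d = json.load(fh)
    return FitResult(**d)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
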