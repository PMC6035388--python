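"""Synthetic cell geometries: elliptical nucleus, nucleoli, cytoplasm.

Emulates the manually traced compartment boundaries of real acquisitions.
The nucleus is an ellipse with requested area and eccentricity, nucleoli
are small discs inside it, and the cytoplasm is a concentric elliptical
annulus scaled so its area is a requested multiple (typically 1-2x) of
the nuclear area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk, ellipse

from .datatypes import CellGeometry, FLIP_PIXEL_SIZE


@dataclass
class GeometrySpec:
    nuclear_area: float = 150.0       # um^2
    nuclear_eccentricity: float = 0.6
    n_nucleoli: int = 2
    nucleolus_radius: float = 1.0     # um
    cyto_area_ratio: float = 1.5      # cytoplasm / nucleus, in [1, 2]
    frame_shape: tuple[int, int] = (128, 128)
    pixel_size: float = FLIP_PIXEL_SIZE
    bleach_placement: str = "centered"   # "centered" | "right_shifted"
    bleach_shape: str = "square"         # "square" | "circle"
    bleach_size: float = 8.0             # px: square side or circle diameter


def _ellipse_axes(area_px: float, eccentricity: float) -> tuple[float, float]:
    # area = pi a b, e = sqrt(1 - (b/a)^2)
    ratio = np.sqrt(1.0 - eccentricity ** 2)  # b/a
    a = np.sqrt(area_px / (np.pi * ratio))
    return a, a * ratio


def make_geometry(spec: GeometrySpec, seed: int = 0) -> CellGeometry:
    """Build a :class:`CellGeometry` satisfying ``spec``; deterministic
    for a fixed seed."""
    rng = np.random.default_rng(seed)
    h, w = spec.frame_shape
    cr, cc = h / 2.0, w / 2.0
    px_area = spec.pixel_size ** 2

    a_nuc, b_nuc = _ellipse_axes(spec.nuclear_area / px_area,
                                 spec.nuclear_eccentricity)
    # total cell ellipse sized so cytoplasm = ratio * nucleus
    scale = np.sqrt(1.0 + spec.cyto_area_ratio)
    a_cell, b_cell = a_nuc * scale, b_nuc * scale
    if a_cell >= w / 2 - 2 or b_cell >= h / 2 - 2:
        raise ValueError("requested geometry does not fit the frame")

    nucleus = np.zeros((h, w), dtype=bool)
    rr, cols = ellipse(cr, cc, b_nuc, a_nuc, shape=(h, w))
    nucleus[rr, cols] = True
    cell = np.zeros((h, w), dtype=bool)
    rr, cols = ellipse(cr, cc, b_cell, a_cell, shape=(h, w))
    cell[rr, cols] = True
    cytoplasm = cell & ~nucleus

    bleach = _place_bleach(spec, nucleus, (cr, cc), (a_nuc, b_nuc))

    # nucleoli must stay inside the nucleus and clear of the bleach site
    protect = np.zeros((h, w), dtype=bool)
    br, bc = np.nonzero(bleach)
    pad = 2
    protect[max(br.min() - pad, 0):br.max() + pad + 1,
            max(bc.min() - pad, 0):bc.max() + pad + 1] = True
    nucleoli = np.zeros((h, w), dtype=bool)
    r_nucleolus = spec.nucleolus_radius / spec.pixel_size
    for _ in range(spec.n_nucleoli):
        for _attempt in range(50):
            dr = rng.uniform(-0.6, 0.6) * b_nuc
            dc = rng.uniform(-0.6, 0.6) * a_nuc
            rr, cols = disk((cr + dr, cc + dc), r_nucleolus, shape=(h, w))
            inside = np.zeros((h, w), dtype=bool)
            inside[rr, cols] = True
            if np.all(nucleus[inside]) and not (inside & protect).any():
                nucleoli |= inside
                break
    return CellGeometry(pixel_size=spec.pixel_size, nucleus_mask=nucleus,
                        nucleoli_mask=nucleoli, cytoplasm_mask=cytoplasm,
                        bleach_roi=bleach)


def _place_bleach(spec: GeometrySpec, nucleus_ok: np.ndarray, center,
                  axes) -> np.ndarray:
    h, w = nucleus_ok.shape
    cr, cc = center
    a_nuc, _ = axes
    if spec.bleach_placement == "right_shifted":
        cc = cc + 0.6 * a_nuc
    elif spec.bleach_placement != "centered":
        raise ValueError(f"unknown placement {spec.bleach_placement!r}")
    bleach = np.zeros((h, w), dtype=bool)
    if spec.bleach_shape == "square":
        side = int(round(spec.bleach_size))
        r0, c0 = int(round(cr - side / 2)), int(round(cc - side / 2))
        bleach[r0:r0 + side, c0:c0 + side] = True
    elif spec.bleach_shape == "circle":
        rr, cols = disk((cr, cc), spec.bleach_size / 2.0, shape=(h, w))
        bleach[rr, cols] = True
    else:
        raise ValueError(f"unknown bleach shape {spec.bleach_shape!r}")
    if not np.all(nucleus_ok[bleach]):
        raise ValueError("bleach ROI does not fit inside the nucleus")
    return bleach
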