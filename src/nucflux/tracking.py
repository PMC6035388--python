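"""Cell tracking on label movies, morphology metrics and correlation
analysis of time-lapse signals.

Tracking consumes per-frame foreground masks for a nuclear and a
cytoplasmic channel (segmentation thresholds are upstream of this
module).  It runs in two stages: a frame-processing stage that labels
objects, splits touching cells with a marker-based distance-transform
watershed, handles division (one cytoplasmic object over two nuclei) and
removes border-touching or nucleus-less objects; then a frame-joining
stage that propagates identities by mask overlap, with one-to-many and
many-to-one care.  Tracks shorter than ``min_frames`` (default 24 frames
= two hours at 5-min resolution) are dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import pearsonr, t as t_dist
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

DEFAULT_FRAME_INTERVAL_MIN = 5.0


def morphology(mask: np.ndarray, pixel_size: float = 1.0) -> dict:
    """Area, perimeter, eccentricity and circularity of one region.

    Circularity f_circ = 4 pi Area / Perimeter^2 is 1 for a circle and
    lower for other shapes; values slightly above 1 can occur because the
    perimeter estimator under-measures digital contours and are left
    unclipped.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    props = regionprops(mask.astype(int))[0]
    area = props.area * pixel_size ** 2
    # chain-code perimeters over-measure smooth contours while Crofton
    # under-measures corner-rich ones; their mean acts as a corner
    # correction and keeps circularity near 1 for discs
    perim = 0.5 * (props.perimeter + props.perimeter_crofton) * pixel_size
    circ = 4.0 * np.pi * area / perim ** 2 if perim > 0 else np.nan
    return {"area": float(area), "perimeter": float(perim),
            "eccentricity": float(props.eccentricity),
            "circularity": float(circ),
            "centroid": tuple(float(c) for c in props.centroid)}


def _split_touching(cyt_frame: np.ndarray, nuc_frame: np.ndarray):
    """Label a cytoplasm frame, splitting objects that cover several
    nuclei via a nucleus-seeded watershed on the distance transform."""
    nuc_lab = sk_label(nuc_frame)
    cyt_lab = sk_label(ndimage.binary_erosion(cyt_frame))
    cyt_lab = watershed(-ndimage.distance_transform_edt(cyt_frame),
                        markers=nuc_lab, mask=cyt_frame)
    # objects without any nucleus marker come out as 0 under the
    # watershed; recover them so they can be removed explicitly
    leftover = cyt_frame & (cyt_lab == 0)
    if leftover.any():
        extra = sk_label(leftover)
        extra[extra > 0] += cyt_lab.max()
        cyt_lab = cyt_lab + extra
    return cyt_lab, nuc_lab


def _frame_objects(cyt_frame, nuc_frame, min_area: int):
    """Frame-processing stage: labelled cells valid in this frame."""
    cyt_lab, nuc_lab = _split_touching(cyt_frame, nuc_frame)
    h, w = cyt_frame.shape
    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    valid = {}
    for p in regionprops(cyt_lab):
        m = cyt_lab == p.label
        if p.area < min_area:
            continue
        if (m & border).any():
            continue                      # metrics unreliable at the edge
        n_nuclei = len(np.unique(nuc_lab[m & (nuc_lab > 0)]))
        if n_nuclei == 0:
            continue                      # nucleus-less object
        valid[p.label] = m
    return valid, nuc_lab


@dataclass
class Track:
    cell_id: int
    frames: list = field(default_factory=list)
    records: list = field(default_factory=list)   # per-frame morphology

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records)
        df.insert(0, "frame", self.frames)
        df.insert(0, "cell_id", self.cell_id)
        return df


def track_cells(nuclei: np.ndarray, cytoplasm: np.ndarray,
                min_frames: int = 24, min_area: int = 20,
                pixel_size: float = 1.0,
                intensity: np.ndarray | None = None) -> list[Track]:
    """Track cells through a (T, H, W) pair of foreground mask stacks.

    Returns tracks covering at least ``min_frames`` consecutive frames.
    If an ``intensity`` stack is given, per-frame nuclear and
    cytoplasmic median intensities and the N/C ratio are recorded.
    """
    if nuclei.shape != cytoplasm.shape:
        raise ValueError("channel stacks must share a shape")
    if nuclei.shape[0] == 0:
        raise ValueError("empty movie")
    tracks: dict[int, Track] = {}
    prev_masks: dict[int, np.ndarray] = {}
    next_id = 1
    for f in range(nuclei.shape[0]):
        objects, nuc_lab = _frame_objects(cytoplasm[f], nuclei[f],
                                          min_area)
        assigned: dict[int, np.ndarray] = {}
        used_prev: set[int] = set()
        # frame joining: match to the previous frame by largest overlap
        for lab, m in objects.items():
            best_id, best_ov = None, 0
            for tid, pm in prev_masks.items():
                ov = int((m & pm).sum())
                if ov > best_ov:
                    best_id, best_ov = tid, ov
            if best_id is not None and best_id not in used_prev:
                tid = best_id
                used_prev.add(tid)
            else:
                tid = next_id          # unmatched or many-to-one loser
                next_id += 1
            assigned[tid] = m
            rec = morphology(m, pixel_size)
            nm = (nuc_lab > 0) & m
            if nm.any():
                nrec = morphology(nm, pixel_size)
                rec.update({f"nuc_{k}": v for k, v in nrec.items()
                            if k != "centroid"})
            if intensity is not None and nm.any():
                med_n = float(np.median(intensity[f][nm]))
                med_c = float(np.median(intensity[f][m & ~nm]))
                rec["nc_ratio"] = med_n / med_c if med_c > 0 else np.nan
            tr = tracks.setdefault(tid, Track(cell_id=tid))
            tr.frames.append(f)
            tr.records.append(rec)
        prev_masks = assigned
    out = []
    for tr in tracks.values():
        # keep the longest consecutive stretch
        frames = np.asarray(tr.frames)
        if len(frames) == 0:
            continue
        breaks = np.where(np.diff(frames) > 1)[0]
        start = 0
        best = (0, 0)
        for b in list(breaks) + [len(frames) - 1]:
            if b - start > best[1] - best[0]:
                best = (start, b)
            start = b + 1
        i0, i1 = best
        if frames[i1] - frames[i0] + 1 >= min_frames:
            tr.frames = list(frames[i0:i1 + 1])
            tr.records = tr.records[i0:i1 + 1]
            out.append(tr)
    return out


def track_identity_agreement(tracks: list[Track], truth: list[dict],
                             match_radius: float = 6.0) -> float:
    """Fraction of (frame, cell) truth entries matched by a track whose
    identity is consistent over time (majority vote per track)."""
    votes: dict[int, dict] = {}
    hits = []
    for tr in tracks:
        votes[tr.cell_id] = {}
        for f, rec in zip(tr.frames, tr.records):
            cen = np.array(rec["centroid"])
            for tid, c in truth[f].items():
                if np.hypot(*(cen - np.array(c))) <= match_radius:
                    votes[tr.cell_id][tid] = \
                        votes[tr.cell_id].get(tid, 0) + 1
    mapping = {cid: max(v, key=v.get) for cid, v in votes.items() if v}
    total = 0
    for tr in tracks:
        want = mapping.get(tr.cell_id)
        for f, rec in zip(tr.frames, tr.records):
            cen = np.array(rec["centroid"])
            total += 1
            c = truth[f].get(want)
            if c is not None and np.hypot(*(cen - np.array(c))) \
                    <= match_radius:
                hits.append(1)
            else:
                hits.append(0)
    return float(np.mean(hits)) if total else 0.0


# ---------------------------------------------------------- correlations

def autocorrelation(signal, max_lag: int | None = None) -> np.ndarray:
    """Mean-subtracted ACF normalized so ACF(0) = 1."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    n = len(x)
    if max_lag is None:
        max_lag = n - 1
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant signal has no autocorrelation")
    return np.array([x[:n - k] @ x[k:] / denom
                     for k in range(max_lag + 1)])


def cross_correlation(x, y, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation over lags -max_lag..max_lag.

    Positive lag means y lags x (y follows x).  Values fall in [-1, 1]
    and equal the ACF when x is y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        # interpolate the shorter signal onto the longer grid
        if len(x) < len(y):
            x = np.interp(np.linspace(0, 1, len(y)),
                          np.linspace(0, 1, len(x)), x)
        else:
            y = np.interp(np.linspace(0, 1, len(x)),
                          np.linspace(0, 1, len(y)), y)
    x = x - x.mean()
    y = y - y.mean()
    n = len(x)
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise ValueError("constant signal")
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(len(lags), dtype=float)
    for i, k in enumerate(lags):
        if k >= 0:
            vals[i] = x[:n - k] @ y[k:] / denom
        else:
            vals[i] = x[-k:] @ y[:n + k] / denom
    return lags, vals


def cohort_correlation(signals_x: list, signals_y: list, max_lag: int):
    """Per-track cross-correlations with cohort mean and 95% CI."""
    curves = []
    for x, y in zip(signals_x, signals_y):
        lags, vals = cross_correlation(x, y, max_lag)
        curves.append(vals)
    curves = np.asarray(curves)
    mean = curves.mean(axis=0)
    if len(curves) > 1:
        sem = curves.std(axis=0, ddof=1) / np.sqrt(len(curves))
        half = t_dist.ppf(0.975, len(curves) - 1) * sem
    else:
        half = np.zeros_like(mean)
    return {"lags": np.arange(-max_lag, max_lag + 1), "mean": mean,
            "ci_low": mean - half, "ci_high": mean + half,
            "per_track": curves}


def pearson_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations and two-sided p-values (test of zero
    correlation) between all column pairs of static per-cell metrics."""
    cols = df.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols,
                     columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            rv, pv = pearsonr(df[a], df[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def derivative(signal, dt: float = 1.0) -> np.ndarray:
    """Central-difference derivative of a track signal."""
    return np.gradient(np.asarray(signal, dtype=float), dt)
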