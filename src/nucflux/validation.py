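"""Model-validation analyses: the zero-import/export assumption check
for FRAP, and residual reports for FRAP and FLIP fits.

FRAP model fitting assumes nucleocytoplasmic transport is negligible over
the ~15 s recovery.  The check quantifies that assumption: the no-bleach
compartmental model (diffusion forced rapid at 1000 um^2/s so recovery is
reaction-limited) simulates the bleach-point recovery with transport on
and off, a single-reaction model is fitted to both, and the relative
difference between the fitted rates is reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import flip as _flip
from .datatypes import RecoveryCurve
from .frap import fit_reaction
from .geometry import GeometrySpec, make_geometry
from .postbleach import bleach_profile
from .rates import RateSet


@dataclass
class AssumptionReport:
    rate_with_transport: float
    rate_without_transport: float
    bleach_placement: str
    label: str = ""

    @property
    def relative_difference_pct(self) -> float:
        return abs(self.rate_with_transport
                   - self.rate_without_transport) \
            / self.rate_without_transport * 100.0


def _typical_geometry(placement: str) -> GeometrySpec:
    """Ellipse-based masks matching cohort-mean nuclear area and
    eccentricity of activated fibroblasts."""
    return GeometrySpec(nuclear_area=180.0, nuclear_eccentricity=0.7,
                        n_nucleoli=0, cyto_area_ratio=1.5,
                        bleach_placement=placement,
                        bleach_shape="square", bleach_size=8)


def _postbleach_state(grid, geometry, rates: RateSet, K, r_e):
    """Initial state: uniform nuclear concentration 1 carrying an
    exponential-of-Gaussian dip about the bleach point; cytoplasm at its
    steady-state level.  The mobile concentration is uniform and capped
    by the remaining concentration at the bleach point (a higher mobile
    level elsewhere would flow back diffusively and the recovery would
    not be reaction-limited); the immobile species holds the rest."""
    nm_pre = 1.0 / (1.0 + rates.k1 / rates.k_off)
    c0 = rates.k2 / rates.k_im * nm_pre if rates.k_im > 0 else nm_pre
    b_ij = grid.nuc_cells[grid.bleach_index]
    box = grid.pixel_box(b_ij)
    b_center = ((box[0].start + box[0].stop - 1) / 2.0,
                (box[1].start + box[1].stop - 1) / 2.0)
    total = np.empty(grid.n_nuc)
    for k, ij in enumerate(grid.nuc_cells):
        bx = grid.pixel_box(ij)
        cr = (bx[0].start + bx[0].stop - 1) / 2.0
        cc = (bx[1].start + bx[1].stop - 1) / 2.0
        r_um = np.hypot(cr - b_center[0], cc - b_center[1]) \
            * geometry.pixel_size
        total[k] = bleach_profile(r_um, K, r_e)
    mobile = total.min()     # the bleach-point value
    x = np.empty(2 * grid.n_nuc + grid.n_cyt)
    x[:grid.n_nuc] = mobile
    x[grid.n_nuc:2 * grid.n_nuc] = total - mobile
    x[2 * grid.n_nuc:] = c0
    return x


def zero_transport_check(rates: RateSet, K: float = 1.0,
                         r_e: float = 1.5, r_n: float = 1.232,
                         placement: str = "centered",
                         duration: float = 15.0, dt: float = 0.06,
                         D_fast: float = 1000.0,
                         label: str = "") -> AssumptionReport:
    """Quantify the effect of ignoring import/export on the fitted
    dissociation rate (no-bleach forward model, rapid diffusion)."""
    spec = _typical_geometry(placement)
    geometry = make_geometry(spec, seed=7)
    grid = _flip.discretize(geometry)
    sim_rates = rates.replace(eta=0.0, D=D_fast)
    x0 = _postbleach_state(grid, geometry, sim_rates, K, r_e)
    times = np.arange(0.0, duration + dt / 2, dt)

    fitted = {}
    for transport, r in (("on", sim_rates),
                         ("off", sim_rates.replace(k2=0.0, k_im=0.0))):
        A = _flip._assemble(grid, r, bleach_on=False)
        from scipy.linalg import expm
        P = expm(A * dt)
        x = x0.copy()
        trace = np.empty(len(times))
        b = grid.bleach_index
        trace[0] = x[b] + x[grid.n_nuc + b]
        for i in range(1, len(times)):
            x = P @ x
            trace[i] = x[b] + x[grid.n_nuc + b]
        curve = RecoveryCurve(
            times=np.concatenate([[-3 * dt, -2 * dt, -dt], times]),
            intensity=np.concatenate([[1.0, 1.0, 1.0], trace]),
            is_prebleach=np.array([True] * 3 + [False] * len(times)))
        fit = fit_reaction(curve, 1)
        fitted[transport] = fit.parameters["k_off1"]
    return AssumptionReport(rate_with_transport=fitted["on"],
                            rate_without_transport=fitted["off"],
                            bleach_placement=placement, label=label)


# ------------------------------------------------------------- residuals

def frap_residual_report(curves, fits) -> dict:
    """Per-time residual traces (observed minus predicted) for a cohort
    of recovery curves, plus the median trace across cells."""
    traces = []
    for curve, fit in zip(curves, fits):
        traces.append(curve.post_intensity - fit.fitted_curve)
    traces = np.asarray(traces)
    return {"residuals": traces,
            "median_trace": np.median(traces, axis=0),
            "times": curves[0].post_times}


def flip_residual_report(result) -> dict:
    """FLIP residuals grouped by region: bleach point, remainder of the
    nucleus, cytoplasm."""
    res = result.residuals()
    lab = result.model.grid.cell_labels()
    groups = {"bleach_point": res[:, lab == _flip.LABEL_BLEACH],
              "nucleus": res[:, lab == _flip.LABEL_NUCLEUS],
              "cytoplasm": res[:, lab == _flip.LABEL_CYTOPLASM]}
    return {"times": result.model.fit_times,
            "by_region": groups,
            "median_traces": {k: np.median(v, axis=1)
                              for k, v in groups.items() if v.size}}
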