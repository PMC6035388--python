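# Methods

## Scope and model

`nucflux` models a fluorescently tagged transcriptional regulator that
shuttles between cytoplasm and nucleus and binds immobile nuclear
partners.  Inside the nucleus a mobile species N_M diffuses (coefficient
D), associates with chromatin partners at pseudo-first-order rate
k1 = k̃1·N_CHR and dissociates at k-1; the bound species N_I does not
diffuse.  The cytoplasmic species C only diffuses.  The compartments
exchange across the nuclear envelope by first-order import (k-2, into
the nucleus) and export (k2).  All rates are 1/s; D is in µm²/s;
intensities are treated as proportional to concentration.

## FRAP analysis

**Postbleach profile.**  The first postbleach frame, re-centred on the
bleach spot and restricted to the nucleus minus nucleoli (dense
chromatin excludes the reporter there), is reduced to a median radial
profile: per 1-pixel annulus, intensities are linearly interpolated onto
a uniform 360-point polar-angle grid (compensating the sparse sampling
near the centre) and the median taken; the representative radius of a
bin is the median sample radius.  The profile is fitted with the
exponential-of-Gaussian

    C(r, 0) = exp[−K_PB · exp(−2r²/r_e²)],

giving the bleach depth K_PB and effective radius r_e (wider than the
nominal ROI radius r_n because diffusion proceeds during the ~2.9 s
bleach).  A grid pre-scan precedes the local least-squares refinement so
the fit sits at the global SSE minimum.

**Bleach depth from the recovery curve.**  With ν0 = r_e²/r_n², the
first recovery point obeys S(0) = ν0·K^(−ν0)·γ(ν0, K) with γ the lower
incomplete gamma function; this is exactly the bleach profile averaged
under a Gaussian detection weight of e⁻² radius r_n (verified against
numerical quadrature to <1e−12; a plain disc average does *not*
reproduce the relation).  K_RC is obtained by bracketed root search
(S(0) is strictly decreasing in K) and is the depth used downstream,
since it is self-consistent with the recovery data.

**Candidate recovery models.**  Four models are fitted to the
normalized recovery (background subtracted, whole-field acquisition
decay divided out, prebleach mean scaled to 1):

* diffusion: the series Q_D(t) = Σ_m (−K)^m/m! · r_e²/(r_e² + m(8D_e t + r_n²)),
  truncated when a term falls below 1e−10 (cap 200 terms); one free
  parameter D_e, initial guess 19 µm²/s (interpolated mobility of 3–5×
  GFP multimers, the tag's approximate size).
* reaction–diffusion: an axisymmetric two-species PDE on r ∈ [0, 12 µm]
  (zero flux at both ends, initial condition = binding equilibrium
  scaled by the bleach profile, readout under the same Gaussian
  detection weight), free (k_on, k_off, D1) with bound-state diffusion
  D2 = 0.  The radial method-of-lines system is linear and is propagated
  exactly with matrix exponentials (80 radial nodes by default; the
  closed-form diffusion series is reproduced to <0.5% in the k_on → 0
  limit, and the fast-diffusion limit collapses onto a single
  exponential after the sub-frame equilibration transient).
* single / double reaction: Q(t) = Σ Aᵢ(1 − e^(−kᵢ(t−t₀))), with t₀
  absorbing the uncertainty in the time origin (and, for n = 1, the
  nonzero initial intensity).

All fits minimize the time-weighted SSE

    SSE_w = ∫₀^τ (S − Q)² / (ψ + ∫₀^τ S dφ) dψ

(trapezoidal quadrature; the integral in the denominator removes the
t = 0 singularity, so early frames — which carry the fast-rate
information — dominate).  Initial guesses come from an exponential
pre-fit y = α(1 − e^(−κt)) started at (α, κ) = (0.3, 0.5); the double
reaction seeds its fast rate from the first 30% and its slow rate from
the final 30% of the single-reaction fit.  Bounded trust-region least
squares with three deterministically jittered restarts guards against
local minima.

**Filtering and selection.**  Fits are discarded when physically
implausible: D_e > 60 µm²/s (approaches single-GFP mobility — too fast
for a 4× larger fusion), any rate > 25 s⁻¹ (unresolvable at 60 ms
frames), dissociation < 0.01 s⁻¹ (0.001 s⁻¹ in the slow-TEAD mode) —
such "rates" reflect drift, not binding.  Surviving models are ranked by
AIC = n·ln(SSE_w/n) + 2(p+1) (AICc optional) and Akaike weights.  If a
diffusion-containing model carries the top weight it is selected;
otherwise the single vs double reaction is arbitrated by the nested
F-test F = ((SSE₁−SSE₂)/(df₁−df₂))/(SSE₂/df₂), the double reaction being
accepted only when p ≤ 0.05 *and* its Akaike weight exceeds the
single's.  Cells with no plausible fit are "noisy" and enter cohort
statistics at the arbitrary placeholder 3.5 s⁻¹ (assumed rapid
recovery); cohort medians are reported with and without placeholders.
Half-times are computed for descriptive parity only — they conflate
diffusion, binding and geometry and are never used for inference.

## FLIP analysis

**Discretization.**  The cell is gridded into square cells the size of
the bleach ROI (8 px ≈ 2.1 µm at the default 0.264 µm/px), the lattice
anchored so one cell coincides exactly with the ROI.  A grid point is
nuclear/cytoplasmic when ≥50% covered by the respective mask; grid-point
intensity is the mean over in-mask pixels of its own compartment, so
boundary cells report pure-compartment intensity.  Thin cytoplasmic
regions are expected to be pre-excluded from the mask (low focal-volume
signal is a geometry artifact, not kinetics).

**Forward model.**  Nuclear cells carry (N_M, N_I) with 5-point
Laplacian diffusion on N_M, binding k1/k−1, and a bleach sink η on both
species at the ROI cell(s); cytoplasmic cells carry diffusing C.  Each
nucleus–cytoplasm edge exchanges (k−2·C − k2·N_M)·(L/A) with
L/A = h/h² = 1/h, the interface-length-to-area scaling that keeps the
rates in 1/s and makes fitted rates grid-convergent (export/import move
<10% when the fitting lattice is halved).  The semi-discrete system is
linear, so propagation uses exact dense matrix exponentials per frame
interval (the system is stiff — η and D/h² are fast against the
transport rates — and the exponential integrator handles this with
machine-precision mass conservation; total signal is conserved exactly
at η = 0 and strictly decreasing otherwise).  The bleach schedule is
interleaved: the sink is on for the bleach duration of each frame
interval, which at the canonical protocol (2 s bleach between frames
2 s apart) is effectively continuous.

**Initial state and fitting.**  Before bleaching the system is at its
compartmental steady state, which pins N_M0 = (k−2/k2)·C0 and
N_I0 = (k1/k−1)·N_M0 and removes two free parameters.  D (19 µm²/s) and
k−1 (the FRAP cohort median for the cell type, 0.55 s⁻¹ normal / 0.40
s⁻¹ activated by default) are fixed; (k1, k2, k−2, η, C0) are fitted by
bounded least squares (rates in [1e−6, 50] s⁻¹, C0 under twice the
maximum intensity — generous bounds that exclude the degenerate k2 → 0
steady state).  Initial guesses: C0 = median cytoplasmic intensity,
k1 = the fixed k−1, and (k2, k−2, η) from a two-compartment ODE pre-fit
to the bleach-point and mean cytoplasmic traces, with fallback defaults
of 0.002–0.005 s⁻¹ (the N/C ratio deciding whether import or export is
guessed larger) and η = 1.5 s⁻¹.

**Weights.**  Residuals are weighted per grid point and time as
w = 1/[(ψ + Σ∫S)·∫S_p], i.e. time-weighted as in FRAP and normalized by
each grid point's total intensity, then re-scaled so the bleach point,
the rest of the nucleus, and the cytoplasm contribute equal total
weight — without this the small bleach region would be swamped by the
cell's bulk.  Grid points dark at all times get zero weight.

**Sensitivity and diagnostics.**  `FlipResults.sensitivity_sweep`
refits the free parameters with k−1 or D fixed on a grid (±50% in k−1
moves import/export by <10% while association moves most — association
is the least identifiable, absorbing the mobile-fraction constraint);
`sse_heatmap` exposes the weighted-SSE surface over parameter pairs
(association/export show a sharp minimum; import/export a shallow
near-linear valley reflecting the N/C intensity ratio).  Residual
reports group observed-minus-predicted by bleach point, remaining
nucleus, and cytoplasm.

## Steady state and rate substitution

Fractions follow from the steady-state relations with amounts =
concentration × compartment volume; the nuclear/cytoplasmic effective
volume ratio defaults to 1, which reproduces the published fractions
(normal ~40% nuclear / ~12% bound; activated ~61% / ~24%) from the
published medians, and is exposed as a parameter because the original
analysis does not state how volumes enter.  `substitute_rates` swaps
named rates between two rate sets; a distribution is classified
"CAF-like" above 55% nuclear.  Swapping export alone converts either
phenotype into the other, matching the published substitution analysis.

## Zero-transport check for FRAP

The FRAP models assume no import/export during the ~15 s recovery.  The
check builds a typical-cell geometry (ellipse masks at cohort-mean area
180 µm² and eccentricity 0.7), initializes the nucleus at concentration
1 with an exponential-of-Gaussian dip (nominal radius 1.232 µm) at the
bleach point and the cytoplasm at its steady-state level, forces
reaction-limited recovery by setting D = 1000 µm²/s with the mobile
concentration uniform and capped at the bleach-point total (any excess
would recover diffusively), and simulates the η = 0 model for 15 s with
transport on and off.  Single-reaction fits to the two bleach-point
traces differ by ≪5% in rate for both wild-type rate sets (the effect
grows with dissociation rate and shrinks for boundary-adjacent bleach
placement).

## Synthetic data: what it does and does not show

Generators produce postbleach frames (profile + additive Gaussian noise
inside the nucleus), recovery curves from each candidate model's closed
form (or the radial PDE for reaction–diffusion), FLIP movies from the
compartmental model solved on a quarter-ROI lattice and painted onto the
pixel raster, and label-mask tracking movies with known identities,
divisions, touching events and border exits.  Defaults follow the
acquisition they emulate: 128×128 frames, 3 prebleach frames, 2.9 s
bleach then 60 ms frames for 18 s (FRAP); 150 frames every 2 s with 2 s
bleaching between frames and an 8×8 px (≈4.46 µm²) ROI (FLIP); noise is
additive Gaussian with sd 0.02 on normalized intensity (the original
noise statistics are not published; this is recorded as an assumption).
Nuclear geometry defaults to 150 µm² with 1–2 nucleoli and a
cytoplasm/nucleus area ratio of 1.5.

Passing recovery tests therefore demonstrates correctness of the
inference given the model class and realistic acquisition noise; they
do not probe photophysics (blinking, reversible photoswitching),
shot-noise statistics, cell movement during acquisition, or boundary
misclassification from manual tracing — all listed as residual sources
in the original analysis and out of scope here.

## Numerical choices and known limitations

* All semi-discrete systems are linear; matrix-exponential propagation
  replaces stiff ODE integration, making solves exact in time and
  bit-reproducible.
* The FLIP staircase interface discretization is first order: halving
  the simulation lattice still moves the bleach-point trace by ~0.6–1%
  of its initial value, so the simulator default is the finest lattice
  that keeps dense exponentials cheap (quarter-ROI).  Fitted transport
  rates at the canonical coarse grid carry a few-percent discretization
  bias (export ~3%, import ~8–10% median on synthetic movies), in line
  with the original method's stated coarse-grid tradeoff.
* Association k1 is the least identifiable FLIP parameter (~±20%);
  import/export are robust to it.
* Perimeter (hence circularity) uses the mean of the chain-code and
  Crofton estimators as a corner correction; circularity can slightly
  exceed 1 for near-circular digital shapes and is not clipped.
* Tie-breaks: model selection prefers the single reaction unless the
  double reaction wins both the F-test and the Akaike comparison;
  many-to-one tracking overlaps assign the existing identity to the
  largest-overlap object and new identities to the rest.
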