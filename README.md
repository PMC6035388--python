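# nucflux

Quantitative nucleocytoplasmic shuttling kinetics from photobleaching
experiments.

Transcriptional regulators such as YAP1 move continuously between the
cytoplasm and the nucleus, where a fraction binds chromatin-associated
partners (e.g. TEAD).  `nucflux` estimates the four rates that govern
this steady state — chromatin association `k1` and dissociation `k-1`,
nuclear export `k2` and import `k-2` — from two complementary live-cell
assays:

* **FRAP** (fluorescence recovery after photobleaching): a circular
  nuclear or cytoplasmic region is bleached once and the recovery
  `S(t)` is fitted with four candidate models — pure/effective
  diffusion, reaction–diffusion, and one- or two-exponential reaction
  models `Q(t) = Σ Aᵢ(1 − e^{−kᵢ(t−t₀)})` — under a time-weighted SSE
  (early frames up-weighted), with implausible fits discarded and the
  rest arbitrated by AIC/Akaike weights and a nested F-test.  In the
  rapid-diffusion regime the selected reaction rate is the chromatin
  dissociation rate `k-1`; its reciprocal is the mean residence time.
* **FLIP** (fluorescence loss in photobleaching): a small nuclear square
  is bleached repeatedly while the whole cell is imaged.  The cell is
  discretized into a coarse lattice and a compartmentalized
  reaction–diffusion PDE — mobile/bound species in the nucleus, a
  diffusing species in the cytoplasm, flux boundary conditions
  `k2·N_M ⇌ k-2·C` across the nuclear envelope, and a bleach sink η —
  is fitted to every grid point at once, yielding `k1`, `k2`, `k-2`, η
  and the cytoplasmic level `C0` (with `D` and `k-1` fixed from FRAP).

From the fitted rates the package computes steady-state distributions
(cytoplasmic / nuclear-mobile / chromatin-bound fractions via
`N_M = (k-2/k2)·C`, `N_I = (k1/k-1)·N_M`), rate-substitution experiments
between cell states, the zero-transport assumption check for FRAP,
residual analyses, and cell-tracking / correlation statistics for
time-lapse morphology and nuclear-to-cytoplasmic ratio dynamics.
Because raw imaging data of this kind are rarely shareable, a
first-class synthetic-data module simulates every input (postbleach
frames, recovery curves, FLIP movies, label-mask tracking movies) from
known ground truth.

## Worked example

Simulate a noisy nuclear FRAP curve at the activated-fibroblast median
dissociation rate (0.39 s⁻¹) and run model selection:

```python
from nucflux import FrapRecoveryModel, GroundTruth, simulate_frap_curve

truth = GroundTruth(model_id="single_reaction", amplitudes=(0.62,),
                    reaction_rates=(0.39,), t0=-2.0, noise_sd=0.02, seed=11)
curve = simulate_frap_curve(truth)
res = FrapRecoveryModel(curve, K_RC=1.0, r_e=1.5, r_n=1.232).fit()
print(res.summary())
```

```
FRAP recovery model selection
====================================================
model                       wSSE       AIC   weight    status
diffusion               0.005406  -3285.13    0.000  ok
reaction_diffusion        0.0055         -        -  rate_exceeds_frame_rate_bound
single_reaction        0.0003369  -4116.54    0.874  ok
double_reaction        0.0003368  -4112.68    0.126  ok
nested F-test single vs double: F=0.066, p=0.9359
selected: single_reaction (A1=0.6207, k_off1=0.3936, t0=-1.94)
dissociation rate: 0.3936 1/s
```

The diffusion model fits poorly (16× larger weighted SSE), the double
reaction does not justify its extra parameters (F-test p = 0.94), and
the selected single-reaction rate 0.394 s⁻¹ recovers the generating
0.39 s⁻¹ — a ~2.5 s mean chromatin residence time.

The same round trip for FLIP:

```python
from nucflux import (FlipModel, GeometrySpec, GroundTruth, make_geometry,
                     simulate_flip_movie)
from nucflux.rates import CAF1_WT

geom = make_geometry(GeometrySpec(), seed=1)
movie = simulate_flip_movie(GroundTruth(rates=CAF1_WT.replace(eta=1.5,
                            k_off=0.40), noise_sd=0.02, seed=3), geom)
print(FlipModel(movie, geom, fixed_k_off=0.40).fit().summary())
```

recovers export 0.018 s⁻¹ and import ~0.018 s⁻¹ from the
activated-state ground truth (printed medians 0.018 / 0.017 s⁻¹).

A thin CLI mirrors the library: `nucflux simulate frap|flip|profile|tracks`,
`nucflux fit-frap`, `nucflux fit-flip`, `nucflux steady-state`,
`nucflux validate zero-transport`, `nucflux track`.

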