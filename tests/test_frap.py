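"""FRAP recovery fitting, plausibility filters, AIC/F-test selection."""
import numpy as np
import pytest

from nucflux.datatypes import RecoveryCurve
from nucflux.frap import (ModelFit, RadialReactionDiffusion,
                          akaike_weights, apply_plausibility_filters,
                          diffusion_curve, fit_diffusion, fit_reaction,
                          fit_reaction_diffusion, half_time,
                          nested_f_test, reaction_curve, select_model,
                          summarize_cohort, weighted_sse)
from nucflux.postbleach import initial_intensity
from nucflux.rates import RateSet
from nucflux.simulate import GroundTruth, simulate_frap_curve


def _curve(t, S, pre=3):
    dt = t[1] - t[0]
    times = np.concatenate([t[0] - dt * np.arange(pre, 0, -1), t])
    intensity = np.concatenate([np.ones(pre), S])
    return RecoveryCurve(times=times, intensity=intensity,
                         is_prebleach=np.arange(len(times)) < pre)


# --------------------------------------------------------- weighted SSE

def test_weighted_sse_zero_for_perfect_model():
    t = np.linspace(0, 5, 20)
    S = 1 - 0.5 * np.exp(-t)
    assert weighted_sse(t, S, S) == 0.0


def test_weighted_sse_quadratic_in_residual():
    t = np.linspace(0, 5, 20)
    S = 1 - 0.5 * np.exp(-t)
    sse1 = weighted_sse(t, S, S + 0.1)
    sse2 = weighted_sse(t, S, S + 0.2)
    assert sse2 == pytest.approx(4 * sse1)


def test_weighted_sse_two_point_hand_value():
    # S=(0.5,1), Q=(0.5,0.5) on t=(0,1): int S dt = 0.75,
    # integrand (0, 0.25/1.75), trapezoid = 0.25/(2*1.75) = 1/14
    assert weighted_sse([0.0, 1.0], [0.5, 1.0], [0.5, 0.5]) \
        == pytest.approx(1.0 / 14.0)


def test_weighted_sse_rejects_mismatched_grids():
    with pytest.raises(ValueError):
        weighted_sse([0, 1], [1, 1], [1.0])
    with pytest.raises(ValueError):
        weighted_sse([], [], [])


# --------------------------------------------------------- model curves

def test_diffusion_curve_limits():
    # plateau at 1 and Q_D(0) equal to the bleach-depth relation S(0)
    assert diffusion_curve([1e7], 10.0, 1.0, 1.5, 1.232)[0] \
        == pytest.approx(1.0, abs=1e-6)
    q0 = diffusion_curve([0.0], 10.0, 1.0, 1.2, 1.0)[0]
    assert q0 == pytest.approx(initial_intensity(1.0, 1.44), abs=1e-9)


def test_reaction_curve_half_recovery():
    # single reaction A=0.8, k=0.5: half the amplitude at t = ln2/k
    val = reaction_curve([np.log(2) / 0.5], 0.8, 0.5, 0.0)[0]
    assert val == pytest.approx(0.4)


def test_double_reaction_equal_rates_collapse():
    t = np.linspace(0, 18, 100)
    two = reaction_curve(t, (0.3, 0.5), (0.4, 0.4), 0.0)
    one = reaction_curve(t, 0.8, 0.4, 0.0)
    assert np.max(np.abs(two - one)) < 1e-12


def test_reaction_diffusion_small_kon_matches_diffusion_series():
    rd = RadialReactionDiffusion(1.0, 1.5, 1.232)
    t = np.arange(0, 10, 0.06)
    q_rd = rd.curve(t, 1e-9, 1.0, 10.0)
    q_d = diffusion_curve(t, 10.0, 1.0, 1.5, 1.232)
    assert np.max(np.abs(q_rd - q_d)) < 0.01


def test_reaction_diffusion_fast_diffusion_is_single_reaction_like():
    # after the sub-frame diffusive equilibration, the recovery is a
    # single exponential in the bound-state release
    rd = RadialReactionDiffusion(1.0, 1.5, 1.232)
    t = np.arange(0, 15, 0.06)
    q = rd.curve(t, 0.3, 0.5, 5000.0)
    fit = fit_reaction(_curve(t[1:], q[1:]), 1)
    assert np.max(np.abs(fit.fitted_curve - q[1:])) < 0.01
    assert fit.parameters["k_off1"] == pytest.approx(0.5, rel=0.05)


# ----------------------------------------------------------------- fits

def test_fit_diffusion_recovers_rate():
    truth = GroundTruth(model_id="diffusion", noise_sd=0.0, K=1.0,
                        r_e=1.5, r_n=1.232,
                        rates=RateSet(k1=0, k_off=1, k2=0, k_im=0, D=10.0))
    curve = simulate_frap_curve(truth)
    fit = fit_diffusion(curve, 1.0, 1.5, 1.232)
    assert fit.parameters["D_e"] == pytest.approx(10.0, rel=0.01)


def test_fit_single_reaction_recovers_parameters():
    truth = GroundTruth(model_id="single_reaction", amplitudes=(0.7,),
                        reaction_rates=(0.5,), t0=0.0, noise_sd=0.0)
    fit = fit_reaction(simulate_frap_curve(truth), 1)
    assert fit.parameters["A1"] == pytest.approx(0.7, abs=1e-4)
    assert fit.parameters["k_off1"] == pytest.approx(0.5, abs=1e-4)
    assert fit.parameters["t0"] == pytest.approx(0.0, abs=1e-3)


def test_fit_reaction_time_shift_reparameterization():
    truth = GroundTruth(model_id="single_reaction", amplitudes=(0.7,),
                        reaction_rates=(0.5,), t0=0.0, noise_sd=0.0)
    base = fit_reaction(simulate_frap_curve(truth), 1)
    shifted = GroundTruth(model_id="single_reaction", amplitudes=(0.7,),
                          reaction_rates=(0.5,), t0=-0.5, noise_sd=0.0)
    fit = fit_reaction(simulate_frap_curve(shifted), 1)
    assert fit.parameters["k_off1"] == pytest.approx(
        base.parameters["k_off1"], rel=1e-3)
    assert fit.parameters["t0"] == pytest.approx(-0.5, abs=1e-3)


def test_double_fit_on_single_data_degenerates():
    truth = GroundTruth(model_id="single_reaction", amplitudes=(0.7,),
                        reaction_rates=(0.5,), noise_sd=0.0)
    fit = fit_reaction(simulate_frap_curve(truth), 2)
    p = fit.parameters
    amp_zero = min(p["A1"], p["A2"]) < 0.02
    rates_equal = abs(p["k_off1"] / p["k_off2"] - 1) < 0.05
    assert amp_zero or rates_equal


def test_fit_reaction_diffusion_recovers_rates():
    truth = GroundTruth(model_id="reaction_diffusion", noise_sd=0.0,
                        K=1.0, r_e=1.5, r_n=1.232,
                        rates=RateSet(k1=0.3, k_off=0.5, k2=0, k_im=0,
                                      D=5.0))
    fit = fit_reaction_diffusion(simulate_frap_curve(truth), 1.0, 1.5,
                                 1.232)
    assert fit.parameters["k_on"] == pytest.approx(0.3, rel=0.05)
    assert fit.parameters["k_off"] == pytest.approx(0.5, rel=0.05)


# ------------------------------------------------- filters and selection

@pytest.mark.parametrize("params,model,mode,plausible,reason", [
    ({"D_e": 61.0}, "diffusion", "default", False,
     "diffusion_exceeds_GFP_bound"),
    ({"D_e": 59.0}, "diffusion", "default", True, None),
    ({"A1": .5, "k_off1": 0.02, "t0": 0}, "single_reaction", "default",
     True, None),
    ({"A1": .5, "k_off1": 26.0, "t0": 0}, "single_reaction", "default",
     False, "rate_exceeds_frame_rate_bound"),
    ({"A1": .5, "k_off1": 0.005, "t0": 0}, "single_reaction", "default",
     False, "dissociation_below_detection"),
    ({"A1": .5, "k_off1": 0.005, "t0": 0}, "single_reaction", "tead",
     True, None),
])
def test_plausibility_filters(params, model, mode, plausible, reason):
    fit = ModelFit(model, params, 1.0, 100)
    out = apply_plausibility_filters(fit, mode=mode)
    assert out.plausible is plausible
    assert out.discard_reason == reason


def test_akaike_weights():
    assert np.allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])
    w = akaike_weights([10.0, 12.0])
    assert w[0] == pytest.approx(0.731, abs=1e-3)
    assert w[1] == pytest.approx(0.269, abs=1e-3)


def test_f_statistic_hand_value():
    f1 = ModelFit("single_reaction", {}, 2.0, 15)   # df = 12
    f2 = ModelFit("double_reaction", {}, 1.0, 15)   # df = 10
    F, p = nested_f_test(f1, f2)
    assert F == pytest.approx(5.0)
    assert 0 < p < 1


def test_selection_weight_invariant_to_order():
    t = np.linspace(0, 18, 301)
    truth = GroundTruth(model_id="single_reaction", amplitudes=(0.8,),
                        reaction_rates=(0.4,), noise_sd=0.01, seed=1)
    curve = simulate_frap_curve(truth)
    f1 = fit_reaction(curve, 1)
    f2 = fit_reaction(curve, 2)
    r_a = select_model([f1, f2])
    r_b = select_model([f2, f1])
    assert r_a.selected_id == r_b.selected_id
    assert r_a.selected.akaike_weight == pytest.approx(
        r_b.selected.akaike_weight)


def test_all_discarded_flags_noisy():
    fit = ModelFit("single_reaction",
                   {"A1": .5, "k_off1": 30.0, "t0": 0}, 1.0, 100)
    report = select_model([fit])
    assert report.noisy and report.selected is None


# ---------------------------------------------------------------- cohort

def test_cohort_identical_rates():
    out = summarize_cohort([0.4, 0.4, 0.4])
    assert out["median"] == 0.4


def test_cohort_noisy_placeholder_convention():
    out = summarize_cohort([0.3, 0.4, 0.5], n_noisy=2)
    assert out["median"] == 0.5           # (0.3,0.4,0.5,3.5,3.5)
    assert out["median_fitted_only"] == 0.4
    with pytest.raises(ValueError):
        summarize_cohort([], n_noisy=0)


def test_half_time_single_reaction():
    truth = GroundTruth(model_id="single_reaction", amplitudes=(0.8,),
                        reaction_rates=(0.5,), noise_sd=0.0)
    curve = simulate_frap_curve(truth)
    # S0 ~ 0, plateau ~0.8: half-recovery near ln2/k
    assert half_time(curve) == pytest.approx(np.log(2) / 0.5, rel=0.05)


# ------------------------------------------------------------ residuals

def test_selected_model_residuals_unstructured_over_seeds():
    """Runs test on residuals of the generating model: non-significant
    for at least 90% of seeds (no time trend left behind)."""
    from statsmodels.sandbox.stats.runs import runstest_1samp
    ok = 0
    for seed in range(50):
        truth = GroundTruth(model_id="single_reaction",
                            amplitudes=(0.8,), reaction_rates=(0.4,),
                            noise_sd=0.02, seed=seed)
        curve = simulate_frap_curve(truth)
        fit = fit_reaction(curve, 1)
        resid = curve.post_intensity - fit.fitted_curve
        _, p = runstest_1samp(resid, cutoff=0.0, correction=True)
        ok += p > 0.05
    assert ok >= 45
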