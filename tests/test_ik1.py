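"""Rectifier formulation, chord conductance, AP clamp and parameter fitting."""

import numpy as np
import pytest

from atrikir.ik1 import (
    GENOTYPES, IK1Params, IVCurve, chord_conductance, fit_ik1,
    genotype_params, ik1_current, nernst_potassium, simulate_ap_clamp,
)
from atrikir.synthetic import DEFAULT_IV_GRID, make_ap_waveform, make_iv_dataset

EK = nernst_potassium()


class TestCurrentFormulation:
    def test_zero_at_reversal_for_any_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = IK1Params(g_k1=rng.uniform(0, 0.5), a=rng.uniform(0, 0.3),
                          b=rng.uniform(-120, 0))
            assert ik1_current(EK, p, EK) == pytest.approx(0.0, abs=1e-12)

    def test_ohmic_limit(self):
        p = IK1Params(g_k1=1.0, a=0.0, b=-80.0)
        assert ik1_current(EK + 10.0, p, EK) == pytest.approx(10.0)
        v = np.linspace(-120, 20, 29)
        np.testing.assert_allclose(ik1_current(v, p, EK), v - EK)

    def test_continuous_in_a_at_zero(self):
        v = np.linspace(-100, 0, 21)
        p0 = IK1Params(g_k1=0.02, a=0.0, b=-80.0)
        p1 = IK1Params(g_k1=0.02, a=1e-9, b=-80.0)
        np.testing.assert_allclose(ik1_current(v, p0, EK),
                                   ik1_current(v, p1, EK), rtol=1e-6)

    def test_wt_outward_peak_position(self):
        v = np.linspace(-90, -20, 1401)
        i = ik1_current(v, genotype_params("WT"), EK)
        assert -70.0 <= v[np.argmax(i)] <= -50.0

    def test_mixture_endpoints_reproduce_components(self):
        wt = genotype_params("WT")
        mut = genotype_params("D172N")
        v = np.linspace(-110, 10, 25)
        as_wt = IK1Params(g_k1=mut.g_k1, a=mut.a, b=mut.b, mixture_weight=1.0)
        as_mut = IK1Params(g_k1=mut.g_k1, a=mut.a, b=mut.b, mixture_weight=0.0)
        np.testing.assert_allclose(ik1_current(v, as_wt, EK, wt_params=wt),
                                   ik1_current(v, wt, EK))
        np.testing.assert_allclose(ik1_current(v, as_mut, EK, wt_params=wt),
                                   ik1_current(v, mut, EK))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            IK1Params(g_k1=-0.1, a=0.05, b=-80)
        with pytest.raises(ValueError):
            IK1Params(g_k1=0.1, a=-0.05, b=-80)
        with pytest.raises(ValueError):
            IK1Params(g_k1=0.1, a=0.05, b=-80, mixture_weight=1.5)


class TestChordConductance:
    def test_ohmic_curve_constant_conductance(self):
        p = IK1Params(g_k1=2.0, a=0.0, b=-80.0)
        curve = IVCurve(DEFAULT_IV_GRID, ik1_current(DEFAULT_IV_GRID, p, EK))
        v, g = chord_conductance(curve, EK)
        np.testing.assert_allclose(g, 2.0)

    def test_wt_conductance_non_increasing_above_minus_60(self):
        curve = make_iv_dataset("WT", noise_sd=0.0)
        v, g = chord_conductance(curve, EK)
        sel = v > -60.0
        assert np.all(np.diff(g[sel]) <= 1e-12)

    def test_e299v_conductance_flat_over_physiological_range(self):
        """Homozygous E299V abolishes rectification: the chord conductance
        varies by less than 10% of its mean between -55 and 0 mV."""
        curve = make_iv_dataset("E299V", noise_sd=0.0)
        v, g = chord_conductance(curve, EK)
        sel = (v >= -55.0) & (v <= 0.0)
        assert (g[sel].max() - g[sel].min()) < 0.1 * g[sel].mean()

    def test_reversal_point_excluded(self):
        v = np.array([EK - 2.0, EK - 0.5, EK, EK + 0.5, EK + 2.0, EK + 4.0])
        curve = IVCurve(v, np.zeros_like(v))
        kept, _ = chord_conductance(curve, EK)
        assert np.all(np.abs(kept - EK) > 1.0)


class TestFitting:
    @pytest.mark.parametrize("genotype", GENOTYPES)
    def test_noiseless_recovery_to_0p1_percent(self, genotype):
        truth = genotype_params(genotype)
        curve = make_iv_dataset(genotype, noise_sd=0.0)
        res = fit_ik1(curve, EK)
        assert res.residual < 1e-8
        assert res.params.g_k1 == pytest.approx(truth.g_k1, rel=1e-3)
        if truth.a > 0:
            assert res.params.a == pytest.approx(truth.a, rel=1e-3)
            assert res.params.b == pytest.approx(truth.b, rel=1e-3)
        else:
            # ohmic template: any near-zero steepness is equivalent
            v = curve.voltages
            np.testing.assert_allclose(
                ik1_current(v, res.params, EK), curve.currents, atol=1e-5)

    def test_monte_carlo_recovery_under_noise(self):
        """Median relative parameter errors over 20 noisy datasets:
        g_k1 within 2%, steepness a within 5% (noise at 1% of the
        template's dynamic range)."""
        truth = genotype_params("WT")
        clean = make_iv_dataset("WT", noise_sd=0.0)
        sd = 0.01 * float(np.ptp(clean.currents))
        g_err, a_err = [], []
        for seed in range(20):
            curve = make_iv_dataset("WT", noise_sd=sd, seed=seed)
            res = fit_ik1(curve, EK, init=IK1Params(0.02, 0.04, -60.0))
            g_err.append(abs(res.params.g_k1 - truth.g_k1) / truth.g_k1)
            a_err.append(abs(res.params.a - truth.a) / truth.a)
        assert np.median(g_err) < 0.02
        assert np.median(a_err) < 0.05

    def test_fitted_d172n_exceeds_fitted_wt_between_m75_m45(self):
        fits = {}
        for g in ("WT", "D172N"):
            fits[g] = fit_ik1(make_iv_dataset(g, noise_sd=0.0), EK).params
        v = np.arange(-75.0, -44.9, 1.0)
        assert np.all(ik1_current(v, fits["D172N"], EK)
                      > ik1_current(v, fits["WT"], EK))

    def test_requires_data_spanning_reversal(self):
        v = np.arange(-60.0, 0.0, 5.0)
        curve = IVCurve(v, v - EK)
        with pytest.raises(ValueError):
            fit_ik1(curve, EK)


class TestAPClamp:
    def test_constant_clamp_at_reversal_gives_zero_trace(self):
        t = np.arange(0.0, 100.0, 0.5)
        v = np.full_like(t, EK)
        trace = simulate_ap_clamp(genotype_params("WT"), t, v, EK)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)

    def test_wt_peak_current_during_terminal_repolarisation(self):
        wf = make_ap_waveform(1000.0)
        trace = simulate_ap_clamp(genotype_params("WT"), wf.times,
                                  wf.voltages, EK)
        v_at_max = wf.voltages[np.argmax(trace)]
        assert -80.0 <= v_at_max <= -40.0

    def test_e299v_exceeds_wt_throughout_plateau(self):
        wf = make_ap_waveform(1000.0)
        wt = simulate_ap_clamp(genotype_params("WT"), wf.times, wf.voltages, EK)
        ev = simulate_ap_clamp(genotype_params("E299V"), wf.times,
                               wf.voltages, EK)
        plateau = wf.voltages > -30.0
        assert np.all(ev[plateau] > wt[plateau])
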