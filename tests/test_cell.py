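"""Atrial cell model: derivatives, stepping, interventions, genotype effects."""

import numpy as np
import pytest

from atrikir.cell import (
    CellParams, apply_intervention, derivatives, initial_state, pace, step,
    N_STATE, STATE_NAMES,
)
from atrikir.ik1 import IK1Params, genotype_params, ik1_current, nernst_potassium
from atrikir.protocols_cell import steady_state_biomarkers


@pytest.fixture(scope="module")
def rested_wt(wt_params):
    """WT cell left unstimulated for 20 s (quiescent steady state)."""
    rec = pace(wt_params, bcl=5000.0, n_beats=4, dt=0.01, stim_amp=0.0,
               stim_dur=1.0, record_last=1)
    return rec["state"]


class TestDerivatives:
    def test_quiescent_state_is_a_fixed_point(self, rested_wt, wt_params):
        dy, _ = derivatives(rested_wt, wt_params, i_stim=0.0)
        # voltage and gates are equilibrated; concentrations drift slowly
        assert abs(dy[0]) < 1e-3  # mV/ms
        assert np.all(np.abs(dy[1:16]) < 1e-6)
        assert np.all(np.abs(dy[16:]) < 1e-4)  # mM/ms

    def test_rate_is_linear_in_stimulus(self, rested_wt, wt_params):
        dy0, _ = derivatives(rested_wt, wt_params, i_stim=0.0)
        dy1, _ = derivatives(rested_wt, wt_params, i_stim=7.5)
        # positive stimulus depolarises: dV/dt rises by exactly I (pA/pF)
        assert dy1[0] - dy0[0] == pytest.approx(7.5, rel=1e-12)
        # the stimulus charge is booked to K+; every other rate is untouched
        assert dy1[17] - dy0[17] == pytest.approx(
            7.5 * 100.0 / (96.4867 * 13668.0), rel=1e-9)
        others = [k for k in range(N_STATE) if k not in (0, 17)]
        np.testing.assert_allclose(dy1[others], dy0[others], rtol=0, atol=1e-15)

    def test_traced_ik1_matches_standalone_formulation(self, wt_params):
        ek = nernst_potassium(k_in=139.0)
        for v in (-80.0, -60.0, -40.0, 0.0, 20.0):
            y = initial_state()
            y[0] = v
            y[17] = 139.0
            _, cur = derivatives(y, wt_params)
            expected = ik1_current(v, wt_params.ik1, ek)
            assert cur["I_K1"] == pytest.approx(expected, rel=1e-9)

    def test_nan_state_flags_blow_up(self, wt_params):
        y = initial_state()
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            derivatives(y, wt_params)


class TestStepping:
    def test_gate_relaxes_exponentially_under_voltage_clamp(self, wt_params):
        """With V clamped, each gate approaches its steady state as
        exp(-t/tau): after t >> tau the residual is below 1e-6."""
        from atrikir.cell import _vgate_coeffs, N_VGATE

        inf = np.empty(N_VGATE)
        tau = np.empty(N_VGATE)
        _vgate_coeffs(-30.0, inf, tau)
        y0 = initial_state()
        y = y0.copy()
        y[0] = -30.0
        t_clamp, dt = 100.0, 0.005
        for _ in range(int(t_clamp / dt)):
            y = step(y, dt, wt_params)
            y[0] = -30.0
        for g in range(N_VGATE):
            residual = abs(y[1 + g] - inf[g])
            bound = abs(y0[1 + g] - inf[g]) * np.exp(-t_clamp / tau[g]) + 1e-9
            assert residual <= bound + 1e-6 or t_clamp < 5 * tau[g], g
            if t_clamp > 14 * tau[g]:  # fully relaxed gates hit steady state
                assert residual < 1e-6, g

    def test_dt_convergence_of_apd90(self, wt_params):
        apds = []
        for dt in (0.01, 0.005):
            bm, _ = steady_state_biomarkers(wt_params, n_beats=10, dt=dt)
            apds.append(bm.apd90)
        assert abs(apds[0] - apds[1]) < 1.0  # ms

    def test_dt_precondition_enforced(self, wt_params):
        with pytest.raises(ValueError):
            step(initial_state(), 0.05, wt_params)

    def test_paced_limit_cycle_is_periodic(self, wt_params):
        """At the paced limit cycle the state returns to itself each beat
        (net transmembrane charge per cycle ~ 0)."""
        rec = pace(wt_params, bcl=1000.0, n_beats=50, dt=0.005, record_last=2)
        t, v = rec["t"], rec["V"]
        first, second = v[t < 1000.0], v[t >= 1000.0]
        n = min(first.size, second.size)
        assert np.max(np.abs(first[:n] - second[:n])) < 0.5  # mV


class TestInterventions:
    def test_identity_leaves_parameters_unchanged(self, wt_params):
        out = apply_intervention(wt_params, {"I_Kr": 1.0, "I_CaL": 1.0})
        assert out == wt_params

    def test_kr_kur_half_block(self, wt_params):
        out = apply_intervention(wt_params, {"I_Kr": 0.5, "I_Kur": 0.5})
        assert out.g_kr == pytest.approx(0.5 * wt_params.g_kr)
        assert out.g_kur == pytest.approx(0.5 * wt_params.g_kur)
        assert out.g_cal == wt_params.g_cal
        assert wt_params.g_kr == pytest.approx(0.029411765)  # original intact

    def test_cal_agonism_250_percent(self, wt_params):
        out = apply_intervention(wt_params, {"I_CaL": 3.5})
        assert out.g_cal == pytest.approx(3.5 * wt_params.g_cal)

    def test_unknown_current_rejected(self, wt_params):
        with pytest.raises(ValueError, match="unknown current"):
            apply_intervention(wt_params, {"I_Kx": 0.5})

    def test_composition_commutes(self, wt_params):
        a = apply_intervention(apply_intervention(wt_params, {"I_Kr": 0.5}),
                               {"I_CaL": 2.0})
        b = apply_intervention(apply_intervention(wt_params, {"I_CaL": 2.0}),
                               {"I_Kr": 0.5})
        np.testing.assert_allclose(a.to_vector(), b.to_vector())


class TestGenotypes:
    def test_apd90_ordering_across_genotypes(self, fitted_genotype_biomarkers):
        bm = fitted_genotype_biomarkers
        assert (bm["WT"].apd90 > bm["WT-D172N"].apd90 > bm["D172N"].apd90
                > bm["WT-E299V"].apd90 > bm["E299V"].apd90)

    def test_d172n_hyperpolarises_resting_potential(self,
                                                    fitted_genotype_biomarkers):
        bm = fitted_genotype_biomarkers
        assert bm["D172N"].rmp < bm["WT-D172N"].rmp < bm["WT"].rmp

    def test_removing_ik1_depolarises_rmp(self, wt_params):
        no_k1 = apply_intervention(wt_params, {"I_K1": 0.0})
        bm_wt, _ = steady_state_biomarkers(wt_params, n_beats=20, dt=0.01)
        bm_no, _ = steady_state_biomarkers(no_k1, n_beats=20, dt=0.01)
        assert bm_no.rmp > bm_wt.rmp + 5.0
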