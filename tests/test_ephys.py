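"""Passive-fit, IV/Boltzmann and AP-waveform feature extraction."""

import numpy as np
import pytest

from tauhcn import ephys
from tauhcn.simulate import NeuronParams, simulate_neuron
from tauhcn.traces import StepProtocol, Trace

from conftest import make_voltage_trace


# ---------------------------------------------------------------------- Vj

@pytest.mark.parametrize("vj,expected", [(15.0, -80.0), (0.0, -65.0)])
def test_junction_correction_shifts_by_minus_vj(vj, expected):
    tr = make_voltage_trace(np.full(2000, -65.0))
    out = ephys.correct_junction_potential(tr, Vj=vj)
    assert np.allclose(out.samples, expected)
    assert out.junction_corrected


def test_junction_correction_rejects_double_correction():
    tr = make_voltage_trace(np.full(2000, -65.0))
    out = ephys.correct_junction_potential(tr)
    with pytest.raises(ValueError):
        ephys.correct_junction_potential(out)


# ------------------------------------------------------------- passive fit

def _exp_step_trace(A=-15.0, C=None, V0=-80.0, tau=12.0, dt=0.05,
                    proto=StepProtocol()):
    """Synthetic step response; if C is given, superimpose an early dip so
    the within-step minimum deflection is exactly C."""
    t = np.arange(0, proto.offset + 300.0 + dt, dt)
    v = np.full_like(t, V0)
    sel = (t >= proto.onset) & (t < proto.offset)
    ts = t[sel] - proto.onset
    defl = A * (1.0 - np.exp(-ts / tau))
    if C is not None:
        # add a transient reaching exactly C at its trough
        trough = C - A * (1.0 - np.exp(-120.0 / tau))
        defl = defl + trough * np.exp(-0.5 * ((ts - 120.0) / 25.0) ** 2)
    v[sel] += defl
    return Trace(dt=dt, samples=v, unit="mV", protocol=proto)


def test_pure_exponential_has_zero_sag():
    fit = ephys.fit_passive_response(_exp_step_trace())
    assert fit.sag_sub == pytest.approx(0.0, abs=0.2)
    assert fit.sag_fit == pytest.approx(0.0, abs=0.2)
    assert fit.A == pytest.approx(-15.0, abs=0.05)
    assert fit.tau_m == pytest.approx(12.0, rel=0.02)


def test_sag_sub_formula_printed_example():
    """V0 = -80, minimum -100 (C = -20), steady -95 (A = -15):
    sag_sub = 100*(C - A)/C = 25 %."""
    fit = ephys.fit_passive_response(_exp_step_trace(A=-15.0, C=-20.0))
    assert fit.C == pytest.approx(-20.0, abs=0.05)
    assert fit.A == pytest.approx(-15.0, abs=0.05)
    assert fit.sag_sub == pytest.approx(25.0, abs=0.3)


def test_input_resistance_recovers_leak_on_passive_cell(step_protocol):
    """R_in from the passive fit equals 1/g_L within 1 %."""
    tr = simulate_neuron(NeuronParams(g_h=0.0, g_L=10.0), step_protocol)
    fit = ephys.fit_passive_response(tr)
    assert fit.R_in == pytest.approx(100.0, rel=0.01)


def test_sag_invariant_under_baseline_shift(step_protocol):
    """Deflections are baseline-relative: shifting the whole trace moves V0
    but leaves sag measures unchanged."""
    tr = simulate_neuron(NeuronParams(g_h=5.0), step_protocol)
    fit0 = ephys.fit_passive_response(tr)
    shifted = tr.copy_with(samples=tr.samples + 13.0)
    fit1 = ephys.fit_passive_response(shifted)
    assert fit1.V0 == pytest.approx(fit0.V0 + 13.0, abs=1e-9)
    assert fit1.sag_sub == pytest.approx(fit0.sag_sub, abs=1e-9)
    assert fit1.sag_fit == pytest.approx(fit0.sag_fit, abs=1e-9)


def test_passive_fit_against_fine_grid_oracle(step_protocol):
    """A/B/C/tau_m from the dt = 0.05 ms pipeline agree within 2 % with the
    quantities extracted from a dt = 0.005 ms reference simulation by
    exhaustive extremum search."""
    p = NeuronParams(g_h=4.0)
    fit = ephys.fit_passive_response(simulate_neuron(p, step_protocol))

    fine = simulate_neuron(p, step_protocol, dt=0.005)
    t, v = fine.time_ms, fine.samples
    V0 = v[(t >= step_protocol.onset - 50.0) & (t < step_protocol.onset)].mean()
    sel = (t >= step_protocol.onset) & (t < step_protocol.offset)
    defl = v[sel] - V0
    C_ref = defl.min()
    A_ref = defl[t[sel] >= step_protocol.offset - 100.0].mean()
    assert fit.C == pytest.approx(C_ref, rel=0.02)
    assert fit.A == pytest.approx(A_ref, rel=0.02)
    assert fit.fit_converged and fit.B <= fit.C <= 0  # B beyond the observed minimum
    assert fit.sag_fit > fit.sag_sub > 0


def test_passive_fit_requires_hyperpolarizing_step():
    tr = _exp_step_trace()
    with pytest.raises(ValueError):
        ephys.fit_passive_response(tr, StepProtocol(step_amp=0.0))
    with pytest.raises(ValueError):
        ephys.fit_passive_response(tr, StepProtocol(step_amp=100.0))


# ----------------------------------------------------------------- IV fit

BOLTZ = lambda v, gmax, vh, k: gmax / (1.0 + np.exp(-(v - vh) / k))


def _iv_currents(gmax=0.5, vh=-30.0, k=8.0, C_m=100.0, g_leak=2.0,
                 E_leak=-70.0):
    V = np.arange(-90.0, 21.0, 10.0)
    return V, g_leak * (V - E_leak) + BOLTZ(V, gmax, vh, k) * 100.0 * C_m


def test_boltzmann_recovered_exactly_from_noiseless_currents():
    """With the leak known exactly, noiseless Boltzmann currents invert to
    machine precision; with the leak estimated from the two most negative
    steps (where a little channel current persists), recovery is still
    within a fraction of a percent."""
    V, I = _iv_currents()
    res = ephys.analyze_iv(I, V, C_m_est=100.0, known_leak=(2.0, -70.0))
    assert not res.flagged
    assert res.G_max == pytest.approx(0.5, abs=1e-8)
    assert res.V_half == pytest.approx(-30.0, abs=1e-6)
    assert res.slope_k == pytest.approx(8.0, abs=1e-6)

    est = ephys.analyze_iv(I, V, C_m_est=100.0)
    assert est.G_max == pytest.approx(0.5, rel=0.02)
    assert est.V_half == pytest.approx(-30.0, abs=1.0)


def test_boltzmann_fit_is_scale_equivariant():
    V, I = _iv_currents(g_leak=0.0)
    r1 = ephys.analyze_iv(I, V, C_m_est=100.0)
    r2 = ephys.analyze_iv(3.0 * I, V, C_m_est=100.0)
    assert r2.G_max == pytest.approx(3.0 * r1.G_max, rel=1e-6)
    assert r2.V_half == pytest.approx(r1.V_half, abs=1e-6)
    assert r2.slope_k == pytest.approx(r1.slope_k, abs=1e-6)


def test_pure_ohmic_input_is_flagged():
    V = np.arange(-90.0, 21.0, 10.0)
    I = 2.0 * (V + 70.0)
    res = ephys.analyze_iv(I, V, C_m_est=100.0)
    assert res.flagged
    assert np.allclose(res.specific_currents, 0.0, atol=1e-9)


def test_vhalf_recovery_under_multiplicative_noise(rng):
    """Median |V_half error| < 2 mV across 100 noisy realisations (5 %
    multiplicative noise), matching the Monte-Carlo design tolerance."""
    V, I = _iv_currents()
    errs = []
    for _ in range(100):
        noisy = I * rng.normal(1.0, 0.05, size=I.size)
        res = ephys.analyze_iv(noisy, V, C_m_est=100.0)
        if not res.flagged:
            errs.append(abs(res.V_half - (-30.0)))
    assert np.median(errs) < 2.0


def test_analyze_iv_validates_inputs():
    V = np.arange(-90.0, -60.0, 10.0)
    with pytest.raises(ValueError):
        ephys.analyze_iv(np.zeros(3), V, C_m_est=100.0)


# ----------------------------------------------------------------- AP stats

def test_gaussian_spike_width_matches_analytic_fwhm():
    """For a Gaussian bump the width at the half level between threshold and
    peak has a closed form; measured width must match it."""
    dt = 0.01
    t = np.arange(0, 500, dt)
    base, amp, sigma = -60.0, 100.0, 0.4
    v = base + amp * np.exp(-0.5 * ((t - 250.0) / sigma) ** 2)
    tr = Trace(dt=dt, samples=v, unit="mV",
               protocol=StepProtocol(step_amp=300.0, onset=0.0, duration=500.0))
    st = ephys.analyze_ap(tr)
    assert st is not None
    half = 0.5 * (st.threshold + st.peak)
    width_true = 2.0 * sigma * np.sqrt(2.0 * np.log(amp / (half - base)))
    assert st.width == pytest.approx(width_true, rel=0.02)
    assert st.peak == pytest.approx(base + amp, abs=1e-6)


def test_max_rise_agrees_with_centered_difference_oracle(rng):
    dt = 0.02
    t = np.arange(0, 500, dt)
    v = -60.0 + 90.0 * np.exp(-0.5 * ((t - 200.0) / 0.5) ** 2)
    tr = Trace(dt=dt, samples=v, unit="mV",
               protocol=StepProtocol(step_amp=300.0, onset=0.0, duration=500.0))
    st = ephys.analyze_ap(tr)
    oracle = np.max((v[2:] - v[:-2]) / (2 * dt))
    assert st.max_rise == pytest.approx(oracle, rel=1e-6)


def test_no_spike_returns_none():
    tr = make_voltage_trace(np.full(4000, -70.0))
    assert ephys.analyze_ap(tr) is None
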