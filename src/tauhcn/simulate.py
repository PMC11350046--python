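"""Single-compartment conductance-based neuron with an h-current.

The model is a leaky membrane plus a hyperpolarization-activated mixed
cation conductance (HCN-type, carrying I_h) and an optional non-inactivating
potassium conductance:

    C_m dV/dt = -g_L (V - E_L) - g_h m (V - E_h) - g_K n (V - E_K) + I_inj(t)

with first-order gating

    dm/dt = (m_inf(V) - m) / tau_h,   m_inf(V) = 1 / (1 + exp((V - V_half_h) / k_h))

so that m grows on hyperpolarization (k_h > 0), and n the mirror image for
the depolarization-activated potassium conductance.  During a hyperpolarizing
current step the slowly activating inward I_h pulls the voltage back up from
its early minimum toward a less negative steady state ("sag") and produces a
depolarizing overshoot after step offset ("rebound") — the two signatures the
feature extractor quantifies.

Integration is fixed-step classical Runge-Kutta (RK4, default dt = 0.05 ms):
deterministic and comfortably accurate for gating time constants of tens to
hundreds of milliseconds.  A holding current is solved for so the
pre-stimulus membrane voltage sits exactly at the protocol's holding target,
mirroring the constant-current holding used in the recordings this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .traces import StepProtocol, Trace

__all__ = ["NeuronParams", "IntegrationError", "simulate_neuron", "holding_current"]


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters (pF, nS, mV, ms)."""

    C_m: float = 100.0      # membrane capacitance, pF
    g_L: float = 10.0       # leak conductance, nS
    E_L: float = -80.0      # leak reversal, mV
    g_h: float = 2.0        # maximal h-conductance, nS
    E_h: float = -30.0      # h-current reversal, mV
    V_half_h: float = -82.0 # h-gate half-activation, mV
    k_h: float = 7.0        # h-gate slope, mV (>0: opens on hyperpolarization)
    tau_h: float = 100.0    # h-gate time constant, ms
    g_K: float = 0.0        # non-inactivating K conductance, nS
    E_K_rev: float = -100.0 # K reversal, mV
    V_half_K: float = -30.0 # K-gate half-activation, mV
    k_K: float = 10.0       # K-gate slope, mV (opens on depolarization)
    tau_K: float = 5.0      # K-gate time constant, ms
    noise_sd: float = 0.0   # additive recording noise on V, mV

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be positive")
        if self.g_h < 0 or self.g_K < 0:
            raise ValueError("conductances must be non-negative")
        if self.k_h <= 0 or self.tau_h <= 0:
            raise ValueError("k_h and tau_h must be positive")

    def m_inf(self, V: float) -> float:
        return 1.0 / (1.0 + np.exp((V - self.V_half_h) / self.k_h))

    def n_inf(self, V: float) -> float:
        return 1.0 / (1.0 + np.exp(-(V - self.V_half_K) / self.k_K))


class IntegrationError(RuntimeError):
    """Raised when the membrane-state integration diverges."""


def _steady_current(p: NeuronParams, V: float) -> float:
    """Injected current (pA) needed to hold V at steady state."""
    return (
        p.g_L * (V - p.E_L)
        + p.g_h * p.m_inf(V) * (V - p.E_h)
        + p.g_K * p.n_inf(V) * (V - p.E_K_rev)
    )


def holding_current(params: NeuronParams, V_target: float) -> float:
    """Constant current (pA) that clamps the resting voltage at ``V_target``."""
    return _steady_current(params, V_target)


def _resting_potential(p: NeuronParams, I_hold: float) -> float:
    f = lambda V: I_hold - _steady_current(p, V)
    return brentq(f, -150.0, 50.0, xtol=1e-10)


def simulate_neuron(
    params: NeuronParams,
    protocol: StepProtocol,
    seed: int | None = None,
    dt: float = 0.05,
    post_ms: float = 300.0,
) -> Trace:
    """Integrate the current-clamp response to a square current step.

    The injected current is a constant holding term (solved so the
    pre-stimulus voltage equals ``protocol.holding_target``) plus
    ``protocol.step_amp`` pA between onset and offset.  The returned trace
    covers ``onset + duration + post_ms`` and carries the ground-truth
    parameters in ``meta``.
    """
    if dt <= 0 or dt > 0.05:
        raise ValueError("integration step must satisfy 0 < dt <= 0.05 ms")
    p = params
    I_hold = holding_current(p, protocol.holding_target)

    n_total = int(round((protocol.onset + protocol.duration + post_ms) / dt)) + 1
    t = np.arange(n_total) * dt
    in_step = (t >= protocol.onset) & (t < protocol.offset)
    I_inj = I_hold + np.where(in_step, protocol.step_amp, 0.0)

    V = protocol.holding_target
    m = p.m_inf(V)
    n = p.n_inf(V)
    out = np.empty(n_total)
    out[0] = V

    def deriv(V, m, n, I):
        dV = (
            -p.g_L * (V - p.E_L)
            - p.g_h * m * (V - p.E_h)
            - p.g_K * n * (V - p.E_K_rev)
            + I
        ) / p.C_m
        dm = (p.m_inf(V) - m) / p.tau_h
        dn = (p.n_inf(V) - n) / p.tau_K
        return dV, dm, dn

    for i in range(1, n_total):
        # injected current is piecewise constant; use the value on [t_i-1, t_i)
        I = I_inj[i - 1]
        k1 = deriv(V, m, n, I)
        k2 = deriv(V + 0.5 * dt * k1[0], m + 0.5 * dt * k1[1], n + 0.5 * dt * k1[2], I)
        k3 = deriv(V + 0.5 * dt * k2[0], m + 0.5 * dt * k2[1], n + 0.5 * dt * k2[2], I)
        k4 = deriv(V + dt * k3[0], m + dt * k3[1], n + dt * k3[2], I)
        V = V + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m = m + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        n = n + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if not (np.isfinite(V) and np.isfinite(m) and np.isfinite(n)):
            raise IntegrationError(
                f"membrane state diverged at step {i} (t = {i * dt:.3f} ms)"
            )
        out[i] = V

    if p.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, p.noise_sd, size=out.shape)

    meta = {
        "kind": "current-clamp-step",
        "params": {k: getattr(p, k) for k in p.__dataclass_fields__},
        "I_hold_pA": I_hold,
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
    }
    return Trace(dt=dt, samples=out, unit="mV", protocol=protocol, meta=meta)
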