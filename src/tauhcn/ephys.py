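"""Passive properties, sag, rebound, conductance activation and AP metrics.

Conventions for the hyperpolarizing-step analysis (all deflections are
baseline-relative, in mV):

* ``V0``    mean voltage over the 50 ms immediately before step onset;
* ``C``     the most negative deflection reached within the step;
* ``A``     mean deflection over the last 20 % of the step (steady state);
* ``B``     asymptotic deflection of a single-exponential fit
            ``V(t) - V0 = B (1 - exp(-(t - onset)/tau_m))`` restricted to the
            initial falling phase where the deflection lies between 10 % and
            90 % of C;
* ``sag_sub = 100 (C - A) / C`` and ``sag_fit = 100 (B - A) / B`` (%);
* ``R_in  = A / step_amp`` (mV/pA = GΩ, reported in MΩ);
* ``rebound`` max voltage above baseline in the 200 ms after step offset.

The current-voltage analysis follows the outward non-inactivating potassium
protocol: a 12-step, 10 mV family from -90 mV, ohmic leak estimated on the
two most hyperpolarized steps, currents normalised to membrane capacitance,
and the specific conductance G = I_specific / 100 mV (a fixed potassium
driving force; a physical per-step V - E_K variant is available behind a
flag) fitted with a Boltzmann sigmoid G(V) = G_max / (1 + exp(-(V - V_half)/k)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .traces import StepProtocol, Trace

__all__ = [
    "PassiveFit",
    "IVResult",
    "APStats",
    "correct_junction_potential",
    "fit_passive_response",
    "analyze_iv",
    "analyze_ap",
]

DEFAULT_VJ = 15.0  # liquid junction potential, mV

BASELINE_MS = 50.0      # pre-onset window for V0
STEADY_FRACTION = 0.2   # last fraction of the step averaged for A
REBOUND_MS = 200.0      # post-offset window for rebound
AP_DVDT_THRESHOLD = 20.0  # mV/ms, spike threshold criterion


@dataclass(frozen=True)
class PassiveFit:
    V0: float
    A: float
    B: float
    C: float
    tau_m: float
    R_in: float
    sag_sub: float
    sag_fit: float
    rebound: float
    fit_converged: bool = True


@dataclass(frozen=True)
class IVResult:
    step_voltages: np.ndarray
    leak_conductance: float   # nS
    leak_reversal: float      # mV
    specific_currents: np.ndarray  # pA/pF
    G: np.ndarray             # nS/pF
    G_max: float
    V_half: float
    slope_k: float
    flagged: bool = False


@dataclass(frozen=True)
class APStats:
    peak: float
    threshold: float
    max_rise: float
    width: float
    n_spikes: int


def correct_junction_potential(trace: Trace, Vj: float = DEFAULT_VJ) -> Trace:
    """Shift a voltage trace by -Vj (arithmetic junction-potential correction)."""
    if trace.unit != "mV":
        raise ValueError("junction correction applies to voltage traces")
    if trace.junction_corrected:
        raise ValueError("trace is already junction-corrected")
    return trace.copy_with(samples=trace.samples - Vj, junction_corrected=True)


def fit_passive_response(trace: Trace, protocol: StepProtocol | None = None) -> PassiveFit:
    """Extract passive properties, sag and rebound from a hyperpolarizing step."""
    if protocol is None:
        if not isinstance(trace.protocol, StepProtocol):
            raise ValueError("trace carries no step protocol")
        protocol = trace.protocol
    if protocol.step_amp == 0:
        raise ValueError("step amplitude must be non-zero")
    if protocol.step_amp > 0:
        raise ValueError("passive fit expects a hyperpolarizing (negative) step")
    if protocol.onset < BASELINE_MS:
        raise ValueError(f"need >= {BASELINE_MS} ms of baseline before onset")

    t = trace.time_ms
    v = trace.samples
    base = (t >= protocol.onset - BASELINE_MS) & (t < protocol.onset)
    V0 = float(v[base].mean())

    in_step = (t >= protocol.onset) & (t < protocol.offset)
    step_t = t[in_step]
    step_v = v[in_step] - V0

    i_min = int(np.argmin(step_v))
    C = float(step_v[i_min])

    steady = step_t >= protocol.offset - STEADY_FRACTION * protocol.duration
    A = float(step_v[steady].mean())

    # exponential fit on the initial falling phase, deflection in [0.10 C, 0.90 C]
    fall_t = step_t[: i_min + 1]
    fall_v = step_v[: i_min + 1]
    band = (fall_v <= 0.10 * C) & (fall_v >= 0.90 * C)
    B = np.nan
    tau_m = np.nan
    converged = False
    if band.sum() >= 3:
        tt = fall_t[band] - protocol.onset
        vv = fall_v[band]
        model = lambda t, B, tau: B * (1.0 - np.exp(-t / tau))
        try:
            (B, tau_m), _ = curve_fit(
                model, tt, vv, p0=(C, max(tt[-1] / 2.0, trace.dt)), maxfev=10000
            )
            converged = np.isfinite(B) and np.isfinite(tau_m) and tau_m > 0
        except RuntimeError:
            converged = False

    sag_sub = 0.0 if C == 0 else 100.0 * (C - A) / C
    sag_fit = 100.0 * (B - A) / B if converged and B != 0 else np.nan

    # mV / pA = GΩ; report MΩ
    R_in = float(A / protocol.step_amp * 1000.0)

    after = (t >= protocol.offset) & (t < protocol.offset + REBOUND_MS)
    rebound = float(np.max(v[after]) - V0) if after.any() else np.nan

    return PassiveFit(
        V0=V0, A=A, B=float(B), C=C, tau_m=float(tau_m), R_in=R_in,
        sag_sub=float(sag_sub), sag_fit=float(sag_fit), rebound=rebound,
        fit_converged=converged,
    )


def analyze_iv(
    steady_currents: np.ndarray,
    step_voltages: np.ndarray,
    C_m_est: float,
    fixed_driving_force: float | None = 100.0,
    E_K: float = -100.0,
    known_leak: tuple[float, float] | None = None,
) -> IVResult:
    """Leak-subtracted Boltzmann activation fit of an outward-current family.

    Parameters
    ----------
    steady_currents : pA, one steady-state current per voltage step.
    step_voltages : mV, typically -90 ... +20 in 10 mV increments (12 steps).
    C_m_est : membrane capacitance estimate, pF.
    fixed_driving_force : mV.  When set (default 100 mV) the specific
        conductance is I_specific / fixed_driving_force at every step; pass
        ``None`` to use the per-step physical driving force V - E_K instead.
    known_leak : optional ``(conductance nS, reversal mV)``.  When provided
        (e.g. from generator metadata) it is subtracted exactly; otherwise
        an ohmic leak is estimated from the two most hyperpolarized steps,
        where the channels are assumed closed.
    """
    I = np.asarray(steady_currents, dtype=float)
    V = np.asarray(step_voltages, dtype=float)
    if I.shape != V.shape:
        raise ValueError("currents and voltages must align")
    if I.size < 4:
        raise ValueError("need at least 4 usable voltage steps")
    if C_m_est <= 0:
        raise ValueError("capacitance must be positive")

    order = np.argsort(V)
    V, I = V[order], I[order]

    if known_leak is not None:
        g_leak, E_leak = known_leak
    else:
        # ohmic leak from the two most hyperpolarized steps (channels
        # assumed closed there)
        g_leak = (I[1] - I[0]) / (V[1] - V[0])          # nS (pA/mV)
        E_leak = V[0] - I[0] / g_leak if g_leak != 0 else V[0]
    I_leak = g_leak * (V - E_leak) if g_leak != 0 else np.zeros_like(V)

    I_spec = (I - I_leak) / C_m_est                     # pA/pF
    if fixed_driving_force is not None:
        drive = np.full_like(V, float(fixed_driving_force))
    else:
        drive = V - E_K
        keep = np.abs(drive) > 5.0  # avoid the reversal-potential singularity
        V, I_spec, drive = V[keep], I_spec[keep], drive[keep]
    G = I_spec / drive                                  # nS/pF

    if np.allclose(G, 0.0, atol=1e-9):
        # nothing but leak: no activating conductance to fit
        return IVResult(
            step_voltages=V, leak_conductance=float(g_leak),
            leak_reversal=float(E_leak), specific_currents=I_spec, G=G,
            G_max=np.nan, V_half=np.nan, slope_k=np.nan, flagged=True,
        )

    boltzmann = lambda v, gmax, vhalf, k: gmax / (1.0 + np.exp(-(v - vhalf) / k))
    flagged = False
    try:
        span = max(G.max() - min(G.min(), 0.0), 1e-12)
        (G_max, V_half, slope_k), _ = curve_fit(
            boltzmann, V, G, p0=(span, float(np.median(V)), 10.0), maxfev=20000
        )
    except RuntimeError:
        G_max, V_half, slope_k = np.nan, np.nan, np.nan
        flagged = True
    if not flagged and (not np.isfinite(G_max) or G_max <= 0):
        flagged = True

    return IVResult(
        step_voltages=V, leak_conductance=float(g_leak), leak_reversal=float(E_leak),
        specific_currents=I_spec, G=G, G_max=float(G_max), V_half=float(V_half),
        slope_k=float(slope_k), flagged=flagged,
    )


def analyze_ap(trace: Trace, protocol: StepProtocol | None = None) -> APStats | None:
    """Waveform metrics of the first evoked action potential.

    Threshold is the voltage at the first crossing of dV/dt >= 20 mV/ms;
    width is the time spent above the half level (threshold + peak)/2.
    Returns ``None`` when no spike is found (not an error).
    """
    if protocol is None and isinstance(trace.protocol, StepProtocol):
        protocol = trace.protocol
    t = trace.time_ms
    v = trace.samples
    if protocol is not None:
        sel = (t >= protocol.onset) & (t < protocol.offset)
        t, v = t[sel], v[sel]
    if v.size < 3:
        return None

    dvdt = np.gradient(v, trace.dt)
    above = np.flatnonzero(dvdt >= AP_DVDT_THRESHOLD)
    if above.size == 0:
        return None
    i_thr = int(above[0])
    threshold = float(v[i_thr])
    i_peak = i_thr + int(np.argmax(v[i_thr:]))
    peak = float(v[i_peak])
    max_rise = float(dvdt[i_thr:].max())

    half = 0.5 * (threshold + peak)
    above_half = v >= half
    # width of the contiguous supra-half segment containing the peak
    i0 = i_peak
    while i0 > 0 and above_half[i0 - 1]:
        i0 -= 1
    i1 = i_peak
    while i1 < v.size - 1 and above_half[i1 + 1]:
        i1 += 1
    width = float((i1 - i0) * trace.dt)

    # count spikes as upward threshold-crossing runs of dV/dt
    runs = np.flatnonzero(np.diff((dvdt >= AP_DVDT_THRESHOLD).astype(int)) == 1).size
    n_spikes = max(1, runs)

    return APStats(peak=peak, threshold=threshold, max_rise=max_rise,
                   width=width, n_spikes=n_spikes)
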