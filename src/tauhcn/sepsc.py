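"""Template-matching detection and kinetics of spontaneous EPSCs.

Detection uses a scaled-template (Clements–Bekkers-style) criterion: at every
offset the template is fitted to the trace by optimal scale and baseline
offset, and the detection criterion is the fitted scale divided by its
standard error.  Events are declared at local maxima of the criterion above
threshold, separated by at least a refractory gap, and then screened by a
deterministic amplitude filter (fitted amplitude at least three times the
robust noise SD, estimated from the median absolute deviation of the
first-differenced trace) — a reproducible stand-in for the manual
false-positive check used with interactive analysis software.

All rolling sums are computed with FFT correlation, so 30 s gap-free traces
at 10 kHz are processed in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .traces import Trace

__all__ = [
    "Template",
    "EventList",
    "WaveformStats",
    "biexp_kernel",
    "make_template",
    "detect_events",
    "average_events",
    "waveform_stats",
]

DEFAULT_THRESHOLD = 4.0   # detection-criterion threshold
REFRACTORY_MS = 5.0       # minimum separation between detected events
AMPLITUDE_SD_FACTOR = 3.0 # fitted |amplitude| must exceed this x noise SD
DEFAULT_WINDOW_MS = 50.0  # event-average snippet length


def biexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float,
                 amp: float = 1.0) -> np.ndarray:
    """Biexponential synaptic kernel with peak value ``amp`` (pA).

    k(t) = a (exp(-t/tau_decay) - exp(-t/tau_rise)), with ``a`` chosen so the
    extremum equals ``amp``; negative ``amp`` gives an inward current.
    """
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=float)
    t_peak = kernel_peak_time(tau_rise, tau_decay)
    shape_peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = amp / shape_peak * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise))
    out[t < 0] = 0.0
    return out


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the biexponential extremum (closed form)."""
    return (np.log(tau_decay / tau_rise) * tau_rise * tau_decay
            / (tau_decay - tau_rise))


@dataclass(frozen=True)
class Template:
    """Unit-peak inward-negative detection template sampled at the trace dt."""

    tau_rise: float
    tau_decay: float
    dt: float
    length_ms: float = 30.0
    samples: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.samples is None:
            t = np.arange(int(round(self.length_ms / self.dt)) + 1) * self.dt
            object.__setattr__(
                self, "samples", biexp_kernel(t, self.tau_rise, self.tau_decay, -1.0)
            )


def make_template(tau_rise: float = 0.8, tau_decay: float = 4.0,
                  dt: float = 0.1, length_ms: float = 30.0) -> Template:
    return Template(tau_rise=tau_rise, tau_decay=tau_decay, dt=dt,
                    length_ms=length_ms)


@dataclass
class EventList:
    times_ms: np.ndarray          # detection (template onset) times, sorted
    amplitudes: np.ndarray        # fitted scale, pA (negative = inward)
    criterion: np.ndarray         # detection-criterion value per event
    duration_ms: float

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.size > 1 and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times_ms.size


@dataclass(frozen=True)
class WaveformStats:
    frequency: float     # Hz
    amplitude: float     # pA, absolute value of the mean-event peak
    half_width: float    # ms
    rate_of_rise: float  # pA/ms
    n_events: int


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the MAD of first differences (insensitive to events)."""
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def detect_events(trace: Trace, template: Template,
                  threshold: float = DEFAULT_THRESHOLD,
                  refractory_ms: float = REFRACTORY_MS) -> EventList:
    """Run the scaled-template search over a gap-free current trace."""
    if trace.unit != "pA":
        raise ValueError("event detection expects a current trace (pA)")
    if abs(template.dt - trace.dt) > 1e-9:
        raise ValueError("template must be sampled at the trace dt")
    y = trace.samples
    w = template.samples
    N = w.size
    if N > y.size:
        raise ValueError("template longer than trace")

    # Rolling least-squares fit y ~ s*w + c over each window of length N.
    ones = np.ones(N)
    Sy = fftconvolve(y, ones[::-1], mode="valid")
    Syy = fftconvolve(y * y, ones[::-1], mode="valid")
    Swy = fftconvolve(y, w[::-1], mode="valid")
    Sw = w.sum()
    Sww = float(w @ w)

    denom = Sww - Sw * Sw / N
    scale = (Swy - Sw * Sy / N) / denom
    sse = Syy - Sy * Sy / N - scale * scale * denom
    sse = np.maximum(sse, 0.0)
    # floor the standard error so a perfect (noise-free) match yields a
    # large finite criterion instead of 0/0
    se_scale = np.maximum(np.sqrt(sse / (N - 2) / denom), 1e-9)
    crit = scale / se_scale

    # local maxima of the criterion above threshold (inward events: scale < 0
    # with a negative-going template gives positive scale; template is
    # negative-peaked so inward events produce scale > 0)
    above = crit > threshold
    idx = np.flatnonzero(above[1:-1] & (crit[1:-1] >= crit[:-2])
                         & (crit[1:-1] > crit[2:])) + 1

    # enforce refractory separation, keeping the larger criterion
    refr = int(round(refractory_ms / trace.dt))
    kept: list[int] = []
    for i in idx:
        if kept and i - kept[-1] < refr:
            if crit[i] > crit[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    kept_arr = np.asarray(kept, dtype=int)

    # amplitude screen: fitted event amplitude >= 3 x robust noise SD
    noise_sd = robust_noise_sd(y)
    if kept_arr.size:
        amps = -scale[kept_arr]  # pA, negative = inward
        ok = np.abs(amps) >= AMPLITUDE_SD_FACTOR * noise_sd
        kept_arr, amps = kept_arr[ok], amps[ok]
    else:
        amps = np.empty(0)

    # tail suppression: the criterion also peaks on the decay of an already
    # accepted event (a shifted template fits an exponential tail well), so a
    # candidate within one template length of accepted events must exceed
    # their predicted remaining tail by the same 3-sigma margin
    if kept_arr.size:
        # unit-peak positive kernel shape over an extended horizon (events
        # decay beyond the truncated template length)
        horizon = 6 * N
        shape = biexp_kernel(np.arange(horizon) * trace.dt,
                             template.tau_rise, template.tau_decay, 1.0)
        acc_idx: list[int] = []
        acc_amp: list[float] = []
        for i, amp in zip(kept_arr, amps):
            pred = 0.0
            for j, aj in zip(acc_idx, acc_amp):
                lag = i - j
                if 0 < lag < horizon:
                    pred += abs(aj) * shape[lag]
            # 20 % relative margin: the criterion is amplitude-independent,
            # so an arbitrarily small tail remnant matches the template
            # shape well even in noiseless traces
            if abs(amp) >= 1.2 * pred + AMPLITUDE_SD_FACTOR * noise_sd:
                acc_idx.append(int(i))
                acc_amp.append(float(amp))
        kept_arr = np.asarray(acc_idx, dtype=int)
        amps = np.asarray(acc_amp)

    return EventList(
        times_ms=kept_arr * trace.dt,
        amplitudes=amps,
        criterion=crit[kept_arr],
        duration_ms=trace.duration_ms,
    )


def average_events(trace: Trace, events: EventList,
                   window_ms: float = DEFAULT_WINDOW_MS,
                   pre_ms: float = 10.0, baseline_ms: float = 3.0,
                   peak_search_ms: float = 15.0) -> np.ndarray | None:
    """Pointwise mean of baseline-subtracted, peak-aligned event snippets.

    Detection times mark template onsets, whose lag to the physical event
    depends on the template/event kinetics mismatch, so snippets are aligned
    on each event's current minimum (searched within ``peak_search_ms`` after
    detection) with ``pre_ms`` of context before the peak; the baseline is
    the mean of the first ``baseline_ms`` of the snippet.  Returns ``None``
    for an empty event list.
    """
    if events.n == 0:
        return None
    y = trace.samples
    npre = int(round(pre_ms / trace.dt))
    nb = int(round(baseline_ms / trace.dt))
    nw = int(round(window_ms / trace.dt))
    nsearch = int(round(peak_search_ms / trace.dt))
    margin = int(round(3.0 / trace.dt))  # alignment search half-width, 3 ms

    anchors = []
    for t in events.times_ms:
        i = int(round(t / trace.dt))
        ipk = i + int(np.argmin(y[i:i + nsearch]))
        if ipk - npre - margin >= 0 and ipk - npre + nw + margin <= y.size:
            anchors.append(ipk)
    if not anchors:
        return None

    def extract(shifts):
        out = []
        for ipk, s in zip(anchors, shifts):
            lo = ipk + s - npre
            snip = y[lo:lo + nw].astype(float)
            snip -= snip[:nb].mean() if nb else 0.0
            out.append(snip)
        return np.asarray(out)

    # raw peak positions jitter by the noise; refine by correlation
    # alignment against the running mean (matched-filter timing), twice
    shifts = np.zeros(len(anchors), dtype=int)
    snips = extract(shifts)
    for _ in range(2):
        mean = snips.mean(axis=0)
        for j, ipk in enumerate(anchors):
            lo0 = ipk - npre
            best, best_sse = 0, np.inf
            for s in range(-margin, margin + 1):
                cand = y[lo0 + s:lo0 + s + nw]
                cand = cand - cand[:nb].mean()
                sse = float(np.sum((cand - mean) ** 2))
                if sse < best_sse:
                    best, best_sse = s, sse
            shifts[j] = best
        snips = extract(shifts)
    return snips.mean(axis=0)


def _fit_rise(w: np.ndarray, dt: float, i_peak: int) -> float | None:
    """Max |dI/dt| on the rising phase via a biexponential fit.

    The biexponential's steepest point is its onset, where a sampled
    derivative under-reads by an amount that depends on the kinetics, so the
    mean waveform is fitted with a free-onset biexponential and the maximum
    slope is read off the continuous fit.  Returns ``None`` if the fit
    fails.
    """
    from scipy.optimize import curve_fit

    t = np.arange(w.size) * dt

    def model(t, amp, tau_rise, tau_decay, t0):
        if not tau_decay > tau_rise > 0:
            return np.full_like(t, 1e6)
        return biexp_kernel(t - t0, tau_rise, tau_decay, amp)

    t_peak = i_peak * dt
    p0 = (float(w[i_peak]), 1.0, 5.0, max(t_peak - 2.0, 0.0))
    try:
        popt, _ = curve_fit(model, t, w, p0=p0, maxfev=5000)
    except RuntimeError:
        return None
    amp, tr, td, t0 = popt
    if not (td > tr > 0) or abs(amp) < 1e-12:
        return None
    tf = np.linspace(0.0, t_peak - t0 if t_peak > t0 else td, 2000)
    k = biexp_kernel(tf, tr, td, amp)
    return float(np.abs(np.gradient(k, tf[1] - tf[0])).max())


def waveform_stats(mean_waveform: np.ndarray | None, events: EventList,
                   duration_s: float, dt: float,
                   smooth_ms: float = 0.3) -> WaveformStats:
    """Frequency and kinetic summary from the averaged event waveform.

    ``rate_of_rise`` is the maximum |dI/dt| on the rising phase of the mean
    waveform, evaluated on a continuous biexponential fit of the waveform
    (with a sampled-derivative fallback); ``half_width`` is the time spent
    below the half-amplitude level, with linear interpolation at the
    crossings.  Light Savitzky-Golay smoothing (window ``smooth_ms``) keeps
    the discrete measurements from riding residual noise.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    freq = events.n / duration_s
    if mean_waveform is None or events.n == 0:
        return WaveformStats(frequency=freq, amplitude=np.nan,
                             half_width=np.nan, rate_of_rise=np.nan,
                             n_events=events.n)

    w = np.asarray(mean_waveform, dtype=float)
    if smooth_ms and smooth_ms > 0:
        from scipy.signal import savgol_filter
        win = max(5, int(round(smooth_ms / dt)) | 1)
        if win < w.size:
            w = savgol_filter(w, win, polyorder=3)

    baseline = 0.0  # snippets are baseline-subtracted
    i_peak = int(np.argmin(w))  # inward-negative extremum
    amplitude = float(abs(w[i_peak] - baseline))

    half = w[i_peak] / 2.0
    below = w <= half
    # half-width: contiguous stretch around the peak below the half level,
    # with linear interpolation at both crossings
    i0 = i_peak
    while i0 > 0 and below[i0 - 1]:
        i0 -= 1
    i1 = i_peak
    while i1 < w.size - 1 and below[i1 + 1]:
        i1 += 1
    t0 = i0 * dt
    if i0 > 0 and w[i0 - 1] != w[i0]:
        t0 -= dt * (half - w[i0]) / (w[i0 - 1] - w[i0])
    t1 = i1 * dt
    if i1 < w.size - 1 and w[i1 + 1] != w[i1]:
        t1 += dt * (half - w[i1]) / (w[i1 + 1] - w[i1])
    half_width = float(t1 - t0)

    rate_of_rise = _fit_rise(np.asarray(mean_waveform, dtype=float), dt, i_peak)
    if rate_of_rise is None:
        dwdt = np.gradient(w, dt)
        rate_of_rise = float(np.abs(dwdt[: i_peak + 1]).max()) if i_peak > 0 else np.nan

    return WaveformStats(frequency=freq, amplitude=amplitude,
                         half_width=half_width, rate_of_rise=rate_of_rise,
                         n_events=events.n)
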