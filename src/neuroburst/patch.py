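"""Whole-cell patch-clamp analyses.

Procedures for voltage- and current-clamp sweeps from cultured neurons:

* passive properties — whole-cell capacitance from the area under the
  capacity discharge of a -10 mV test pulse, and current densities (pA/pF);
* synaptic analysis — EPSC detection with a rise-time gate, averaged-event
  decay fitted mono- and bi-exponentially with an area-weighted decay time
  t_w = (A1*t1 + A2*t2) / (A1 + A2);
* slow voltage-clamp bursts (zero-Mg2+ style recordings): deflections > 8 pA
  sustained >= 2 s, with filtered amplitude and raw charge transfer;
* action-potential metrics at rheobase — threshold (dV/dt criterion), peak,
  amplitude, 10-90% rise time, T50, area, latency and jitter (coefficient of
  variation of latency);
* voltage-gated channel analyses — Boltzmann fits of (in)activation curves,
  A-current isolation by prepulse subtraction, antagonist percent
  inhibition, and HCN sag amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

__all__ = [
    "SweepTrace",
    "DecayFit",
    "BoltzmannFit",
    "APMetrics",
    "EPSCEvent",
    "VCBurst",
    "capacitance_from_discharge",
    "current_density",
    "fit_boltzmann",
    "na_inactivation_curves",
    "detect_epscs",
    "fit_weighted_decay",
    "detect_vc_bursts",
    "ap_metrics",
    "find_rheobase",
    "subtract_a_current",
    "percent_inhibition",
    "sag_amplitude",
]


@dataclass
class SweepTrace:
    """A uniformly sampled sweep (pA in voltage clamp, mV in current clamp).

    ``step_on``/``step_off`` delimit the command step (s); ``step_level`` is
    the step amplitude in the command units (mV or pA).
    """

    time_s: np.ndarray
    signal: np.ndarray
    units: str = "pA"
    holding: float | None = None
    step_level: float | None = None
    step_on: float | None = None
    step_off: float | None = None
    capacitance_pF: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise ValueError("time and signal must be 1-D and equal length")
        if self.time_s.size < 2:
            raise ValueError("sweep too short")
        dt = np.diff(self.time_s)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform sampling")
        if not (np.all(np.isfinite(self.signal)) and np.all(np.isfinite(self.time_s))):
            raise ValueError("non-finite values in sweep")
        if self.step_on is not None and self.step_off is not None:
            if not (self.time_s[0] <= self.step_on < self.step_off <= self.time_s[-1]):
                raise ValueError("step window outside trace")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.dt

    def index_of(self, t: float) -> int:
        return int(round((t - self.time_s[0]) / self.dt))


@dataclass(frozen=True)
class DecayFit:
    """Mono- or bi-exponential decay fit with weighted time constant (ms)."""

    A1: float
    t1: float
    A2: float
    t2: float
    t_w: float
    model: str  # "mono" | "bi"
    aicc_mono: float | None = None
    aicc_bi: float | None = None

    def __post_init__(self) -> None:
        if self.t1 <= 0 or (self.model == "bi" and self.t2 <= 0):
            raise ValueError("decay time constants must be positive")
        taus = (self.t1, self.t2) if self.model == "bi" else (self.t1, self.t1)
        if not (min(taus) - 1e-9 <= self.t_w <= max(taus) + 1e-9):
            raise ValueError("t_w must lie between the component time constants")


@dataclass(frozen=True)
class BoltzmannFit:
    """Fit of I(V) = Imax / (1 + exp((V50 - V)/km))."""

    Imax: float
    V50: float
    km: float
    se: tuple = (np.nan, np.nan, np.nan)
    residuals: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.km == 0:
            raise ValueError("km must be non-zero")

    def predict(self, v) -> np.ndarray:
        return boltzmann(np.asarray(v, dtype=float), self.Imax, self.V50, self.km)


@dataclass(frozen=True)
class APMetrics:
    threshold_mV: float
    peak_mV: float
    amplitude_mV: float
    area_mV_ms: float
    rise_time_ms: float
    T50_ms: float
    latency_ms: float | None = None
    jitter: float | None = None
    rheobase_pA: float | None = None


@dataclass(frozen=True)
class EPSCEvent:
    time_s: float
    amplitude: float  # positive magnitude, signal units
    rise_time_ms: float
    decay: np.ndarray = field(repr=False, default=None)  # post-peak segment


@dataclass(frozen=True)
class VCBurst:
    start_s: float
    end_s: float
    amplitude_pA: float  # peak of filtered, baseline-subtracted current
    charge_pC: float  # integral of raw baseline-subtracted current

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def boltzmann(v, imax, v50, km):
    z = np.clip((v50 - v) / km, -700, 700)  # avoid exp overflow far from V50
    return imax / (1.0 + np.exp(z))


# ---------------------------------------------------------------------------
# passive properties


def capacitance_from_discharge(
    sweep: SweepTrace, dV_mV: float, baseline_s: float = 0.05
) -> float:
    """Whole-cell capacitance (pF) from the area under the capacity transient.

    The charge is the integral of the baseline- and steady-state-subtracted
    current transient after the step onset; C = Q / |dV|.  The baseline is
    the median over ``baseline_s`` before the step; the steady state is the
    median over the final quarter of the step.
    """
    if sweep.step_on is None or sweep.step_off is None:
        raise ValueError("step metadata required")
    if dV_mV == 0:
        raise ValueError("dV must be non-zero")
    i0 = sweep.index_of(sweep.step_on)
    i1 = sweep.index_of(sweep.step_off)
    pre = sweep.signal[max(0, i0 - int(round(baseline_s / sweep.dt))):i0]
    if pre.size == 0:
        raise ValueError("no baseline window before the pulse")
    # the steady-state level inside the pulse carries the resistive current;
    # subtracting it isolates the capacitive transient
    quarter = max(1, (i1 - i0) // 4)
    steady = np.median(sweep.signal[i1 - quarter:i1])
    transient = sweep.signal[i0:i1] - steady
    q_pC = float(np.trapezoid(transient, dx=sweep.dt))  # pA*s == pC
    if abs(q_pC) < 1e-12:
        warnings.warn("zero-area capacity transient")
        return 0.0
    c_pF = abs(q_pC) / abs(dV_mV) * 1e3  # pC/mV = nF; 1 nF = 1000 pF
    return c_pF


def current_density(peak_pA: float, capacitance_pF: float) -> float:
    """Peak current normalised to cell size (pA/pF), sign preserved."""
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    return peak_pA / capacitance_pF


# ---------------------------------------------------------------------------
# curve fits


def fit_boltzmann(voltages, currents) -> BoltzmannFit:
    """Least-squares Boltzmann fit I(V) = Imax / (1 + exp((V50 - V)/km)).

    Handles both rising (km > 0) and falling (km < 0, e.g. steady-state
    inactivation) curves; the slope sign of the initial guess is taken from
    the data.
    """
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 points spanning the transition")
    imax0 = i.max() if abs(i.max()) >= abs(i.min()) else i.min()
    half = imax0 / 2.0
    v50_0 = float(v[np.argmin(np.abs(i - half))])
    rising = np.polyfit(v, i, 1)[0] * np.sign(imax0) > 0
    km0 = (v.max() - v.min()) / 6.0 * (1 if rising else -1)
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann, v, i, p0=[imax0, v50_0, km0], maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Boltzmann fit did not converge (p0: Imax={imax0:.3g}, "
            f"V50={v50_0:.3g}, km={km0:.3g})"
        ) from exc
    se = tuple(np.sqrt(np.diag(pcov)))
    resid = i - boltzmann(v, *popt)
    return BoltzmannFit(Imax=float(popt[0]), V50=float(popt[1]), km=float(popt[2]),
                        se=se, residuals=resid)


def na_inactivation_curves(
    sweeps: list[tuple[float, SweepTrace]], mode: str = "fast"
) -> tuple[np.ndarray, np.ndarray, BoltzmannFit]:
    """Steady-state inactivation from a family of prepulse sweeps.

    ``sweeps`` pairs each prepulse voltage (mV) with the test-pulse sweep
    recorded immediately after it (toxin-subtracted).  The peak test current
    per prepulse is normalised to the overall maximum and fitted with a
    Boltzmann.  ``mode`` labels the protocol ("fast": 100 ms prepulse,
    "slow": 5 s); it does not alter the computation.
    """
    if mode not in ("fast", "slow"):
        raise ValueError("mode must be 'fast' or 'slow'")
    if not sweeps:
        raise ValueError("no sweeps")
    volts, peaks = [], []
    for v_pre, sw in sweeps:
        if v_pre is None:
            raise ValueError("missing prepulse voltage metadata")
        if sw.step_on is None or sw.step_off is None:
            raise ValueError("missing test-pulse window metadata")
        seg = sw.signal[sw.index_of(sw.step_on):sw.index_of(sw.step_off)]
        peaks.append(float(np.max(np.abs(seg))))
        volts.append(float(v_pre))
    volts = np.asarray(volts)
    peaks = np.asarray(peaks)
    if peaks.max() <= 0:
        raise ValueError("no detectable test-pulse current")
    norm = peaks / peaks.max()
    order = np.argsort(volts)
    fit = fit_boltzmann(volts[order], norm[order])
    return volts[order], norm[order], fit


def _exp1(t, a1, t1):
    return a1 * np.exp(-t / t1)


def _exp2(t, a1, t1, a2, t2):
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)


def _aicc(resid_ss: float, n: int, k: int) -> float:
    if n <= k + 2:
        return np.inf
    aic = n * np.log(max(resid_ss, 1e-300) / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_weighted_decay(time_ms, waveform) -> DecayFit:
    """Fit the post-peak decay mono- and bi-exponentially; pick by AICc.

    ``waveform`` is an averaged, baseline-subtracted event, decaying from its
    peak (first sample); ``time_ms`` starts at 0.  The weighted decay
    constant is t_w = (A1*t1 + A2*t2) / (A1 + A2) with component amplitudes
    as weights; for the mono model t_w = t1.
    """
    t = np.asarray(time_ms, dtype=float)
    y = np.asarray(waveform, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need matching time/waveform with >= 5 samples")
    if t[-1] - t[0] < 5.0:
        raise ValueError("need >= 5 ms of post-peak decay")
    t = t - t[0]
    sign = 1.0 if abs(y.max()) >= abs(y.min()) else -1.0
    yy = sign * y
    peak = max(yy.max(), 1e-12)
    span = t[-1]
    results = {}
    try:
        p1, _ = optimize.curve_fit(
            _exp1, t, yy, p0=[peak, span / 5],
            bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=20000,
        )
        ss1 = float(np.sum((yy - _exp1(t, *p1)) ** 2))
        results["mono"] = (p1, _aicc(ss1, t.size, 2))
    except RuntimeError:
        pass
    try:
        p2, _ = optimize.curve_fit(
            _exp2, t, yy, p0=[peak / 2, span / 10, peak / 2, span / 2],
            bounds=([0, 1e-6, 0, 1e-6], [np.inf] * 4), maxfev=20000,
        )
        ss2 = float(np.sum((yy - _exp2(t, *p2)) ** 2))
        results["bi"] = (p2, _aicc(ss2, t.size, 4))
    except RuntimeError:
        pass
    if not results:
        raise RuntimeError("neither decay model converged")
    aicc_mono = results.get("mono", (None, None))[1]
    aicc_bi = results.get("bi", (None, None))[1]
    model = min(results, key=lambda m: results[m][1])
    p = results[model][0]
    if model == "mono":
        a1, t1 = (sign * p[0], p[1])
        return DecayFit(A1=float(a1), t1=float(t1), A2=0.0, t2=float(t1),
                        t_w=float(t1), model="mono",
                        aicc_mono=aicc_mono, aicc_bi=aicc_bi)
    a1, t1, a2, t2 = p
    if t1 > t2:  # order components fast-first
        a1, t1, a2, t2 = a2, t2, a1, t1
    t_w = (a1 * t1 + a2 * t2) / (a1 + a2) if (a1 + a2) > 0 else t1
    return DecayFit(A1=float(sign * a1), t1=float(t1), A2=float(sign * a2),
                    t2=float(t2), t_w=float(t_w), model="bi",
                    aicc_mono=aicc_mono, aicc_bi=aicc_bi)


def weighted_tau(a1: float, t1: float, a2: float, t2: float) -> float:
    """t_w = (A1*t1 + A2*t2) / (A1 + A2)."""
    return (a1 * t1 + a2 * t2) / (a1 + a2)


# ---------------------------------------------------------------------------
# synaptic events


def detect_epscs(
    trace: SweepTrace,
    noise_sd: float | None = None,
    min_amplitude_mult: float = 3.0,
    max_rise_ms: float = 5.0,
    polarity: int = -1,
    min_separation_ms: float = 5.0,
    smooth_ms: float = 1.0,
) -> list[EPSCEvent]:
    """Threshold-based EPSC detection with a rise-time gate.

    The trace is lightly smoothed (``smooth_ms`` boxcar) before peak
    detection to suppress single-sample noise crossings.  Events are
    deflections of ``polarity`` sign exceeding ``min_amplitude_mult`` times
    the noise SD of the smoothed trace over the median baseline, with
    10-90% rise time <= ``max_rise_ms`` (slower events, e.g. IPSC-like or
    burst envelopes, are rejected).  ``noise_sd`` defaults to a robust (MAD)
    estimate from the smoothed trace.
    """
    y = trace.signal
    if trace.time_s[-1] - trace.time_s[0] < 10.0:
        warnings.warn("epoch shorter than 10 s: frequency estimate unstable")
    baseline = np.median(y)
    x = polarity * (y - baseline)
    win = max(1, int(round(smooth_ms / 1e3 / trace.dt)))
    xs = np.convolve(x, np.ones(win) / win, mode="same") if win > 1 else x
    if noise_sd is None:
        noise_sd = float(np.median(np.abs(xs - np.median(xs))) / 0.6745)
    if noise_sd <= 0:
        return []
    thr = min_amplitude_mult * noise_sd
    dist = max(1, int(round(min_separation_ms / 1e3 / trace.dt)))
    peaks, _ = signal.find_peaks(xs, height=thr, distance=dist)
    events = []
    for p in peaks:
        amp = x[p]
        # walk back to 10% and 90% crossings (on the smoothed trace)
        amp_s = xs[p]
        i90 = p
        while i90 > 0 and xs[i90] > 0.9 * amp_s:
            i90 -= 1
        i10 = i90
        while i10 > 0 and xs[i10] > 0.1 * amp_s:
            i10 -= 1
        rise_ms = (i90 - i10) * trace.dt * 1e3
        if rise_ms > max_rise_ms:
            continue
        events.append(EPSCEvent(
            time_s=float(trace.time_s[p]), amplitude=float(amp),
            rise_time_ms=float(rise_ms),
            decay=y[p:min(y.size, p + dist * 4)] - baseline,
        ))
    return events


def epsc_frequency(events: list[EPSCEvent], duration_s: float) -> float:
    """Event rate in Hz."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(events) / duration_s


def detect_vc_bursts(
    trace: SweepTrace,
    amplitude_threshold_pA: float = 8.0,
    min_duration_s: float = 2.0,
    filter_window_s: float = 0.05,
    polarity: int = -1,
) -> list[VCBurst]:
    """Slow voltage-clamp bursts: sustained deflections of the holding current.

    The trace is median-filtered (``filter_window_s``) to remove fast EPSCs;
    bursts are periods where the filtered, baseline-subtracted current
    exceeds ``amplitude_threshold_pA`` continuously for >= ``min_duration_s``.
    The amplitude is the filtered peak (EPSC-free); the charge integrates the
    raw current over the event, EPSCs included.
    """
    y = polarity * trace.signal
    win = max(1, int(round(filter_window_s / trace.dt)))
    if win % 2 == 0:
        win += 1
    filt = signal.medfilt(y, kernel_size=win)
    baseline = np.median(filt)
    above = (filt - baseline) > amplitude_threshold_pA
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    bursts = []
    for s, e in zip(starts, ends):
        dur = (e - 1 - s) * trace.dt
        if dur < min_duration_s:
            continue
        seg_filt = filt[s:e] - baseline
        seg_raw = y[s:e] - baseline
        bursts.append(VCBurst(
            start_s=float(trace.time_s[s]), end_s=float(trace.time_s[e - 1]),
            amplitude_pA=float(seg_filt.max()),
            charge_pC=float(np.trapezoid(seg_raw, dx=trace.dt)),
        ))
    return bursts


# ---------------------------------------------------------------------------
# action potentials


def _find_spikes(sweep: SweepTrace, min_peak_mV: float = -10.0) -> np.ndarray:
    """Indices of action-potential peaks in a current-clamp sweep."""
    peaks, _ = signal.find_peaks(sweep.signal, height=min_peak_mV, prominence=20.0)
    return peaks


def count_spikes(sweep: SweepTrace) -> int:
    return int(_find_spikes(sweep).size)


def ap_metrics(
    sweeps: list[SweepTrace],
    dvdt_threshold_V_per_s: float = 20.0,
    rheobase_pA: float | None = None,
) -> APMetrics | None:
    """Action-potential waveform metrics from rheobase sweeps.

    Waveform metrics (threshold, peak, amplitude, 10-90% rise, T50, area)
    come from the first spike of the first spiking sweep; latency is the
    first-spike threshold time from step onset, averaged over spiking
    sweeps, and jitter is the coefficient of variation of latency
    (population SD / mean; >= 5 sweeps recommended).  Returns ``None`` when
    no sweep spikes.
    """
    latencies = []
    first_metrics = None
    for sw in sweeps:
        peaks = _find_spikes(sw)
        if peaks.size == 0:
            continue
        p = int(peaks[0])
        v = sw.signal
        dvdt = np.gradient(v, sw.dt) / 1e3  # mV/s -> V/s
        # search back from the peak for the last sub-criterion point
        i = p
        while i > 0 and dvdt[i - 1] >= dvdt_threshold_V_per_s:
            i -= 1
        thr_idx = i
        thr = float(v[thr_idx])
        peak = float(v[p])
        amp = peak - thr
        if amp <= 0:
            continue
        if sw.step_on is not None:
            latencies.append(sw.time_s[thr_idx] - sw.step_on)
        if first_metrics is None:
            # 10-90% rise between threshold and peak
            seg = v[thr_idx:p + 1]
            t10 = thr + 0.1 * amp
            t90 = thr + 0.9 * amp
            i10 = int(np.argmax(seg >= t10))
            i90 = int(np.argmax(seg >= t90))
            rise_ms = (i90 - i10) * sw.dt * 1e3
            # T50: time from peak down to half amplitude
            half = thr + 0.5 * amp
            post = v[p:]
            below = np.flatnonzero(post <= half)
            t50_ms = (below[0] * sw.dt * 1e3) if below.size else np.nan
            # area between outbound and return threshold crossings
            ret = np.flatnonzero(post <= thr)
            end = p + (int(ret[0]) if ret.size else post.size - 1)
            area = float(np.trapezoid(v[thr_idx:end + 1] - thr,
                                      dx=sw.dt) * 1e3)  # mV*ms
            first_metrics = dict(threshold_mV=thr, peak_mV=peak, amplitude_mV=amp,
                                 rise_time_ms=float(rise_ms), T50_ms=float(t50_ms),
                                 area_mV_ms=area)
    if first_metrics is None:
        return None
    latency_ms = jitter = None
    if latencies:
        lat = np.asarray(latencies) * 1e3
        latency_ms = float(lat.mean())
        if lat.size >= 2 and latency_ms > 0:
            jitter = float(lat.std() / lat.mean())  # population SD (CV convention)
    return APMetrics(latency_ms=latency_ms, jitter=jitter,
                     rheobase_pA=rheobase_pA, **first_metrics)


def find_rheobase(
    stimulate,
    coarse_step_pA: float = 10.0,
    refine_pA: float = 1.0,
    start_pA: float = 0.0,
    max_pA: float = 500.0,
) -> float:
    """Minimal injected current (pA) eliciting >= 1 spike.

    ``stimulate`` maps a current (pA) to a :class:`SweepTrace`.  Ascending
    coarse steps find the first spiking current, then bisection refines to
    ``refine_pA`` resolution.  Assumes a monotone spiking response.
    """
    if coarse_step_pA <= 0 or refine_pA <= 0:
        raise ValueError("steps must be positive")
    lo, hi = start_pA, None
    i = start_pA
    while i <= max_pA:
        if count_spikes(stimulate(i)) >= 1:
            hi = i
            break
        lo = i
        i += coarse_step_pA
    if hi is None:
        raise RuntimeError(f"no spiking up to {max_pA} pA")
    # integer bisection on the refine_pA grid
    lo_k = int(np.floor(lo / refine_pA))
    hi_k = int(np.ceil(hi / refine_pA))
    while hi_k - lo_k > 1:
        mid_k = (lo_k + hi_k) // 2
        if count_spikes(stimulate(mid_k * refine_pA)) >= 1:
            hi_k = mid_k
        else:
            lo_k = mid_k
    return hi_k * refine_pA


# ---------------------------------------------------------------------------
# voltage-gated currents


def subtract_a_current(
    sweep_hyper: SweepTrace, sweep_depol: SweepTrace, capacitance_pF: float
) -> tuple[np.ndarray, float]:
    """Isolate the transient A-type K+ current by prepulse subtraction.

    The depolarised-prepulse sweep (A-current inactivated) is subtracted
    pointwise from the hyperpolarised-prepulse sweep (A-current available)
    and divided by the whole-cell capacitance.  Returns the density
    waveform (pA/pF) and its peak (signed by the transient polarity).
    """
    if sweep_hyper.time_s.size != sweep_depol.time_s.size or not np.allclose(
        sweep_hyper.time_s, sweep_depol.time_s
    ):
        raise ValueError("time-base mismatch between sweeps")
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    diff = (sweep_hyper.signal - sweep_depol.signal) / capacitance_pF
    peak = float(diff[np.argmax(np.abs(diff))])
    return diff, peak


def percent_inhibition(control_peak: float, drug_peak: float) -> float:
    """(1 - drug/control) x 100."""
    if control_peak == 0:
        raise ValueError("control peak must be non-zero")
    return (1.0 - drug_peak / control_peak) * 100.0


def sag_amplitude(sweep: SweepTrace, steady_frac: float = 0.1) -> float:
    """HCN sag (mV): trough minus steady-state voltage during a
    hyperpolarising step, as a positive magnitude.

    The steady state is the mean over the final ``steady_frac`` of the step.
    A monotone relaxation without rebound gives ~0.
    """
    if sweep.step_on is None or sweep.step_off is None:
        raise ValueError("step metadata required")
    i0, i1 = sweep.index_of(sweep.step_on), sweep.index_of(sweep.step_off)
    if i1 - i0 < 10:
        raise ValueError("step window too short")
    seg = sweep.signal[i0:i1]
    tail = max(1, int(round(steady_frac * seg.size)))
    steady = float(np.mean(seg[-tail:]))
    trough = float(seg.min())
    return max(0.0, steady - trough)
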