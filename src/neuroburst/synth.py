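"""Ground-truth synthetic data generators.

Every analysis stage of the package can be exercised without recordings:
these generators emit data in the containers the analysis modules consume,
together with the planted ground truth, and are deterministic per seed.

The spike-train generator is a doubly stochastic Poisson construction —
independent background Poisson trains per electrode superposed with
Poisson-timed population-burst epochs in which participating electrodes fire
at an elevated rate.  Defaults emulate a 64-electrode (8 x 8) array recorded
for 10 minutes.  The action-potential generator is template-based (not
conductance-based) so its ground-truth metrics are exact by construction;
neither generator claims biophysical realism beyond what the detectors
assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neuroburst.mea import SpikeTrainSet
from neuroburst.patch import SweepTrace, boltzmann, weighted_tau
from neuroburst.screen import ExpressionMatrix

__all__ = [
    "SpikeTrainGenConfig",
    "GroundTruth",
    "gen_spike_trains",
    "gen_raw_traces",
    "gen_epsc_trace",
    "gen_boltzmann_data",
    "gen_ap_sweeps",
    "gen_expression_matrix",
]


@dataclass(frozen=True)
class SpikeTrainGenConfig:
    """Population spike-train generator settings (64-electrode array,
    10-min recording by default)."""

    n_electrodes: int = 64
    duration_s: float = 600.0
    background_rate_hz: float = 0.1
    nb_rate_per_min: float = 2.0
    nb_within_rate_hz: float = 100.0  # per participating electrode, inside a burst
    nb_duration_s: float = 0.3
    participation_prob: float = 0.6
    jitter_sd_s: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        rates = (self.background_rate_hz, self.nb_rate_per_min,
                 self.nb_within_rate_hz, self.nb_duration_s, self.jitter_sd_s)
        if any(v < 0 for v in rates):
            raise ValueError("rates and durations must be non-negative")
        if not 0 <= self.participation_prob <= 1:
            raise ValueError("participation_prob must be in [0, 1]")
        if self.n_electrodes < 1 or self.duration_s <= 0:
            raise ValueError("need >= 1 electrode and positive duration")


@dataclass
class GroundTruth:
    """Planted schedule/parameters accompanying a generated dataset."""

    event_times: np.ndarray | None = None
    event_participants: list | None = None
    spike_times: dict | None = None
    params: dict = field(default_factory=dict)


def _poisson_times(rng, rate_hz, t0, t1):
    n = rng.poisson(max(0.0, rate_hz) * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def gen_spike_trains(
    cfg: SpikeTrainGenConfig | None = None, seed: int | None = None
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Background Poisson trains plus planted population-burst epochs.

    Burst onsets are Poisson with rate ``nb_rate_per_min``; each electrode
    participates in a given burst with ``participation_prob``, firing at
    ``nb_within_rate_hz`` for ``nb_duration_s`` after a Gaussian-jittered
    onset.  Returns the spike trains and the planted schedule.
    """
    cfg = cfg or SpikeTrainGenConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    onsets = _poisson_times(rng, cfg.nb_rate_per_min / 60.0, 0.0, cfg.duration_s)
    participants = [
        np.flatnonzero(rng.random(cfg.n_electrodes) < cfg.participation_prob)
        for _ in onsets
    ]
    trains = {}
    for e in range(cfg.n_electrodes):
        t = [_poisson_times(rng, cfg.background_rate_hz, 0.0, cfg.duration_s)]
        for onset, part in zip(onsets, participants):
            if e not in part:
                continue
            start = onset + rng.normal(0.0, cfg.jitter_sd_s)
            burst = start + np.sort(
                rng.uniform(0.0, cfg.nb_duration_s,
                            size=rng.poisson(cfg.nb_within_rate_hz * cfg.nb_duration_s))
            )
            t.append(burst)
        merged = np.unique(np.concatenate(t))
        trains[e] = merged[(merged >= 0) & (merged <= cfg.duration_s)]
    truth = GroundTruth(
        event_times=onsets,
        event_participants=participants,
        spike_times={e: trains[e].copy() for e in trains},
        params={"config": cfg},
    )
    return SpikeTrainSet(trains=trains, duration_s=cfg.duration_s), truth


def biphasic_template(fs_hz: float, width_ms: float = 1.0) -> np.ndarray:
    """Unit-peak biphasic extracellular spike template (negative-leading)."""
    n = max(5, int(round(width_ms / 1e3 * fs_hz)))
    t = np.linspace(-1.0, 1.0, n)
    sigma = 0.35
    w = -t * np.exp(-(t ** 2) / (2 * sigma ** 2))
    return w / np.max(np.abs(w))


def gen_raw_traces(
    spikes: SpikeTrainSet,
    fs_hz: float = 12500.0,
    noise_sd: float = 1.0,
    amplitude: float = 10.0,
    template: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Gaussian noise with a biphasic template inserted at each spike time.

    ``amplitude / noise_sd`` sets the SNR.  Returns ``(traces, fs_hz)`` with
    traces of shape (n_electrodes, n_samples).
    """
    if fs_hz < 10000:
        raise ValueError("sample rate must be >= 10 kHz")
    rng = np.random.default_rng(seed)
    if template is None:
        template = biphasic_template(fs_hz)
    n_samp = int(round(spikes.duration_s * fs_hz))
    if template.size > n_samp:
        raise ValueError("template longer than trace")
    kernel = template * amplitude
    half = template.size // 2
    traces = rng.normal(0.0, noise_sd, size=(spikes.n_electrodes, n_samp))
    for i, e in enumerate(spikes.electrodes):
        for t in spikes.trains[e]:
            c = int(round(t * fs_hz))
            lo, hi = c - half, c - half + kernel.size
            klo, khi = max(0, -lo), kernel.size - max(0, hi - n_samp)
            traces[i, max(0, lo):min(n_samp, hi)] += kernel[klo:khi]
    return traces, fs_hz


def epsc_kernel(
    fs_hz: float, t1_ms: float, t2_ms: float, a1_frac: float = 0.5,
    rise_ms: float = 0.5, duration_ms: float = 60.0,
) -> np.ndarray:
    """Unit-peak EPSC kernel: linear rise then bi-exponential decay.

    The decay is ``a1*exp(-t/t1) + a2*exp(-t/t2)`` with ``a1 + a2 = 1``; its
    amplitude-weighted time constant is ``a1*t1 + a2*t2``.
    """
    if t1_ms <= 0 or t2_ms <= 0:
        raise ValueError("decay constants must be positive")
    n_rise = max(1, int(round(rise_ms / 1e3 * fs_hz)))
    rise = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    t = np.arange(int(round(duration_ms / 1e3 * fs_hz))) / fs_hz * 1e3
    decay = a1_frac * np.exp(-t / t1_ms) + (1 - a1_frac) * np.exp(-t / t2_ms)
    return np.concatenate([rise, decay])


def gen_epsc_trace(
    rate_hz: float = 1.0,
    amp_mean: float = 20.0,
    amp_sd: float = 5.0,
    t1_ms: float = 2.0,
    t2_ms: float = 12.0,
    a1_frac: float = 0.5,
    noise_sd: float = 1.0,
    duration_s: float = 60.0,
    fs_hz: float = 10000.0,
    polarity: int = -1,
    seed: int | None = None,
) -> tuple[SweepTrace, GroundTruth]:
    """Poisson-timed EPSC-like events on a noisy voltage-clamp baseline.

    Events are the :func:`epsc_kernel` shape scaled by truncated-Gaussian
    amplitudes, inward by default.  The ground truth carries event times,
    amplitudes and the analytic weighted decay time of the kernel.
    """
    rng = np.random.default_rng(seed)
    times = _poisson_times(rng, rate_hz, 0.0, duration_s)
    amps = np.clip(rng.normal(amp_mean, amp_sd, size=times.size), amp_mean / 4, None)
    n_samp = int(round(duration_s * fs_hz))
    y = rng.normal(0.0, noise_sd, size=n_samp)
    kernel = epsc_kernel(fs_hz, t1_ms, t2_ms, a1_frac)
    for t, a in zip(times, amps):
        c = int(round(t * fs_hz))
        hi = min(n_samp, c + kernel.size)
        if c < n_samp:
            y[c:hi] += polarity * a * kernel[: hi - c]
    sweep = SweepTrace(time_s=np.arange(n_samp) / fs_hz, signal=y, units="pA",
                       holding=-70.0)
    truth = GroundTruth(
        event_times=times,
        spike_times=None,
        params={
            "amplitudes": amps, "t1_ms": t1_ms, "t2_ms": t2_ms,
            "a1_frac": a1_frac, "polarity": polarity,
            "t_w_ms": weighted_tau(a1_frac, t1_ms, 1 - a1_frac, t2_ms),
        },
    )
    return sweep, truth


def gen_boltzmann_data(
    imax: float = 1.0,
    v50: float = -60.0,
    km: float = 6.0,
    voltages=None,
    noise_sd: float = 0.02,
    n_reps: int = 1,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Noisy samples of the Boltzmann curve I(V) = Imax/(1+exp((V50-V)/km)).

    Returns ``(voltages, currents)`` with currents of shape
    ``(n_reps, len(voltages))`` squeezed for a single rep.
    """
    if km == 0:
        raise ValueError("km must be non-zero")
    if voltages is None:
        voltages = np.arange(-120.0, -15.0, 7.5)  # 14-15 points across transition
    v = np.asarray(voltages, dtype=float)
    rng = np.random.default_rng(seed)
    clean = boltzmann(v, imax, v50, km)
    i = clean + rng.normal(0.0, noise_sd, size=(n_reps, v.size))
    truth = GroundTruth(params={"Imax": imax, "V50": v50, "km": km})
    return v, (i[0] if n_reps == 1 else i), truth


def gen_ap_sweeps(
    threshold_current_pA: float = 43.0,
    currents=None,
    latency_mean_ms: float = 10.0,
    latency_sd_ms: float = 0.0,
    max_spikes: int = 3,
    threshold_mV: float = -40.0,
    peak_mV: float = 30.0,
    rest_mV: float = -65.0,
    tau_m_ms: float = 20.0,
    r_in_MOhm: float = 300.0,
    step_on_s: float = 0.1,
    step_dur_s: float = 0.5,
    fs_hz: float = 20000.0,
    seed: int | None = None,
) -> tuple[list[SweepTrace], GroundTruth]:
    """Template-based current-clamp sweeps for a step protocol.

    Below ``threshold_current_pA`` the response is a passive RC charging
    curve; at or above it, stereotyped spikes are pasted onto the passive
    response at the (possibly jittered) latency, saturating at
    ``max_spikes`` (single/double/multiple-spiker emulation).  Ground truth
    carries the planted threshold current, spike template landmarks and the
    per-sweep latencies.
    """
    if currents is None:
        currents = [0.0, 20.0, 40.0, 60.0, 80.0]
    rng = np.random.default_rng(seed)
    n_samp = int(round((step_on_s + step_dur_s + 0.1) * fs_hz))
    t = np.arange(n_samp) / fs_hz
    sweeps, latencies = [], {}
    # stereotyped spike: slow approach ramp (10 V/s, below the 20 V/s
    # threshold criterion) to threshold_mV, fast linear rise to the peak,
    # exponential decay back; the dV/dt threshold detector then recovers
    # threshold_mV exactly at the ramp/rise junction
    ramp_ms, rise_ms_, decay_tau_ms = 0.5, 1.0, 1.0
    ramp_n = int(round(ramp_ms / 1e3 * fs_hz))
    rise_n = int(round(rise_ms_ / 1e3 * fs_hz))
    decay_n = int(round(0.004 * fs_hz))
    ramp = np.linspace(threshold_mV - 10.0 * ramp_ms, threshold_mV, ramp_n,
                       endpoint=False)
    spike_rise = np.linspace(threshold_mV, peak_mV, rise_n, endpoint=False)
    td = np.arange(decay_n) / fs_hz * 1e3
    spike_decay = threshold_mV + (peak_mV - threshold_mV) * np.exp(-td / decay_tau_ms)
    spike_wave = np.concatenate([ramp, spike_rise, spike_decay])
    for i_pA in currents:
        v = np.full(n_samp, rest_mV)
        on, off = int(round(step_on_s * fs_hz)), int(round((step_on_s + step_dur_s) * fs_hz))
        # passive depolarisation saturates below spike threshold (emulating
        # the conductance load of a real cell; keeps subthreshold sweeps
        # subthreshold at any injection)
        dv_ss = min(i_pA * r_in_MOhm * 1e-3,  # pA * MOhm * 1e-3 -> mV
                    threshold_mV - 5.0 - rest_mV)
        tt = (t[on:off] - t[on]) * 1e3
        v[on:off] += dv_ss * (1 - np.exp(-tt / tau_m_ms))
        v[off:] = rest_mV + (v[off - 1] - rest_mV) * np.exp(
            -(t[off:] - t[off]) * 1e3 / tau_m_ms)
        lat_list = []
        if i_pA >= threshold_current_pA:
            n_spk = min(max_spikes, 1 + int((i_pA - threshold_current_pA) // 20))
            lat = max(1.0, latency_mean_ms + (
                rng.normal(0.0, latency_sd_ms) if latency_sd_ms > 0 else 0.0))
            lat_list.append(lat)
            for k in range(n_spk):
                # place the ramp/rise junction (the nominal threshold point)
                # exactly at the planted latency
                s0 = on + int(round((lat + 50.0 * k) / 1e3 * fs_hz)) - ramp_n
                s1 = min(n_samp, s0 + spike_wave.size)
                if 0 <= s0 < n_samp:
                    v[s0:s1] = spike_wave[: s1 - s0]
        latencies[float(i_pA)] = lat_list
        sweeps.append(SweepTrace(
            time_s=t, signal=v, units="mV", holding=rest_mV,
            step_level=float(i_pA), step_on=step_on_s,
            step_off=step_on_s + step_dur_s,
        ))
    truth = GroundTruth(params={
        "threshold_current_pA": threshold_current_pA,
        "threshold_mV": threshold_mV, "peak_mV": peak_mV,
        "amplitude_mV": peak_mV - threshold_mV,
        "T50_ms": float(np.log(2.0) * decay_tau_ms),
        "rise_time_ms": 0.8 * rise_ms_,  # 10-90% of a linear rise
        "latencies_ms": latencies,
        "latency_mean_ms": latency_mean_ms, "latency_sd_ms": latency_sd_ms,
    })
    return sweeps, truth


def make_ap_stimulator(
    threshold_current_pA: float = 43.0, seed: int | None = None, **kwargs
):
    """Callable current (pA) -> sweep, for rheobase searches."""

    def stimulate(i_pA: float) -> SweepTrace:
        sweeps, _ = gen_ap_sweeps(
            threshold_current_pA=threshold_current_pA,
            currents=[i_pA], seed=seed, **kwargs,
        )
        return sweeps[0]

    return stimulate


def gen_expression_matrix(
    n_genes: int = 200,
    n_pairs_per_stage: int = 5,
    stages=range(1, 10),
    planted: dict | None = None,
    noise_sd: float = 0.1,
    baseline: float = 8.0,
    baseline_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Paired log2 expression with planted fold changes.

    Control values are Gaussian around a per-gene baseline; the matched DS
    value adds the planted log2 fold change (``planted``: gene index or name
    -> log2 FC) plus independent pair noise.  Stages default to the nine
    developmental stages used with three-stage sliding windows.
    """
    stages = list(stages)
    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    genes = [f"G{k:05d}" for k in range(n_genes)]
    fc = np.zeros(n_genes)
    for key, lfc in planted.items():
        idx = genes.index(key) if isinstance(key, str) else int(key)
        fc[idx] = lfc
    gene_base = baseline + rng.normal(0.0, baseline_sd, size=n_genes)
    cols, design_rows = {}, []
    pair_id = 0
    for stage in stages:
        for _ in range(n_pairs_per_stage):
            ctrl = gene_base + rng.normal(0.0, noise_sd, size=n_genes)
            ds = ctrl + fc + rng.normal(0.0, noise_sd, size=n_genes)
            s_ds, s_ct = f"DS_{pair_id:03d}", f"CT_{pair_id:03d}"
            cols[s_ds], cols[s_ct] = ds, ctrl
            design_rows.append((s_ds, "DS", pair_id, stage))
            design_rows.append((s_ct, "control", pair_id, stage))
            pair_id += 1
    values = pd.DataFrame(cols, index=genes)
    design = pd.DataFrame(
        design_rows, columns=["sample", "condition", "pair", "stage"]
    ).set_index("sample")
    truth = GroundTruth(params={
        "log2_fc": {genes[k]: fc[k] for k in np.flatnonzero(fc != 0)},
        "noise_sd": noise_sd, "n_pairs_per_stage": n_pairs_per_stage,
    })
    return ExpressionMatrix(values=values, design=design), truth
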