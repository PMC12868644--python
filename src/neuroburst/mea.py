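"""Multi-electrode array (MEA) analysis: spike detection, burst and
network-burst detection, firing-rate and synchrony metrics.

The pipeline mirrors standard extracellular MEA practice for cultured
neuronal networks: spikes are threshold crossings at 6 robust standard
deviations of the per-second noise estimate; electrodes are "active" above
5 spikes/min; single-electrode bursts are runs of >= 5 spikes with every
inter-spike interval (ISI) <= 100 ms; network bursts additionally require
>= 50 pooled spikes with a minimum fraction of active electrodes
participating; synchrony is summarised from pooled pairwise
cross-correlograms of 20-ms binned spike counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MEADetectionParams",
    "SpikeTrainSet",
    "load_traces_h5",
    "BurstEvent",
    "NetworkBurstEvent",
    "BurstStatistics",
    "detect_spikes",
    "active_electrodes",
    "weighted_mean_firing_rate",
    "detect_bursts",
    "burst_statistics",
    "detect_network_bursts",
    "xcorr_area",
    "synchrony_index",
]

MAD_TO_SD = 0.6745  # Phi^-1(0.75): MAD of a Gaussian in SD units


@dataclass(frozen=True)
class MEADetectionParams:
    """Detection and metric parameters.

    ``nb_min_electrode_frac`` defaults to 0.25, inside the accepted 0.20-0.35
    range for synchronous electrode participation.
    """

    threshold_sd: float = 6.0
    noise_window_s: float = 1.0
    active_min_spikes_per_min: float = 5.0
    burst_max_isi_s: float = 0.1
    burst_min_spikes: int = 5
    nb_min_spikes: int = 50
    nb_min_electrode_frac: float = 0.25
    nb_bin_s: float = 0.02
    xcorr_max_lag_s: float = 1.0
    dead_time_s: float = 0.001
    align_window_s: float = 0.0005

    def __post_init__(self) -> None:
        numeric = (
            self.threshold_sd, self.noise_window_s, self.active_min_spikes_per_min,
            self.burst_max_isi_s, self.burst_min_spikes, self.nb_min_spikes,
            self.nb_min_electrode_frac, self.nb_bin_s, self.xcorr_max_lag_s,
            self.dead_time_s, self.align_window_s,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all detection parameters must be positive")
        if not 0.20 <= self.nb_min_electrode_frac <= 0.35:
            raise ValueError("nb_min_electrode_frac must lie in [0.20, 0.35]")


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times (s) over a recording of known duration."""

    trains: dict
    duration_s: float
    layout: dict | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        clean = {}
        for elec, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration_s):
                raise ValueError(f"spike times outside [0, duration] on {elec!r}")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times not strictly increasing on {elec!r}")
            clean[elec] = t
        self.trains = clean

    @property
    def electrodes(self) -> list:
        return list(self.trains)

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def pooled(self, electrodes=None) -> tuple[np.ndarray, np.ndarray]:
        """Merged spike times across electrodes with parallel electrode indices."""
        keys = self.electrodes if electrodes is None else list(electrodes)
        if not keys:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.concatenate([self.trains[k] for k in keys])
        labels = np.concatenate(
            [np.full(len(self.trains[k]), i) for i, k in enumerate(keys)]
        )
        order = np.argsort(times, kind="stable")
        return times[order], labels[order]

    def to_frame(self) -> pd.DataFrame:
        rows = [(e, t) for e, ts in self.trains.items() for t in ts]
        return pd.DataFrame(rows, columns=["electrode", "time_s"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration_s: float | None = None) -> "SpikeTrainSet":
        """Read a spike table with columns ``electrode,time_s``."""
        df = pd.read_csv(path)
        if duration_s is None:
            duration_s = float(df["time_s"].max()) if len(df) else 1.0
        trains = {
            e: np.sort(g["time_s"].to_numpy())
            for e, g in df.groupby("electrode", sort=True)
        }
        return cls(trains=trains, duration_s=duration_s)


@dataclass(frozen=True)
class BurstEvent:
    start_s: float
    end_s: float
    spike_count: int
    electrode: object = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class NetworkBurstEvent:
    start_s: float
    end_s: float
    spike_count: int
    electrodes: frozenset = field(default_factory=frozenset)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BurstStatistics:
    n_bursts: int
    mean_spikes_per_burst: float | None
    mean_duration_s: float | None
    mean_ibi_s: float | None
    frequency_per_min: float


def load_traces_h5(path, dataset: str = "voltage") -> tuple[np.ndarray, float]:
    """Read raw multi-electrode traces from HDF5.

    Expects a ``voltage[channels, samples]`` dataset carrying an ``fs_hz``
    attribute (on the dataset or the file root).  Returns
    ``(traces, fs_hz)`` ready for :func:`detect_spikes`.
    """
    import h5py

    with h5py.File(path, "r") as f:
        dset = f[dataset]
        fs = dset.attrs.get("fs_hz", f.attrs.get("fs_hz"))
        if fs is None:
            raise ValueError("missing fs_hz attribute in HDF5 file")
        return np.asarray(dset[()], dtype=float), float(fs)


def _noise_sd_per_window(v: np.ndarray, fs_hz: float, window_s: float) -> np.ndarray:
    """Per-sample robust noise SD, estimated as MAD/0.6745 in tiling windows."""
    n = v.size
    win = max(1, int(round(window_s * fs_hz)))
    n_win = int(np.ceil(n / win))
    sd = np.empty(n)
    for k in range(n_win):
        seg = v[k * win:(k + 1) * win]
        mad = np.median(np.abs(seg - np.median(seg)))
        sd[k * win:(k + 1) * win] = mad / MAD_TO_SD
    return sd


def detect_spikes(
    traces: np.ndarray,
    fs_hz: float,
    params: MEADetectionParams | None = None,
    electrodes=None,
) -> SpikeTrainSet:
    """Adaptive-threshold spike detection on raw voltage traces.

    ``traces`` is (n_electrodes, n_samples).  Per electrode, the noise SD is
    estimated robustly (MAD/0.6745) in ``noise_window_s`` windows; events are
    crossings of ``|v| > threshold_sd * SD`` with a dead time, and the spike
    time is the extremum of ``|v|`` within +/- ``align_window_s`` of the
    crossing.
    """
    params = params or MEADetectionParams()
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if fs_hz < 1000:
        raise ValueError("sample rate must be >= 1 kHz")
    if not np.all(np.isfinite(traces)):
        raise ValueError("trace contains non-finite values")
    n_elec, n_samp = traces.shape
    if electrodes is None:
        electrodes = list(range(n_elec))
    duration = n_samp / fs_hz
    dead = max(1, int(round(params.dead_time_s * fs_hz)))
    half = max(1, int(round(params.align_window_s * fs_hz)))
    trains: dict = {}
    for i, name in enumerate(electrodes):
        v = traces[i]
        sd = _noise_sd_per_window(v, fs_hz, params.noise_window_s)
        if np.all(sd == 0):
            warnings.warn(f"electrode {name!r}: constant trace, no spikes")
            trains[name] = np.empty(0)
            continue
        above = np.abs(v) > params.threshold_sd * sd
        crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
        spikes = []
        last = -dead - 1
        for c in crossings:
            if c - last <= dead:
                continue
            lo, hi = max(0, c - half), min(n_samp, c + half + 1)
            peak = lo + int(np.argmax(np.abs(v[lo:hi])))
            spikes.append(peak)
            last = peak
        trains[name] = np.unique(np.asarray(spikes, dtype=float)) / fs_hz
    return SpikeTrainSet(trains=trains, duration_s=duration)


def active_electrodes(
    spikes: SpikeTrainSet, params: MEADetectionParams | None = None
) -> set:
    """Electrodes firing at >= ``active_min_spikes_per_min`` (boundary inclusive)."""
    params = params or MEADetectionParams()
    minutes = spikes.duration_s / 60.0
    return {
        e for e, t in spikes.trains.items()
        if t.size / minutes >= params.active_min_spikes_per_min
    }


def weighted_mean_firing_rate(
    spikes: SpikeTrainSet, params: MEADetectionParams | None = None
) -> float:
    """Mean firing rate (Hz) over active electrodes only.

    Total spikes on active electrodes divided by (number of active
    electrodes x duration); 0 Hz with a warning when nothing is active.
    """
    params = params or MEADetectionParams()
    active = active_electrodes(spikes, params)
    if not active:
        warnings.warn("no active electrodes; weighted mean firing rate is 0")
        return 0.0
    total = sum(spikes.trains[e].size for e in active)
    return total / (len(active) * spikes.duration_s)


def detect_bursts(
    times: np.ndarray,
    params: MEADetectionParams | None = None,
    electrode=None,
) -> list[BurstEvent]:
    """Maximal runs of >= ``burst_min_spikes`` spikes with all ISIs <= ceiling."""
    params = params or MEADetectionParams()
    t = np.asarray(times, dtype=float)
    if t.size < params.burst_min_spikes:
        return []
    isi_ok = np.diff(t) <= params.burst_max_isi_s
    bursts = []
    run_start = 0
    for k in range(len(isi_ok) + 1):
        if k == len(isi_ok) or not isi_ok[k]:
            run_len = k - run_start + 1
            if run_len >= params.burst_min_spikes:
                bursts.append(BurstEvent(
                    start_s=float(t[run_start]), end_s=float(t[k]),
                    spike_count=int(run_len), electrode=electrode,
                ))
            run_start = k + 1
    return bursts


def burst_statistics(bursts: list[BurstEvent], duration_s: float) -> BurstStatistics:
    """Mean spikes/burst, duration, inter-burst interval, and bursts/min.

    The inter-burst interval (IBI) is start(k+1) - end(k); it is ``None``
    with fewer than two bursts.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = len(bursts)
    if n == 0:
        return BurstStatistics(0, None, None, None, 0.0)
    bursts = sorted(bursts, key=lambda b: b.start_s)
    ibi = None
    if n >= 2:
        ibi = float(np.mean([bursts[k + 1].start_s - bursts[k].end_s
                             for k in range(n - 1)]))
    return BurstStatistics(
        n_bursts=n,
        mean_spikes_per_burst=float(np.mean([b.spike_count for b in bursts])),
        mean_duration_s=float(np.mean([b.duration_s for b in bursts])),
        mean_ibi_s=ibi,
        frequency_per_min=n / (duration_s / 60.0),
    )


def detect_network_bursts(
    spikes: SpikeTrainSet, params: MEADetectionParams | None = None
) -> list[NetworkBurstEvent]:
    """Network bursts from the pooled spike train of active electrodes.

    Candidate events are maximal pooled-spike runs with pooled ISI <=
    ``burst_max_isi_s``; an event is kept when it contains >=
    ``nb_min_spikes`` spikes and at least ``nb_min_electrode_frac`` of the
    active electrodes contribute at least one spike within it (spike times
    grouped on the ``nb_bin_s`` coincidence grid).
    """
    params = params or MEADetectionParams()
    active = sorted(active_electrodes(spikes, params), key=repr)
    if len(active) < 2:
        return []
    times, labels = spikes.pooled(active)
    if times.size == 0:
        return []
    gaps = np.diff(times) > params.burst_max_isi_s
    boundaries = np.concatenate(([0], np.flatnonzero(gaps) + 1, [times.size]))
    events = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        count = b - a
        if count < params.nb_min_spikes:
            continue
        participants = np.unique(labels[a:b])
        frac = participants.size / len(active)
        if frac >= params.nb_min_electrode_frac:
            events.append(NetworkBurstEvent(
                start_s=float(times[a]), end_s=float(times[b - 1]),
                spike_count=int(count),
                electrodes=frozenset(active[i] for i in participants),
            ))
    return events


def _binned_counts(spikes: SpikeTrainSet, electrodes, bin_s: float) -> np.ndarray:
    n_bins = int(np.ceil(spikes.duration_s / bin_s))
    out = np.zeros((len(electrodes), n_bins))
    for i, e in enumerate(electrodes):
        t = spikes.trains[e]
        if t.size:
            idx = np.minimum((t / bin_s).astype(int), n_bins - 1)
            np.add.at(out[i], idx, 1)
    return out


def xcorr_area(
    spikes: SpikeTrainSet, params: MEADetectionParams | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled, peak-normalised inter-electrode cross-correlogram and its area.

    Spike counts are binned at ``nb_bin_s``; for every ordered electrode pair
    the cross-correlogram over lags ``|tau| <= xcorr_max_lag_s`` is
    normalised to unit peak, then averaged over pairs (pairs whose
    correlogram is identically zero, e.g. an electrode without spikes, are
    excluded).  Returns ``(lags_s, pooled_curve, trapezoidal_area)``.
    """
    params = params or MEADetectionParams()
    active = sorted(active_electrodes(spikes, params), key=repr)
    with_spikes = [e for e in active if spikes.trains[e].size > 0]
    if len(with_spikes) < 2:
        raise ValueError("need >= 2 active electrodes with spikes")
    counts = _binned_counts(spikes, with_spikes, params.nb_bin_s)
    max_lag = int(round(params.xcorr_max_lag_s / params.nb_bin_s))
    n_e, n_bins = counts.shape
    # C[i, j, l] = sum_t x_i(t) x_j(t + l) via one matmul per lag
    lags = np.arange(-max_lag, max_lag + 1)
    curves = np.zeros((n_e, n_e, lags.size))
    for li, lag in enumerate(lags):
        if lag > 0:
            c = counts[:, : n_bins - lag] @ counts[:, lag:].T
        elif lag < 0:
            c = counts[:, -lag:] @ counts[:, : n_bins + lag].T
        else:
            c = counts @ counts.T
        curves[:, :, li] = c
    pooled = np.zeros(lags.size)
    n_pairs = 0
    for i in range(n_e):
        for j in range(n_e):
            if i == j:
                continue
            peak = curves[i, j].max()
            if peak > 0:
                pooled += curves[i, j] / peak
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no electrode pair with overlapping activity")
    pooled /= n_pairs
    lag_s = lags * params.nb_bin_s
    area = float(np.trapezoid(pooled, lag_s))
    return lag_s, pooled, area


def synchrony_index(
    spikes: SpikeTrainSet, params: MEADetectionParams | None = None
) -> float | None:
    """Central-to-total area ratio of the pooled cross-correlogram, in [0, 1].

    The numerator integrates the pooled normalised correlogram over
    ``|tau| <= nb_bin_s``, the denominator over ``|tau| <= xcorr_max_lag_s``.
    Perfectly synchronous trains concentrate correlation mass at zero lag
    (index near 1); independent trains give a flat correlogram and an index
    near ``nb_bin_s / xcorr_max_lag_s``.  Returns ``None`` when fewer than
    two active electrodes carry spikes.
    """
    params = params or MEADetectionParams()
    try:
        lag_s, pooled, total_area = xcorr_area(spikes, params)
    except ValueError:
        return None
    if total_area <= 0:
        return 0.0
    central = np.abs(lag_s) <= params.nb_bin_s + 1e-12
    central_area = float(np.trapezoid(pooled[central], lag_s[central]))
    return float(np.clip(central_area / total_area, 0.0, 1.0))
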