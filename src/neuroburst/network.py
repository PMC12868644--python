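"""Rate-based Hebbian burst-network development simulator.

A recurrent network of ``n_units`` spontaneously bursting units is simulated
in 1-minute bins over many in-vitro "days".  Each unit generates bursts as a
Poisson process whose propensity (bursts/min) depends on the net recurrent
input,

    lambda_i(t) = lambda0 + beta * sum_j w_ij * r_j(t - 1),

where ``r_j`` is the firing rate of unit ``j`` in the previous bin (its burst
count divided by the bin width).  Once per day the symmetric weight matrix is
potentiated by a Hebbian rule proportional to the number of coincident burst
minutes,

    dw_ij = alpha * sum_t b_i(t) * b_j(t),      b_i(t) = 1{unit i burst in bin t},

and clipped to ``[weight_lo, weight_hi]``.  Connectivity is summarised as the
fraction of off-diagonal weights strictly above ``connection_threshold``, and
network bursting as the rate of bins in which at least one unit's net input
exceeds ``burst_input_threshold``.

The disomic (euploid, "D21") parameterisation uses a baseline propensity of
0.1 bursts/min; the trisomy-21 ("T21") parameterisation reduces it to 0.06
bursts/min with all other parameters identical, modelling a reduced intrinsic
propensity to burst.  Hebbian learning amplifies this small difference over
development: the disomic network saturates its connectivity while the
trisomic network does not.

Two per-bin sampling schemes are provided.  The default, ``"poisson"``, draws
true Poisson counts per bin and feeds the counts back as rates.  The
``"bernoulli"`` scheme thins each bin to a binary burst/no-burst draw with
probability ``lambda * dt`` and feeds back the indicator; it is retained so
the two readings can be compared, but it overshoots the trisomic connectivity
endpoint (the coincidence drive is identical but the recurrent drive
saturates differently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "NetworkState",
    "SimulationResult",
    "simulate_day",
    "hebbian_update",
    "connection_probability",
    "network_burst_rate",
    "run_simulation",
]

GENOTYPE_LAMBDA0 = {"d21": 0.1, "t21": 0.06}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the burst-network simulation.

    Defaults are the disomic (D21) parameterisation: 100 units, baseline
    burst propensity ``lambda0`` = 0.1 bursts/min, input gain ``beta`` = 0.01,
    Hebbian learning rate ``alpha`` = 3.45e-4 per coincident burst minute,
    1-min bins, 24 h per day, 100 days, weights bounded in [0, 1], a
    connection counted above weight 0.2 and a network-burst bin above net
    input 0.1.
    """

    n_units: int = 100
    lambda0: float = 0.1  # bursts/min (0.1 disomic, 0.06 trisomic)
    beta: float = 0.01  # propensity gained per unit of net input
    alpha: float = 0.000345  # weight increment per coincident burst minute
    dt: float = 1.0  # min
    minutes_per_day: int = 1440
    n_days: int = 100
    weight_lo: float = 0.0
    weight_hi: float = 1.0
    connection_threshold: float = 0.2
    burst_input_threshold: float = 0.1
    bin_model: str = "poisson"  # "poisson" (counts) or "bernoulli" (thinned)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.lambda0 < 0 or self.beta < 0 or self.alpha < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.lambda0 * self.dt <= 1.0:
            raise ValueError("lambda0 * dt must lie in [0, 1]")
        if not self.weight_lo < self.connection_threshold < self.weight_hi:
            raise ValueError(
                "connection_threshold must lie strictly inside the weight bounds"
            )
        if self.dt <= 0 or self.minutes_per_day <= 0 or self.n_days <= 0:
            raise ValueError("dt, minutes_per_day and n_days must be positive")
        if self.bin_model not in ("poisson", "bernoulli"):
            raise ValueError("bin_model must be 'poisson' or 'bernoulli'")

    @property
    def bins_per_day(self) -> int:
        return int(round(self.minutes_per_day / self.dt))

    @classmethod
    def for_genotype(cls, genotype: str, **overrides) -> "SimulationConfig":
        """Preset configs: ``"d21"`` (lambda0=0.1) or ``"t21"`` (lambda0=0.06)."""
        key = genotype.lower()
        if key not in GENOTYPE_LAMBDA0:
            raise ValueError(f"unknown genotype {genotype!r}; use 'd21' or 't21'")
        overrides.setdefault("lambda0", GENOTYPE_LAMBDA0[key])
        return cls(**overrides)


@dataclass
class NetworkState:
    """Weights, the last day's burst record, and the day counter.

    ``burst_indicators`` holds the binary burst-minute matrix of the most
    recently simulated day (units x bins); ``burst_counts`` the raw per-bin
    event counts (identical to the indicators under the Bernoulli scheme).
    """

    weights: np.ndarray
    burst_indicators: np.ndarray | None = None  # (n_units, bins) uint8
    burst_counts: np.ndarray | None = None  # (n_units, bins) int
    day: int = 0

    @classmethod
    def initial(cls, cfg: SimulationConfig) -> "NetworkState":
        return cls(weights=np.zeros((cfg.n_units, cfg.n_units)), day=0)

    def validate(self, cfg: SimulationConfig) -> None:
        w = self.weights
        if w.shape != (cfg.n_units, cfg.n_units):
            raise ValueError("weight matrix shape mismatch")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-connections must stay zero")
        if w.min() < cfg.weight_lo or w.max() > cfg.weight_hi:
            raise ValueError("weights out of bounds")


@dataclass
class SimulationResult:
    """Per-day trajectories and final state of :func:`run_simulation`."""

    config: SimulationConfig
    connectivity_by_day: np.ndarray
    network_burst_rate_by_day: np.ndarray
    per_day_burst_counts: np.ndarray  # (n_units, n_days) burst events per day
    final_state: NetworkState = field(repr=False)

    @property
    def final_connectivity(self) -> float:
        return float(self.connectivity_by_day[-1])


def simulate_day(
    state: NetworkState, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[NetworkState, np.ndarray]:
    """Simulate one day of bursting; weights are frozen within the day.

    Returns the state with the day's burst record attached, plus the per-bin
    net-input matrix ``u_i(t) = sum_j w_ij r_j(t)`` (shape
    ``(n_units, bins)``), where ``r_j(t)`` is the bin's firing rate in
    bursts/min.  The propensity in bin ``t`` uses the previous bin's rates
    (one-bin delay; same-bin dependence would be circular), and the rates are
    zero at the start of the day.
    """
    if state.day >= cfg.n_days:
        raise ValueError("simulation already ran for n_days")
    w = state.weights
    n, bins = cfg.n_units, cfg.bins_per_day
    bernoulli = cfg.bin_model == "bernoulli"
    indicators = np.empty((n, bins), dtype=np.uint8)
    counts = np.empty((n, bins), dtype=np.int64)
    net_input = np.empty((n, bins))
    u_prev = np.zeros(n)
    for t in range(bins):
        lam = cfg.lambda0 + cfg.beta * u_prev
        if np.any(lam < 0):
            raise ValueError("negative burst propensity: invalid parameterisation")
        if bernoulli:
            p = np.clip(lam * cfg.dt, 0.0, 1.0)
            n_events = (rng.random(n) < p).astype(np.int64)
        else:
            n_events = rng.poisson(lam * cfg.dt)
        counts[:, t] = n_events
        indicators[:, t] = n_events > 0
        # u(t) doubles as the recurrent drive for bin t+1: one matvec per bin
        u_prev = w @ (n_events / cfg.dt)
        net_input[:, t] = u_prev
    return (
        NetworkState(weights=w, burst_indicators=indicators,
                     burst_counts=counts, day=state.day),
        net_input,
    )


def hebbian_update(state: NetworkState, cfg: SimulationConfig) -> NetworkState:
    """Apply the once-per-day Hebbian step and advance the day counter.

    The increment for pair (i, j) is ``alpha`` times the number of bins in
    which both units burst; the result is clipped to the weight bounds, the
    diagonal forced to zero, and symmetry preserved (the coincidence count
    is symmetric).
    """
    if state.burst_indicators is None:
        raise ValueError("no burst indicators: run simulate_day first")
    b = state.burst_indicators.astype(np.float64)
    coincidences = b @ b.T  # exact: integer-valued sums of 0/1 products
    w = state.weights + cfg.alpha * coincidences
    np.clip(w, cfg.weight_lo, cfg.weight_hi, out=w)
    np.fill_diagonal(w, 0.0)
    return NetworkState(weights=w, burst_indicators=state.burst_indicators,
                        burst_counts=state.burst_counts, day=state.day + 1)


def connection_probability(state: NetworkState, cfg: SimulationConfig) -> float:
    """Fraction of off-diagonal weights strictly above the connection threshold."""
    n = state.weights.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")
    off = ~np.eye(n, dtype=bool)
    return float(np.mean(state.weights[off] > cfg.connection_threshold))


def network_burst_rate(net_inputs: np.ndarray, cfg: SimulationConfig) -> float:
    """Events/min: fraction of bins where any unit's net input exceeds threshold."""
    if net_inputs.size == 0:
        raise ValueError("empty net-input matrix")
    hot = net_inputs.max(axis=0) > cfg.burst_input_threshold
    total_minutes = net_inputs.shape[1] * cfg.dt
    return float(hot.sum() / total_minutes)


def run_simulation(cfg: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Alternate daily simulation and Hebbian learning for ``cfg.n_days``.

    Starts from all-zero weights.  ``seed`` overrides ``cfg.seed``; the run
    is bit-identical for a given seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    state = NetworkState.initial(cfg)
    connectivity = np.empty(cfg.n_days)
    nb_rate = np.empty(cfg.n_days)
    burst_counts = np.empty((cfg.n_units, cfg.n_days), dtype=np.int64)
    for d in range(cfg.n_days):
        state, net_inputs = simulate_day(state, cfg, rng)
        nb_rate[d] = network_burst_rate(net_inputs, cfg)
        burst_counts[:, d] = state.burst_counts.sum(axis=1)
        state = hebbian_update(state, cfg)
        connectivity[d] = connection_probability(state, cfg)
    return SimulationResult(
        config=cfg,
        connectivity_by_day=connectivity,
        network_burst_rate_by_day=nb_rate,
        per_day_burst_counts=burst_counts,
        final_state=state,
    )
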