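# Methods notes

## Burst-network development model

The simulator models a culture of `n_units` (default 100) recurrently
coupled, spontaneously bursting units over developmental time. Time is
discretised into 1-minute bins, 1440 bins per simulated day, 100 days by
default. In each bin, unit *i* emits bursts as a Poisson count

> Nᵢ(t) ~ Poisson(λᵢ(t) · dt),  λᵢ(t) = λ₀ + β · Σⱼ wᵢⱼ · rⱼ(t−1)

where rⱼ(t−1) = Nⱼ(t−1)/dt is the previous bin's firing rate in bursts/min
(zero at the start of each day; same-bin dependence would be circular).
Once per day the symmetric weight matrix receives a Hebbian potentiation
proportional to the number of *coincident burst minutes*,

> Δwᵢⱼ = α · Σₜ bᵢ(t) · bⱼ(t),  bᵢ(t) = 1{Nᵢ(t) ≥ 1},

after which weights are clipped to [0, 1] and the diagonal is forced to
zero. Defaults: λ₀ = 0.1 bursts/min (disomic) or 0.06 (trisomic),
β = 0.01 per unit of net input, α = 3.45 × 10⁻⁴ per coincident minute.
Two summary trajectories are recorded per day: the *connection
probability* (fraction of off-diagonal weights strictly above 0.2,
computed after the day's weight update) and the *network-burst rate*
(fraction of bins in which at least one unit's net input
uᵢ(t) = Σⱼ wᵢⱼ rⱼ(t) exceeds 0.1).

### Why counts for the drive and indicators for the plasticity

The model admits several self-consistent discretisations, and the developed
trisomic connectivity discriminates sharply between them because the weight
distribution at day 100 straddles the 0.2 threshold (mean ≈ 0.21,
SD ≈ 0.01 — a few percent change in accumulated drive sweeps the whole
distribution across the threshold). We examined three readings:

1. *Thinned Bernoulli* (at most one burst per bin with p = λ·dt, the
   indicator used both for plasticity and for the recurrent drive): the
   trisomic network ends at connectivity ≈ 0.999, indistinguishable from
   the disomic one. Retained as `bin_model="bernoulli"` for comparison.
2. *Exact bin probability* (p = 1 − e^(−λ·dt)): trisomic ≈ 0.73.
3. *Poisson counts* with the rate (counts/min) as the recurrent drive and
   the burst-minute indicator as the plasticity signal: trisomic ≈ 0.78,
   disomic = 1.0 — a clear genotype separation with the trisomic plateau
   below saturation. This is the default (`bin_model="poisson"`): it
   simulates the stated Poisson process faithfully, feeds back the actual
   firing rate, and uses the binary burst indicator where "coincidence" is
   the biological notion being modelled.

Consequences for closed-form checks: with zero weights the per-unit daily
burst-event count is Poisson(1440·λ₀) (the thinned variant gives
Binomial(1440, λ₀·dt)), and with β = 0 the expected daily weight increment
is α·1440·(1 − e^(−λ₀·dt))². Both are asserted in the test suite.

Because increments are non-negative and clipping only acts from above, the
connectivity trajectory is monotone non-decreasing — asserted per run. The
network-burst rate is bounded by 1 event/min by construction (it counts
qualifying bins); both genotypes saturate this bound once weights mature,
so the genotype difference appears in the *timing* of the sigmoidal rise
(disomic saturates by ~day 10, trisomic by ~day 30), and "dominance" of
the disomic trajectory is evaluated with ≥ on the per-day rates.

The network-burst criterion reads "net input of at least one unit exceeds
threshold"; the population-mean alternative was considered and rejected as
it never crosses 0.1 in the early regime where the two genotypes differ.

Runtime: one full-scale run (100 units × 100 days) takes ~3.5 s; the
40-run acceptance sweep ~2.5 min on one CPU.

## MEA metrics

Noise is estimated per electrode in 1-s tiling windows as MAD/0.6745
(robust to spike contamination); spikes are |v| crossings of 6 estimated
SDs with 1 ms dead time, each aligned to the extremum within ±0.5 ms. At
that threshold the Gaussian false-positive rate is negligible (< 0.1
spikes/s tested on pure noise).

Single-electrode bursts are maximal runs of ≥ 5 spikes with every ISI
≤ 100 ms; the detector is verified exactly against an O(n²) run-enumeration
oracle. Network bursts pool spikes of active electrodes (≥ 5 spikes/min,
boundary inclusive) and keep maximal pooled runs with pooled ISI ≤ 100 ms,
≥ 50 spikes and ≥ 25% of active electrodes contributing a spike (the
participation fraction is configurable within 20–35%). The vendor
algorithms these parameters come from are unpublished, so this is an
interpretation constrained by the stated parameters; it recovers ≥ 95% of
planted population events at the generator defaults with ≤ 1 false event
per 10 minutes on independent sparse Poisson trains.

The synchrony index is defined here as the central-to-total area ratio of
the pooled, per-pair peak-normalised cross-correlogram of 20-ms binned
counts (central window |τ| ≤ 20 ms, total |τ| ≤ 1 s), clipped to [0, 1].
Identical trains give 1; a flat correlogram gives bin/lag = 0.02. The
published index this stands in for is cited without a formula; ours
satisfies the same bounds and ordering (synchronised > jittered >
independent, checked over seeds).

Weighted mean firing rate is total spikes on active electrodes divided by
(active electrode count × duration) — the standard vendor definition; the
boundary electrode at exactly 5 spikes/min is included in both numerator
and denominator.

## Patch-clamp analyses

* **Capacitance**: C = Q/|ΔV| with Q the integral of the
  steady-state-subtracted current transient after a −10 mV test pulse
  (pA·s ≡ pC; pC/mV ≡ nF). Recovers a forward-modelled RC cell within 5%.
* **Boltzmann fits** use `scipy.optimize.curve_fit` with slope-sign-aware
  initial guesses, so rising (activation) and falling (inactivation)
  curves both fit; the exponent is clipped at ±700 to avoid overflow.
  At noise SD 0.02 with 15 voltages, V₅₀ is recovered with < 0.5 mV bias
  and k_m within 10% (100-seed means).
* **Weighted decay**: mono- and bi-exponential models are fitted from the
  peak with non-negative amplitudes and the winner chosen by corrected AIC
  (the combination rule is otherwise unspecified);
  t_w = (A₁t₁ + A₂t₂)/(A₁ + A₂) uses the fitted component amplitudes as
  weights (the common amplitude-weighted convention; the equal-component
  arithmetic — A₁ = A₂, t₁ = 2, t₂ = 4 → 3 ms — is identical under the
  area-weighted alternative).
* **EPSC detection** is amplitude-threshold based (default 3 × noise SD)
  on a lightly smoothed trace (1-ms boxcar) with a 10–90% rise-time
  ceiling of 5 ms to reject slow events; template matching is out of
  scope. At the default multiple, occasional noise crossings are accepted
  as false positives; recall on planted events ≥ 8 SDs is ≥ 96%.
* **Voltage-clamp bursts**: a 50-ms median filter removes fast synaptic
  events before the > 8 pA, ≥ 2 s gate; amplitude is the filtered peak
  while charge integrates the raw trace over the event (trapezoid on the
  uniform grid, so a rectangular deflection yields exactly
  amplitude × duration).
* **AP metrics**: threshold is the first point before the peak where
  dV/dt ≥ 20 V/s (configurable; the criterion itself is a lab convention),
  amplitude = peak − threshold, rise time 10–90%, T50 from peak to half
  amplitude, area integrates V − threshold between threshold crossings,
  latency is threshold time from step onset and jitter its coefficient of
  variation (population SD / mean — the convention that makes latencies
  (9, 10, 11) ms give 0.0816). Rheobase is found by coarse ascending steps
  plus integer bisection on a 1-pA grid.
* **A-current**: pointwise subtraction of the depolarised-prepulse sweep
  from the hyperpolarised-prepulse sweep, normalised by capacitance;
  antagonist sensitivity is (1 − drug/control) × 100. HCN sag is trough
  minus steady state (final 10% of the step), reported ≥ 0.

## Differential-expression screen

Windows are consecutive stage triples with stride one (nine stages →
seven windows). Within a window, every complete DS/control pair
contributes one log2 difference per gene; significance is a two-tailed
paired t-test and the flag requires both |FC| ≥ 1.3 (i.e. |mean log2
diff| ≥ log2 1.3, boundary inclusive) and p < 0.01 on the raw p value.
Degenerate genes (zero-variance differences) take p = 1 when the mean
difference is zero. BH-FDR q values are computed per window when
requested but do not alter the flag, mirroring a headline raw-p screen
with FDR reported "where necessary". Under a global null with 10⁴ genes
the flagged fraction stays below 0.01 (the FC gate makes the combined
rule conservative); a planted two-fold gene with five pairs at noise
SD 0.1 is flagged in ≥ 99% of seeds.

ΔCT relative expression is 2^(−(CT_target − CT_reference)); group
comparisons are ratios of group means of the relative values.

## Synthetic data

The spike-train generator is a doubly stochastic Poisson construction:
per-electrode background Poisson trains (default 0.1 Hz — sparse
baseline activity) superposed with Poisson-timed population bursts
(default 2/min, 0.3 s long, 60% participation, 100 Hz within-burst rate
per participating electrode, 5 ms onset jitter) across a 64-electrode
array for 10 min, matching the recording geometry and duration the MEA
stage targets. It satisfies the detectors' assumptions but does not model
development, refractoriness, electrode cross-talk or distance-dependent
correlations — passing tests demonstrate detector correctness, not
biological realism.

Raw traces insert a biphasic template (negative-leading,
derivative-of-Gaussian shape, ~1 ms) at each spike time into Gaussian
noise; amplitude/noise sets the SNR. The current-clamp generator is
template-based: a sub-criterion approach ramp (10 V/s) meets a fast rise
at the nominal threshold voltage so waveform metrics are exact by
construction, the passive response saturates below threshold, and spike
count saturates to emulate single/double/multiple spikers. The EPSC
generator convolves Poisson event times with a linear-rise/bi-exponential
kernel whose analytic weighted decay is carried in the ground truth.
Expression matrices draw control samples around per-gene baselines
(log2 scale) and add the planted log2 FC plus independent pair noise to
the matched DS sample.

All generators are deterministic given a seed, and each emits its planted
schedule/parameters for self-audit in the tests.

## Known limitations

* The burst-network model is a phenomenological rate model: no inhibition,
  no spiking dynamics, no weight depression; the connectivity endpoint is
  sensitive to the bin-sampling convention (see above), which is why the
  alternative convention is kept available and falsified rather than
  deleted.
* The MEA network-burst and synchrony definitions are reconstructions from
  stated parameters, not re-implementations of the (unpublished) vendor
  algorithms.
* EPSC detection trades precision for simplicity at the default 3-SD
  threshold; raise the multiple or the smoothing window for noisy data.
* The screen assumes complete pairs within each window and excludes genes
  with missing values per window rather than imputing.
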