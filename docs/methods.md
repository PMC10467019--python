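# Methods

## The experimental paradigm

Every analysis in this package operates on the same paradigm: a 2500 ms
current-clamp injection of frozen noise — i.i.d. Gaussian samples convolved
with a 3 ms square kernel, rescaled so the delivered sample SD is exactly
0.04 nA — plus a tonic DC offset chosen so the neuron emits roughly 12–15
spikes per record (a ~5 Hz mean rate, in the theta range).  The same set of
noise realizations (trial *i* uses seed `base_seed + i`) is reused across
conditions, so that the only differences between conditions are the
h-current conductance and the compensating DC.

Design choices in the stimulus generator: the amplitude rescaling is applied
*after* the convolution, so the SD of the delivered current is exact by
construction; the square kernel has unit area (irrelevant after rescaling,
but it fixes the zero-variance edge case where the trace is just the DC);
the Gaussian draw is extended by one kernel width and only fully-supported
convolution samples are kept, so no edge taper enters the record.

DC calibration in `stimgen.calibrate_dc` bisects on the DC for a single
frozen noise, as the in-vitro protocol would.  The protocol layer instead
calibrates against the *mean* spike count over the first five trial noises
(`protocol.calibrate_dc_mean`): a single 2.5 s realization carries a ±3
spike realization bias, and calibrating on one noise can leave conditions
firing at systematically different rates, which confounds every
cross-condition comparison.

## The synthetic neuron

`neuron_sim` implements a single-compartment conductance-based neuron,

    C dV/dt = I_inj − Σ_c gbar_c · m_c^p · h_c · (V − E_c),

with first-order Boltzmann gates (steady state `1/(1+exp(−(V−V½)/k))`,
Gaussian-bump voltage-dependent time constants) integrated by exponential
Euler for the gates and forward Euler for the voltage at dt = 0.025 ms.
Positive current is outward.  The discrete current balance
`C·ΔV/Δt + ΣI_c = I_inj` holds to machine precision by construction, and
the test suite verifies it on every simulation.

The default ("human-like") channel set, with C = 0.2 nF:

| channel | gbar (µS) | E (mV) | gating |
|---|---|---|---|
| NaT    | 4.0    | +50 | m³h; act V½ −38, k 6, τ ≲ 0.1 ms; inact V½ −60, k −7, τ ≤ 6.5 ms |
| Kfast  | 3.0    | −85 | n⁴; V½ −30, k 9; deactivation τ ≈ 6 ms near −75 mV |
| Kslow  | 0.001  | −90 | n; V½ −40, k 5, τ 80 ms (negligible by default) |
| cation | 0.0015 | 0   | ohmic background cation conductance |
| leak   | 0.004  | −90 | ohmic |
| Ih     | 0.07   | −45 | m; V½ −74, k −5 (opens with hyperpolarization); τ(V) peaking at 400 ms near −80 mV, ~50 ms when depolarized |

The `rodent_like` preset is identical except that the h-gate time constant
peaks at ~40 ms instead of ~400 ms.  `scale_channel` produces the
h-conductance conditions (0, 0.5, 1, 2 × default).

These values are implementation defaults, not fits to any published model.
They were chosen so that the preset expresses, at the paradigm's noise level
and firing rate, the phenomena the analyses are designed to measure:

- a **slow membrane** (τ_m ≈ 30–50 ms at rest) so that low-frequency
  components of the filtered noise dominate the subthreshold voltage;
- a **subthreshold resonance** generated by the h-current: its steep,
  hyperpolarized activation curve makes the gate respond strongly to
  post-spike dips while contributing little resting conductance, giving a
  resonant feedback conductance comparable to the total passive conductance
  and a transfer-function peak at 3–5 Hz;
- a **deep but brief afterhyperpolarization** (strong Kfast with fast
  deactivation) so that, without the h-current, recovery is quick relative
  to the interspike interval and firing stays irregular rather than
  clock-like;
- an **inward-current mix**: the background cation conductance carries part
  of the subthreshold inward current, so the h-current's *percentage*
  contribution has genuine dynamics (with a single subthreshold inward
  current it would be pinned at 100%).

Intrinsic properties of the default preset (computed by
`intrinsic_properties`): resting potential −58 mV with the h-current vs
−65 mV without, input resistance 75 vs 184 MΩ, sag ratio 0.45 vs ~0 —
the classic h-current signature (depolarized rest, lower input resistance,
sag), with the caveat that the synthetic cell rests closer to threshold
than typical pyramidal neurons.

Numerical details: a 200 ms settling period at the stimulus's first sample
precedes every record and is discarded; gate states start at their steady
state for `v_init` (−70 mV); integration aborts with a diagnostic if |V|
exceeds 200 mV.  Halving dt changes a 500 ms *subthreshold* trajectory by
less than 0.5 mV (sup-norm); for spiking records a sup-norm bound is not
meaningful because a sub-sample shift of one spike produces an O(100 mV)
pointwise difference, so convergence is asserted on the subthreshold
trajectory.

## Gain estimation

The frequency-dependent gain is `G(f) = |C_sr(f)|/|C_ss(f)|` with
`c_sr(τ) = ⟨s(t) r(t+τ)⟩`, `c_ss(τ) = ⟨s(t) s(t+τ)⟩`, r(t) the binary
firing-rate series (1/Δt at spike samples, Δt the stimulus sample interval)
and s(t) the mean-subtracted stimulus.  G is evaluated on the standard grid
1.0, 1.2, …, 30.0 Hz (146 points).

Estimator choices, all in `fdg.compute_fdg`:

- **Biased correlations** (divide by N); the constant cancels in the ratio.
- **Bartlett lag window**, half-width 500 ms by default, applied to both
  correlation functions before transforming (Blackman–Tukey estimation).
  Without it the single-realization ratio is ill-behaved: wherever the
  noise realization's |S(f)| has a deep null, G(f) spikes, and per-trial
  min-max normalization then maps such spikes to 1.0 and plants spurious
  peaks in trial-averaged curves.  The Fejér kernel of the triangular
  window keeps the autospectrum non-negative, fills the nulls, and trades
  ~2 Hz of frequency resolution for a large variance reduction.  Analyses
  that need sharper resolution can pass a larger `max_lag_ms`.
- **Zero padding to a whole number of 5 s blocks** so the native FFT bin
  spacing divides 0.2 Hz and the grid is evaluated without interpolation.
- The stimulus mean (the DC offset) is removed before correlation — the
  padded records would otherwise leak the 0 Hz term into the 1 Hz end of
  the grid — while r(t) is used raw, and no taper is applied to the data.

Averaging dialects: `average_fdg_insilico` is the plain pointwise mean over
trial curves (used for the deterministic model, where each trial is a
different noise); `average_fdg_invitro` averages trials within a neuron
first and then across neurons with equal weight (average of averages), with
optional per-neuron min-max normalization before the second average.
Normalization of simulated ensembles is per-trial, then averaged, so the
normalized average does not itself range over [0, 1].

`compare_pointwise` replaces an omnibus two-factor analysis with the
simplest defensible pointwise procedure: a two-sample t-test at each of the
146 grid frequencies with Bonferroni correction across the grid.  A planted
10-SD offset at a single frequency is detected exactly, and the family-wise
error rate is verified ≤ 0.07 by simulation.

## Decomposition and spike-triggered averages

`percent_contributions` classifies each membrane current sample by sign
(negative = inward), and expresses each current as a percentage of its
class total at that time step.  The injected current is excluded; the leak
is included by default (`include_passive`); exactly-zero samples belong to
neither class, and samples where a class total is zero carry a
defined=False mask rather than NaNs.  Class sums equal 100 at every defined
sample to 1e-6, and the decomposition is invariant to scaling all currents.

STAs average a signal over windows `[t_spike − w, t_spike]` (right edge at
the threshold-crossing sample, inclusive) for **isolated** spikes only: no
earlier spike within the window and a full window of recorded data (spikes
too close to the record start are dropped rather than padded).  Trials are
averaged with equal weight and the SD band is the across-trial SD.  For
percentage contributions, a channel is averaged in its dominant class over
the analyzed windows; samples where that class is undefined are excluded
with per-lag renormalization by the count of defined samples.

Monotonicity of an STA trace: normalize by the window maximum (outward) or
minimum (inward), resample to a 1 ms grid, smooth with a centered 5-point
moving average whose edge windows shrink symmetrically, difference, and
report the fractions of negative / positive / exactly-zero difference
quotients.  The 1 ms resampling is deliberate: on the raw 0.025 ms
integration grid the sign of the difference quotient is dominated by
discretization noise and the fractions collapse toward 0.5 regardless of
the trace's shape; 1 ms matches the time scale of the averaged contribution
dynamics while leaving 200 samples per 200 ms window.  Exactly-zero
differences are reported separately as `fraction_flat` rather than folded
into either side.

## The protocol and what it shows

`run_protocol` runs the four h-conductance conditions with paired noise
(identical trial seeds) and per-condition DC calibration, then aggregates
per-condition reports: raw and normalized gain ensembles and averages, peak
lists (default prominence 0.1 in normalized units, chosen ≈3× the
point-wise SEM of a 30-trial normalized average), pooled ISI CV,
per-channel contribution STAs at 30/100/200 ms with monotonicity, and
variability summaries.  Trials with fewer than two spikes are excluded and
reported; more than 50% exclusions abort the condition.

At the default study conditions (30 trials, base seed 100) the synthetic
neuron reproduces the central h-current phenomenology:

- the normalized average gain of the default model has a low-frequency peak
  (~3 Hz) that is absent, at the same prominence threshold, when the
  h-conductance is zeroed at matched firing rate;
- the h-current's inward-percentage STA over the 200 ms before spiking is
  non-monotonic — rising while the membrane dips, falling into the spike —
  and the fraction of the window over which it decreases shrinks
  monotonically as the h-conductance grows (halved > default > doubled);
- the rodent-like preset (fast h-kinetics) shows no sub-10 Hz peak with or
  without the h-current.

One reported phenomenon is **not** reproduced: the ordering of interspike-
interval variability between the zero-conductance and default conditions.
In this point-neuron preset the pooled ISI CV of the default condition
(~1.15) is not lower than that of the h-free condition (~1.1); among the
conditions that retain the h-current the CV does fall monotonically with
conductance (halved > default > doubled), but zeroing the conductance
removes the resonant spike-clustering altogether and yields a CV below the
halved condition rather than above the default one.  The mechanism is
visible in the ISI histograms: theta-resonant locking in this small model
concentrates spikes on crests of the band-passed noise, producing
within-crest clusters that inflate the CV, whereas the detailed
multi-compartment models this preset stands in for carry additional
afterhyperpolarization machinery (SK-type and slow potassium currents)
that suppresses those clusters and lets the resonance regularize firing.
Reproducing the CV ordering therefore appears to require more biophysical
machinery than this deliberately minimal preset contains; the corresponding
test is left failing rather than tuned away, and the CV values themselves
are reported by the acceptance script.

## What the generator does and does not emulate

The synthetic model emulates the *statistical structure* the analyses
assume: noisy-input-driven spiking at ~5 Hz, a subthreshold-active slow
inward current with switchable kinetics, labeled per-current traces, and
paired-noise conditions at matched rate.  It does not emulate
multi-compartment morphology, calcium dynamics or calcium-activated
channels, the full ten-current repertoire of detailed cortical models, or
pharmacological blockade (zeroing a conductance has no secondary effects).
Passing tests on the synthetic model therefore validate the *pipeline* —
estimators, decomposition, statistics and orchestration — and the
qualitative h-current phenomenology listed above, not quantitative
properties of any real neuron; quantitative application to detailed models
goes through the trace-table adapter (`import_neuron_export`).

## Problem sizes and tolerances

Default runs use 30 trials × 2.5 s at dt = 0.025 ms (100k steps per trial)
per condition; the full four-condition protocol is ~130 simulations
including calibration.  The estimator oracle check runs on 10⁴-sample
records (relative agreement < 1e-6; observed ~1e-14).  The phase-locking
check averages 20 trials per frequency at 10 grid frequencies.  CV-test
calibration uses 500–1000 null replicate pairs of n = 40 normal samples
(the asymptotic test's distributional assumption; under skewed gamma
intervals the test is conservative, rejecting at ~2% for nominal 5%).
Decomposition conservation is exact to 1e-6 of a percentage point;
reconstruction of absolute currents from percentages is exact to 1e-9 nA.
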