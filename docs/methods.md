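# Methods

This note documents the models, numerical choices and limitations behind
`chancoupler`. The package infers ion-channel subunit stoichiometry and
tests for cooperative ("coupled") gating of channel pairs; every analysis
is paired with a synthetic-data generator that emulates the statistical
structure the analysis assumes, so correctness is established on data with
known ground truth.

## Gating simulation (`synthgen.simulate_sweeps`)

Each protomer of a channel pair is a three-state continuous-time Markov
chain C ⇌ O → I (closed, open, inactivated) with rate constants
`rate_co`, `rate_oc`, `rate_oi`, `rate_ic` in ms⁻¹. No experimental kinetic
scheme is available for the target channel at single-channel resolution, so
this is the smallest scheme with an activation pathway and absorbing
inactivation. Two parameter regimes are provided:

* default ("−20 mV-like"): (k_CO, k_OC, k_OI, k_IC) = (0.5, 0.1, 2.0, 0) ms⁻¹
  — openings cluster early after the step and inactivate quickly;
* `MODEL_MINUS40` ("−40 mV-like"): (0.05, 0.1, 0.5, 0) ms⁻¹ — sparse,
  scattered, later openings.

Per sweep, the dimer is drawn *coupled* with probability φ
(`coupling_fraction`). A coupled dimer evolves as **one** chain whose open
state conducts 2·i; an independent pair as **two** independent chains each
conducting i when open. This makes the concerted case produce direct
closed ↔ double-conductance transitions and never dwell at the single-open
level, while the independent case reaches the double level only by stacking
two openings — exactly the observable dichotomy the coupled-opening
classifier targets. Both conditions share identical per-protomer marginal
kinetics, so their ensemble-average (macroscopic) currents coincide; the
tests verify this at Monte-Carlo precision.

Trajectories are simulated event-by-event with exponential waiting times
(Gillespie), then discretized to the 30 kHz sample grid: each sample carries
the conductance level occupying the majority of its interval (ties toward
the lower level). No anti-alias/Bessel filter is emulated — filtering is an
acquisition detail, and the 0.2 ms segmentation (6 samples) dominates the
effective time resolution. Gaussian current noise of SD `noise_sd` is added
after discretization.

Defaults i = −1.5 pA and noise_sd = 0.15 pA are plausible for a
high-Na⁺-pipette cell-attached recording and are configuration parameters,
not assumptions baked into any analysis. The per-protomer master equation
(matrix exponential of the 3-state generator) serves as an independent
oracle in the tests: with φ = 0, P(level ≥ 1)(t) = 1 − (1 − p_O(t))².

## Idealization and coupling classification (`singlechannel`)

`estimate_levels` builds the pooled all-points amplitude histogram. The
baseline is the sample median (the patch is closed most of the time),
the noise scale is the MAD-based robust SD, and openings are samples beyond
a 3σ exclusion band on the signal-polarity side. The two most populated
local modes of the open-amplitude histogram give i1 and i2 (each refined as
the mean of its assigned samples, so noiseless data are recovered exactly);
if only one open mode exists, i2 = 2·i1 is extrapolated under the dimer
assumption and flagged.

`idealize` cuts each sweep into fixed 0.2 ms segments, assigns every sample
to the nearest of {baseline, i1, i2} and labels the segment with the
majority sample label; all ties break toward the lower level, and a trailing
partial segment is dropped. On a segment occupied by a single level this is
identical to nearest-level assignment of the segment mean; on mixed boundary
segments the majority vote is used because it agrees exactly with the
ground-truth majority label on noiseless data (a segment-mean rule would
mislabel boundary mixes between 50% and 75% double-level occupancy as
level 1). At the default noise (0.15 pA vs. 1.5 pA level spacing) individual
sample misassignment is negligible (≈ 6·10⁻⁷ per sample).

`extract_events` scans the label sequence: an event opens at the first
nonzero label after a closed segment and closes at the next closed segment.
Classification:

* **coupled** — the event reaches level 2 within the coupling window,
  read inclusively as a 0-based offset ∈ {0, 1, 2} segments (0.4 ms);
* **uncoupled_stacked** — level 2 reached later; tallied downstream as two
  level-1 openings (at the event onset and where the second channel joined),
  since non-simultaneous double occupancy is two independent openings, not a
  concerted one;
* **single** — the event never leaves level 1.

Events truncated by sweep end keep their classification and carry a
`truncated` flag. The package assumes exactly one channel pair per record;
patches with more channels are out of scope.

## Photobleaching step counting (`stoichiometry.detect_steps`)

Step detection is greedy binary change-point segmentation of the intensity
trace: repeatedly insert the change point giving the largest reduction in
the residual sum of squares of a piecewise-constant fit, stopping when the
BIC — N·ln(RSS/N) + (m+1)·ln N for m change points (one mean per added
segment plus a shared variance) — stops improving. RSS is floored at 10⁻¹²
so noiseless staircases terminate cleanly. Downward steps are then filtered
by size: only drops of at least `min_step_fraction` (default 0.5) times the
unit-step estimate are retained. The unit step is the median retained drop,
iterated to a fixed point starting from the largest drop; starting from the
largest drop rather than the raw median keeps a handful of small spurious
drops from defining the unit on molecules with few true steps. Upward steps
(blinking recovery) are ignored rather than counted negatively.

A globally optimal dynamic-programming search under the same BIC
(`exhaustive_changepoints`) is shipped as an independent reference; on
noiseless staircases of ≤ 30 frames greedy and exhaustive searches agree
exactly, and under 10% noise their filtered step counts agree on ≥ 90% of
traces (at 30 frames the BIC penalty ln N is weak, so both searches place
extra change points in pure noise, in different but equally admissible ways).

At the standard study conditions (dimer, p = 0.7, bleach rate 0.2 s⁻¹,
0.1 s frames, 30 s traces, noise 10% of the unit step) detection recovers
the true step count for ≈ 99% of detectable molecules. The residual errors
are molecules whose two fluorophores bleach within ≲ 2 frames of each other
(one double-height drop) — an intrinsic resolution limit of frame-based
change-point counting.

## Stoichiometry inference

`fit_subunit_count` maximizes the multinomial log-likelihood of the detected
step counts under P(k | n, p, k ≥ 1) = C(n,k)p^k(1−p)^{n−k} / (1−(1−p)^n)
over candidate n from the largest observed k to `n_max`; ties break toward
the smaller n. The maturation probability p defaults to 0.7 and is held
fixed — it is a property of the fluorophore, measured independently of the
channel under study. The likelihood conditions on detection because dark
molecules are never selected as spots; unconditional tallies exist only for
simulated populations, where `step_histogram` routes zero-step molecules to
`n_undetected`.

`fit_binomial_exponent` compares y = (1−x)^n for n ∈ {1, 2, 3} by weighted
least squares (weights 1/sem² when sem > 0, else 1). All three candidates
have the same number of free parameters (none), so RSS and AIC order
identically; AIC is reported for transparency. A continuous exponent on
[0.5, 5] is fitted by bounded 1-D minimization as a plausibility check. The
fit is scale-free: normalization to the x = 0 reference removes the current
scale.

`bleach_time_stats` summarizes bleaching kinetics by molecule class; for two
independent fluorophores with rate k_b the first-step time is the minimum of
two exponentials (mean 1/(2k_b)) and the total bleach time has mean
1/(2k_b) + 1/k_b = 3/(2k_b). Real GFP populations show rate heterogeneity
that stretches total bleach times beyond this two-exponential prediction;
the generator does not model that heterogeneity.

## Gating curves and FRET (`biophys`)

* **Boltzmann fits** use `scipy.optimize.least_squares` with tolerances
  10⁻¹² and data-driven initialization: V₁/₂ at the voltage nearest
  half-range, |k| = (V₈₀% − V₂₀%)/2.2, signed by the monotonic direction
  (Spearman ρ). A single signed-k form covers activation (k > 0) and
  availability/SSI (k < 0). Non-monotone data warn but still fit.
* **Decay fits** start at the peak sample and fit a biexponential with
  log-linear split initialization (slow τ from the tail, fast from the
  head); τ_f ≤ τ_s is enforced by swapping, and sign-inconsistent
  amplitudes on a monotone decay trigger a single-exponential fallback with
  τ_s reported absent.
* **Conductance transform**: G = I/(V − E_rev) with E_rev linearly
  interpolated from the zero crossing on the outward limb when requested
  (`auto`); the V = E_rev point is excluded and the curve normalized by
  max |G|.
* **Independent-channels null**: Y_mix = w·Y_a + (1−w)·Y_b of the two
  fitted component curves, default w = 0.5 ("averaging"); the weight is
  exposed because co-expression need not produce equal functional
  populations. Averaging fitted curves (not raw data) is the package's
  choice. `coupling_deviation` reports RMS and maximum deviation from the
  null on the overlapping grid (linear interpolation across grids) and
  names the nearer single-component curve.
* **FRET**: FRETc = FRET − a·CFP − b·YFP with defaults a = 0.29, b = 0.04;
  linear, not clipped. `acceptor_photobleach_stat` summarizes per-ROI donor
  dequenching as percent increase with a two-sided paired t-test (chosen as
  the conventional paired comparison; a Wilcoxon variant is easy to add but
  not currently exposed). For true FRET efficiency E the expected increase
  is 100·E/(1−E).

## Synthetic-data scope

The generators emulate: two-protomer Markov gating at 30 kHz under
step protocols (holding −100 mV, test −40/−20 mV, 100-sweep episodic
acquisition), binomially censored photobleaching staircases with exponential
bleach times, binomial dominant-negative suppression with Gaussian noise,
and Boltzmann gating data. They do **not** emulate: fluorophore blinking or
background drift (available as future options; the analyses assume monotone
staircases), voltage-dependent rate constants, capacitance transients,
filter ringing, baseline drift, or patches holding more than one channel
pair. Passing tests therefore demonstrate correctness of the analysis chain
under the stated statistical assumptions, not robustness to every artifact
of real recordings.

## Problem sizes and determinism

Test and acceptance computations use 300–6,000 sweeps, 100–2,000 traces and
10⁵-molecule count draws — sizes at which every Monte-Carlo check holds at
≥ 5σ against its analytic oracle while the whole suite runs in well under a
minute of simulation time. Every stochastic routine takes an explicit
integer seed feeding a `numpy.random.default_rng`; identical (parameters,
seed) pairs give bit-identical outputs, and the pipeline runner requires an
explicit seed in its configuration and echoes it in the run report.

## Conventions

Sample index 0 is the step onset; segment index 0 is the first full segment;
all intervals are half-open [start, end). Inward current is negative.
Time is ms for sweeps and s for bleach traces; intensities are arbitrary
units; tables round-trip at 6 significant digits.
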