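# chancoupler

Quantitative tools for asking whether ion-channel α-subunits assemble and
gate as **dimers**, built around the analysis chain used for voltage-gated
sodium channels (Na_v1.5-like): single-molecule photobleaching step counting,
dominant-negative binomial dose–response fitting, single-channel idealization
with a coupled-opening classifier, whole-cell gating-curve fits, and FRET
crosstalk correction. Every analysis ships with a matched synthetic-data
generator, so the full pipeline is testable end to end without any recordings.

## The models at the core

**Dominant-negative binomial analysis.** If subunits assemble randomly into
an *n*-mer and a single non-conducting mutant subunit silences the complex,
the normalized peak current at mutant cDNA fraction *x* is

    y = (1 − x)^n

so a monomer decays linearly (*n* = 1), a dimer as (1 − x)², a trimer as
(1 − x)³. `stoichiometry.fit_binomial_exponent` selects *n* ∈ {1, 2, 3} by
weighted least squares (and optionally a continuous exponent).

**Photobleaching step counting (SiMPull).** A surface-immobilized *n*-mer
tagged with GFP shows *k* ~ Binomial(*n*, *p*) bleaching steps, where
*p* ≈ 0.7 is the probability a GFP is fluorescently mature. Dark molecules
(*k* = 0) are never spotted, so `stoichiometry.fit_subunit_count` maximizes
the multinomial likelihood of the detected counts under

    P(k | n, p, k ≥ 1) = C(n,k) p^k (1−p)^(n−k) / (1 − (1−p)^n)

Steps are found by greedy binary change-point segmentation with BIC stopping
(`detect_steps`), checked in the tests against an exhaustive dynamic-program
search. For a dimer at *p* = 0.7, 49% of all molecules show exactly two steps.

**Coupled gating.** A patch holding a channel pair shows conductance levels
0, i, 2i. Records are cut into 0.2 ms segments, each labelled with the
nearest level, and an opening is *coupled* when it reaches the double level
within 0.4 ms (two segments) of onset — the signature of a dimer gating as
one concerted unit. Later double-level arrivals are *uncoupled stacking* of
two independent openings and are tallied as two level-1 openings. The
`synthgen` simulator draws each sweep's dimer coupled with probability φ and
evolves C⇌O→I Markov chains by exponential waiting times.

**Gating curves.** Activation and steady-state inactivation are fitted to a
Boltzmann function Y = 1/(1 + exp(−(V − V₁/₂)/k)) (negative *k* for
availability curves); current decay to A_f e^(−t/τ_f) + A_s e^(−t/τ_s) + C;
the independent-channels null for a co-expressed pair is the average of the
two fitted single-population curves (`biophys.independent_mixture`).

**FRET.** Sensitized-emission crosstalk correction
FRETc = FRET − a·CFP − b·YFP with a = 0.29, b = 0.04.

## Worked example

```python
from chancoupler import synthgen as sg, singlechannel as sc, stoichiometry as st

# dominant-negative curve generated under the dimer model, then fitted
dr = sg.simulate_dose_response(n=2, ratios=[0, 1/11, 1/5, 1/2, 4/5, 10/11, 1],
                               noise_sd=0.02, seed=1)
fit = st.fit_binomial_exponent(dr)
print(fit.n_best, round(fit.n_continuous, 2))

# coupled vs independent gating, classified from simulated sweeps
for phi in (1.0, 0.0):
    model = sg.GatingModel(coupling_fraction=phi, **sg.MODEL_MINUS40)
    sweeps = sg.simulate_sweeps(model, sg.StepProtocol(n_sweeps=600), seed=21)
    params = sc.IdealizationParams()
    levels = sc.LevelEstimate(baseline=0.0, i1=-1.5, i2=-3.0)
    events = sc.extract_events(sc.idealize(sweeps, levels, params), params)
    print(phi, events.counts())
```

prints

```
2 2.02
1.0 {'single': 0, 'coupled': 560, 'uncoupled_stacked': 0}
0.0 {'single': 1051, 'coupled': 11, 'uncoupled_stacked': 26}
```

— the noisy dimer dose–response is recognized as a dimer (best integer
exponent 2, continuous exponent ≈ 2), and with full coupling (φ = 1) every
double-level event opens simultaneously, while independent pairs (φ = 0)
produce mostly single openings whose rare double-level episodes are
predominantly non-simultaneous stacking.

There is also a CLI mirroring the library (`chancoupler simulate-dn`,
`dn-fit`, `idealize`, `events`, `bleach-steps`, `stoich-fit`, `boltzmann`,
`decay`, `fret`, `run`, …); see `chancoupler --help`.

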