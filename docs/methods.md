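# Methods

## System and model

The modelled system is a closed, well-mixed vessel of simulated intestinal
fluid (volume `V_w`, ~80 mL after lipase addition) containing olive oil
(~0.088 kg/L) as digestible food, mixed micelles of sodium taurocholate
plus liberated free fatty acids (baseline 5.7 g/L), LDPE strips
(~8.8 g/L, ten strips) as the microplastic, and optionally a POM passive
sampler.  Chemicals are hydrophobic organics indexed by their
octanol–water partition coefficient; every partition coefficient and rate
constant is tied to `log K_OW` through log-linear free-energy
relationships.

Two concentration bases are used and always documented: the
*system-volume* basis (µg of chemical per litre of whole system) and the
*solid-phase* basis (µg per kg of a solid phase, written with a star).
They convert through the phase mass concentration (kg/L).  The
closed-system invariant is that the summed system-basis concentrations of
water, micelle, oil, POM and LDPE equal the total concentration at every
instant, once chemical carried out by sampled strips is counted.

### Partition estimation

At equilibrium each solid phase obeys `C*_phase = K_phase · C_w`.  The
sampler reading gives `C_w = C*_POM/K_POM`, and the closed-system balance
`C_init = C_w (1 + K_POM[POM] + K_micelle[micelle] + K_oil[oil])` is
solved for the single unknown coefficient per experiment.  The oil vials
also contain the baseline bile-salt micelle pool; its contribution is
netted out using the pooled micelle regression (the choice of pooled
rather than per-level values is a convention; both are available).
Negative inversion results — possible under measurement noise — are
flagged, never clipped, so that noisy synthetic studies remain
diagnosable.  Serum albumin is not a modelled sorbing phase; any sorption
to it is absorbed into the operational `K_micelle`.

### Digestion kinetics

Liberated FFA follows the saturating first-order form
`[FFA](t) = FFA_max(1 − e^(−k_FFA t))` (µM, hours), the unique
first-order model with exponential approach to a finite limit.  Shipped
parameter sets: high enzyme `FFA_max = 10.53 µM, k_FFA = 0.079 h⁻¹`; low
enzyme `1.18 µM, 1.22 h⁻¹`.  The low-enzyme rate constant is poorly
identified by a schedule whose first post-zero observation is at 2 h
(its fitted half-rise is already over by then); the package reproduces
this behaviour — refits return the value with a large standard error —
rather than reinterpreting it.

Compartment coupling: micelle mass grows by `[FFA]·MW_FFA·10⁻⁹` kg/L and
oil shrinks by `([FFA]/3)·MW_oil·10⁻⁹` kg/L (three fatty acids per
triglyceride).  `MW_FFA` defaults to oleic acid (282.46 g/mol, the
dominant olive-oil acid) and `MW_oil = 3·MW_FFA + 38.05` (glycerol
backbone minus three waters); both are overridable.  A pH-based FFA proxy
(one proton per liberated FFA, no buffering correction) is provided, with
direct FFA tables preferred for inference.

FFA fitting initialises at the observed plateau and half-rise time with a
small multi-start grid fallback; an all-zero series is reported as
degenerate (amplitude 0, rate unidentifiable) instead of returning an
arbitrary rate.

### Exchange model

Water, micelles, oil and POM equilibrate much faster than the polymer and
are lumped into one pool mass; the dissolved concentration is
`C_w = f_w(t)·m_pool/V_w` with
`f_w = 1/(1 + K_micelle[micelle]_t + K_oil[oil]_t + K_POM[POM])`.
LDPE exchange is biphasic.  The fast reservoir (fraction `f1` of
plastic-bound chemical) follows
`dm_fast/dt = k1 f_w m_pool − k2 m_fast` with the rate constants acting
on system-volume concentrations — this basis matches rate magnitudes
spanning ~10² to ~10⁷ h⁻¹ across the hydrophobicity range and makes the
whole-polymer distribution coefficient `K_p = (k1/k2)/([LDPE]·f1)`.
The slow intrapolymer reservoir (default rate ln2/20 d) is frozen over
72 h digestion scenarios — its half-life is two orders above the
experiment duration — and can be enabled for multi-week scenarios, with
closure `dm_slow/dt = k3((1−f1)/f1 · m_fast − m_slow)` (slow tracks the
fast reservoir's equilibrium share).

Initial conditions anchor either on a day-28 sampler reading
(`C_w = C*_POM/K_POM`, micelle/oil loads from their coefficients, LDPE
from a measured t = 0 strip concentration or the k1/k2 equilibrium) or on
a total concentration (full equilibrium partitioning).  Lipase addition
(10 mL into ~70 mL) is a step dilution at t = 0: masses conserved, volume
and phase concentrations scaled by the configured factor (default 8/7).
The POM sampler is collected before lipase addition, so `[POM] = 0`
during digestion by default.

Strip sampling is a discrete event: each removal takes `1/n` of the LDPE
mass and of its chemical load (strips assumed identical), leaving
solid-basis concentrations continuous while system-basis concentrations
drop.  Emulsion sampling (~1 % of volume) is neglected.  One consequence
of the constant-`k1` basis is that removing plastic raises the
solid-basis equilibrium concentration of the remainder (the same
system-basis equilibrium mass spreads over fewer kilograms); trajectories
therefore keep rising across removal events while mass balance holds
exactly.

Numerics: LSODA with relative tolerance 10⁻⁸ and mass-scaled absolute
tolerance; removal times are segment boundaries forced onto the solver
mesh, so stored values are independent of the output grid; a state stored
exactly at a removal time is the post-event state.  Mass conservation
along simulated trajectories is at machine precision (~10⁻¹⁶ relative).

### Inference

`(k1, k2)` are fitted per congener time series by bounded nonlinear least
squares in log10 space (`log10 k1 ∈ [0, 9]`, `log10 k2 ∈ [−4, 2]`),
unweighted residuals in µg/kg, with the t = 0 observation anchoring the
LDPE boundary condition and the day-28 sampler reading anchoring the
dissolved pool.  A heuristic start (near-equilibrium amplitude, k2 ~
1 h⁻¹) is accepted when it converges away from the bounds; otherwise a
five-point multi-start grid is scanned.  Standard errors come from the
Gauss–Newton covariance in log space, delta-transformed; significance
stars are Wald tests and presentation-only.  Flat (equilibrium) series
are flagged: only the `k1/k2` ratio is identified.  Replicate vessels are
fitted independently and summarised.

## Synthetic data: what it emulates and what it does not

The generators reproduce the experimental design: 10 congeners evenly
spaced over `log K_OW` 5.24–8.18 with spikes drawn uniformly from
30–124 µg/L; partition vials at surfactant levels 5.7/6.9/11.6/64.5 g/L
and oil levels 1.3/6.3/12.6 g/L in quadruplicate; digestion-phase
sampling (one strip removed) at 0, 2, 4, 6, 8, 10, 24, 48, 72 h.  Truth
relations default to the pooled study regressions (micelle slope 0.99,
intercept 0.61; oil 0.85/2.21; high-enzyme `k1` 1.04/−3.01; low-enzyme
1.21/−4.28).  Since desorption showed no usable hydrophobicity trend,
truth `k2` is a constant per enzyme level (1.0 h⁻¹ high, 0.15 h⁻¹ low,
inside the observed ranges 0.283–4.36 and 0.087–0.289 h⁻¹).

Choices a real dataset would pin down instead:

* **K_POM calibration.**  The POM–water relation is a literature input;
  the shipped default (`log K_POM = log K_OW − 1`) is an explicit
  stand-in of typical magnitude.  All round-trip results are invariant to
  it because generation and inversion share the value.
* **f1 and k3** come from prior characterisation of the same strips and
  are not re-estimated here; defaults `f1 = 0.5`, `k3 = ln2/(20 d)`
  (midpoint of the reported 13–32 d half-life range).  Over 72 h the
  trajectories are insensitive to both.
* **Initial disequilibrium.**  Observed digestion-phase uptake is driven
  by the plastic starting below its sorption equilibrium (it held only
  0.2–4 % of total chemical after pre-incubation).  The generator starts
  the fast reservoir at 10 % of its post-dilution k1/k2 equilibrium,
  which reproduces that loading regime; it is a scenario parameter
  (`ldpe_start_fraction`), not an estimate.
* **Noise.**  Multiplicative mean-one lognormal (CV 0.10 default, a
  placeholder — replicate scatter is not reported) on concentration
  readings; additive Gaussian (sd 0.2 µM) floored at zero on FFA series.
  Lognormal noise keeps concentrations positive by construction.

Passing round-trip tests therefore demonstrate correctness of the
estimators under the model's own assumptions (no model error, known
anchors, exchange truly rate-limited by the plastic); they do not
demonstrate that fitted constants from a real vessel are unbiased under
model misspecification, nor do they reproduce scenario metrics that
depend on the measured day-28 state.

## Problem sizes

Defaults used by the drivers and suite: 10 congeners, 280 partition
vials, nine-point kinetic schedules, 100-replicate noise studies for
recovery summaries, 200-replicate FFA refit studies.  These sizes give
stable medians and percentile statements while keeping any single command
in the seconds-to-minutes range.

## Known limitations

* Enzyme-activity modelling (Michaelis–Menten, lipase inhibition by
  plastic) is out of scope; digestion enters only through the fitted
  first-order FFA curve.
* Micelle absorption across the gut lumen, multi-segment GI transit and
  particle translocation are not modelled; the vessel is closed.
* The pH→FFA proxy ignores buffering, as in the assay it mirrors.
* `K_p` inherits the exact algebraic convention `(k1/k2)/([LDPE]·f1)`;
  with time-varying `[LDPE]` (strip sampling) it is reported at the
  initial plastic concentration.
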