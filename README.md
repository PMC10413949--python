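# gutflux

Toxicokinetic modelling of hydrophobic organic chemicals (HOCs) exchanging
between microplastic and the other compartments of a simulated gut fluid
while food lipids are digested.

## The problem

When an organism ingests both contaminated food and contaminated
microplastic, lipid digestion changes the sorption capacity of the gut
content: triglycerides are hydrolysed to free fatty acids (FFA), the oil
pool shrinks, and the mixed-micelle pool (bile salt + FFA) grows.
Chemicals released from the digested food repartition among water,
micelles, oil and plastic.  Because plastic is not absorbed across the gut
lining, any chemical it sequesters is egested — microplastic can act as a
sink that *reduces* chemical bioavailability.  `gutflux` implements the
full quantitative chain needed to study this in a batch gut-fluid system
with PCB-like chemicals, LDPE strips as the plastic, olive oil as the
food, and a POM passive sampler as the dissolved-phase probe:

1. **Partition estimation** (`gutflux.partitioning`).  In a closed vial
   the mass balance on the system-volume basis is
   `C_init = C_w (1 + K_POM[POM] + K_micelle[micelle] + K_oil[oil])`,
   with `C_w = C*_POM / K_POM` read from the passive sampler.  Inverting
   it per vial yields `K_micelle` and `K_oil` (L/kg), which are regressed
   as `log10 K = a·log K_OW + b`.
2. **Digestion kinetics** (`gutflux.digestion`).  Liberated FFA follows
   `[FFA](t) = FFA_max (1 − e^(−k_FFA t))`; micelle and oil mass
   concentrations follow stoichiometrically (three FFA per triglyceride).
3. **Exchange simulation** (`gutflux.exchange`).  Water, micelles, oil
   and POM equilibrate instantly into one pool; the rate-determining step
   is biphasic exchange with LDPE,
   `dC_LDPE,fast/dt = k1 C_w − k2 C_LDPE,fast`, with
   `C_w = f_w(t)·(pool mass)/V_w` and
   `f_w = 1/(1 + K_micelle[micelle]_t + K_oil[oil]_t + K_POM[POM])`.
   Scheduled strip removals are discrete events.  Scenario metrics:
   solid-basis concentration fold increase and percent of total gut
   chemical newly sequestered by plastic.
4. **Inference** (`gutflux.inference`).  `(k1, k2)` are fitted per
   congener by nonlinear least squares in log10 space against observed
   `C*_LDPE(t)`; the plastic–water distribution coefficient follows as
   `K_p = (k1/k2)/([LDPE]·f1)`, and `k1`, `k2`, `K_p` are regressed
   against `log K_OW`.
5. **Synthetic data** (`gutflux.synthetic`).  Seeded generators produce
   complete partition and digestion-phase experiments with known truth,
   so every estimator is testable end to end with no external data.

## Worked example

```sh
python analysis/01_partition_coefficients.py
```

```
280 vials inverted (0 flagged inconsistent under noise)
pooled micelle regression: log K_micelle = 0.994 logKow + 0.582 (r2=0.998, n=160) [truth 0.99 / 0.61]
pooled oil regression:     log K_oil     = 0.832 logKow + 2.329 (r2=0.987, n=120) [truth 0.85 / 2.21]
```

280 synthetic sampler readings (10 congeners × 7 phase-concentration
levels × 4 replicates, 10 % multiplicative noise) were inverted through
the closed-system mass balance; the refitted pooled regressions recover
the generating slopes/intercepts to within a few percent, i.e. the
passive-sampler inversion is unbiased at realistic noise.  The remaining
drivers follow the same pattern: `02` fits lipolysis parameters (the
low-enzyme rate constant comes back with a large standard error — it is
genuinely poorly identified by a schedule with no observations before
2 h), `03` simulates digestion-phase exchange under strip-sampling vs
plastic-retained scenarios, and `04` recovers the rate-constant
regressions from noisy time series.  Outputs land in `results/`.

## Layout

```
src/gutflux/        library (all computation)
analysis/           numbered narrative drivers writing results/
scripts/acceptance.py   headline-number reproduction
tests/              pytest suite (unit, property, end-to-end)
docs/methods.md     model description, assumptions, design choices
```
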