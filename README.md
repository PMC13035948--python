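# migsim

Simulation-based **spatial goodness-of-fit testing for origin–destination
flow models**, built for migration research but applicable to any bilateral
flow system (trade, commuting, mobility networks).

## The problem

Flow regressions — gravity models and their richer descendants — are
routinely judged by explanatory power: pseudo-R², significance of drivers.
Those metrics say nothing about whether the *spatial structure* the model
implies resembles the observed system: are flows as concentrated in a few
corridors as in reality, and as reciprocal? A model can fit bilateral flows
well on average and still imply a migration system nobody would recognise.
`migsim` tests exactly that, in four steps:

1. **Estimate** a Poisson pseudo-maximum-likelihood (PPML) flow regression

   *E*[y<sub>ijt</sub>] = exp(α<sub>i</sub> + γ<sub>j</sub> + δ<sub>t</sub> + **β**′**x**<sub>ijt</sub>),

   with origin, destination and year fixed effects and multiway
   (inclusion–exclusion) clustered standard errors, plus RESET and
   pseudo-R² diagnostics.

2. **Simulate** an ensemble of *S* complete synthetic flow systems: for each
   dyad, draw y\*<sub>ij</sub> ~ TN(ŷ<sub>ij</sub>, σ<sub>ij</sub>²; a, b),
   a truncated normal around the fitted flow with σ recovered from the
   fitted flow's confidence interval, truncated at zero. Optionally each
   simulated matrix is row-calibrated so every origin's outflow total
   matches the observed one.

3. **Summarise** each system with four spatial indices — the aggregate
   coefficient of variation (ACV), the corridor Gini index, the migration
   inequality index (deviation from a uniform corridor distribution), and
   reciprocity, the share of movers matched by a counter-flow,
   Σ min(m<sub>ij</sub>, m<sub>ji</sub>) / Σ m<sub>ij</sub>.

4. **Evaluate**: does each observed index fall inside the simulated
   envelope? How far is each location's observed inflow profile from the
   simulated cloud, measured by the Mahalanobis distance
   D² = (**x** − **μ**)′ **Σ**⁻¹ (**x** − **μ**) with μ, Σ the ensemble
   mean and (shrinkage-regularised) covariance? Which individual corridors
   escape the simulated range?

A known-truth synthetic generator (log-linear Poisson panels with
geography-like dyadic covariates, plus a "reciprocity regime" in which
corridors are more two-way than any multiplicative model can represent)
makes the whole pipeline testable without external data.

## Worked example

```python
import migsim as ms

truth = ms.SyntheticTruth(seed=42)                 # 15 locations x 5 years
panel = ms.generate_panel(truth)                   # Poisson flows, known beta
spec = ms.ModelSpec(
    predictors={"log_distance": "none", "tie": "none", "log_ratio": "none"},
    fixed_effects=("origin", "destination", "year"),
    clusters=("origin", "destination", "year"),
)
model = ms.fit_ppml(panel, spec)
stats = ms.fit_statistics(model)

ens = ms.simulate_ensemble(model, panel, ms.SimulationConfig(S=500, seed=7))
report = ms.evaluate_system(panel, ens)
```

Output (truth: β = −0.8, +0.5, +0.4):

```
log_distance  -0.7920  (se 0.0045)
tie           +0.5064  (se 0.0080)
log_ratio     +0.3870  (se 0.0088)
squared correlation    0.9965
adjusted pseudo-R2     0.9535
within adj. pseudo-R2  0.8307
RESET p                0.4433
```

The estimates recover the truth; RESET does not reject the specification;
`ms.effect_size(model.params["tie"], "exponential")` reports that tied
dyads have 65.9% larger flows. The evaluation table then places every
observed index inside its simulated envelope for this correctly specified
model, e.g. for 2002:

```
      index  year  observed  env_min  env_max  sim_mean  inside
        acv  2002    0.8419   0.8400   0.8500    0.8449    True
       gini  2002    0.5180   0.5175   0.5198    0.5186    True
 inequality  2002    0.3852   0.3848   0.3875    0.3863    True
reciprocity  2002    0.5420   0.5401   0.5447    0.5425    True
```

Under the misfit regime (`ms.generate_reciprocity_regime(truth, 9.0)`),
the same pipeline flags the signature the method exists to detect:
observed reciprocity rises above the simulated envelope while the three
concentration indices remain covered — high statistical fit, wrong
spatial structure.

The same workflow is available from the shell:

```bash
migsim synth --locations 15 --years 2002:2006 --seed 7 --out-flows flows.csv
migsim fit --flows flows.csv --spec spec.yaml --out model.json
migsim evaluate --flows flows.csv --spec spec.yaml --s 1000 --seed 42 \
    --report report.json
```

## Documentation

`docs/methods.md` documents the model and its assumptions, the simulation
and evaluation machinery, the synthetic data generator, numerical choices
and known limitations.
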