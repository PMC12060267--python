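# aq-accountant

Accountability analysis of air-quality regulations: estimate what
source-apportioned PM2.5 concentrations **would have been without
emission controls**, using only observations, emission inventories, and
statistical source–receptor modelling.

Regulatory programs (power-plant SO2/NOx caps, vehicle emission
standards) are credited with large reductions in fine-particle
exposure, but the counterfactual — air quality had the rules never
existed — is unobservable. This package implements the standard
receptor-model accountability chain:

1. **Source apportionment.** Uncertainty-weighted positive matrix
   factorization (PMF) decomposes a speciated concentration matrix
   X (day × species) with paired measurement uncertainties S into
   nonnegative source contributions G and profiles F by minimizing

       Q = Σᵢⱼ ((Xᵢⱼ − (G F)ᵢⱼ) / Sᵢⱼ)²

   with optional dispersion normalization (rescaling each day by a
   ventilation proxy so factors track emissions rather than mixing).

2. **Source–emission modelling.** Each factor's daily contribution is
   modelled by a Gaussian additive model with penalized cubic
   regression splines,

       y_t = a + Σⱼ fⱼ(x_jt) + day-of-week + month + e_t,

   on sector emissions and meteorology, with concurvity-screened
   feature selection, GCV-chosen smoothing, 10-fold cross-validation
   (R², mean bias, RMSE) and permutation variable importance.

3. **Counterfactual calibration.** With observed meteorology held
   fixed, the emission impact and calibrated counterfactual per factor
   are

       EI_t = I_GAM,counterfactual(t) − I_GAM,actual(t)
       CI_t = max(0, I_PMF(t) + EI_t)

   so the counterfactual is anchored to the observed (PMF)
   contributions and additive model bias cancels.

4. **Uncertainty.** Monte Carlo sampling of the counterfactual
   emission trajectories plus ±2·SE model uncertainty, combined by
   root-sum-square into 95% bands.

Because the real speciation-network and inventory feeds are not
redistributable, the package ships a first-class synthetic-data module
(`aq_accountant.synth`) that generates complete worlds — seasonal
AR(1) meteorology, stepwise-regulated factual vs. uncontrolled
counterfactual emissions, nonnegative source contributions with known
responses, and a speciated matrix with an EPA-style uncertainty model —
in which the true counterfactual is known exactly, so every stage is
verifiable offline.

## Worked example

```bash
aq-accountant run --config examples/demo.yaml
```

simulates a four-year world (2005–2008), apportions it with PMF
(4 factors, 5 random starts), fits one spline GAM per factor, removes
all emission controls, and propagates uncertainty (200 draws). The run
prints `pipeline complete` and writes, among others, `ratios.csv`:

```
factor,factual_mean,counterfactual_mean,ratio,undefined
secondary_nitrate,1.7028,3.9378,2.3126,False
diesel_vehicles,3.5926,2.9433,0.8193,False
gasoline_vehicles,1.8472,2.0504,1.1100,False
secondary_sulfate,2.0547,4.2827,2.0843,False
total,9.1973,13.2142,1.4367,False
```

(values abbreviated to 4 decimals): in the final simulated year,
secondary nitrate would have averaged 3.94 µg/m³ without controls
versus 1.70 µg/m³ with them — a factor of 2.3 — and total
source-apportioned PM2.5 would have been 1.44× higher. Early-period
worlds like this show smaller ratios than a full 15-year history, since
most regulatory steps have not yet bitten. `percent_uncertainty.csv`
reports the half-width of the combined 95% band as a percentage of
each factor's counterfactual annual mean (20–57% here), and
`cv_report.csv` the 10-fold out-of-fold R² per factor (0.69–0.78 in
this run).

Every stage is also callable as a library:

```python
from aq_accountant import WeightedPMF, SplineGAM, generate_world

world = generate_world(n_days=3653, seed=7)
pmf = WeightedPMF(n_factors=4, n_random_starts=10, seed=0).fit(world.speciation)
G, F = pmf.model_.G, pmf.model_.F
```

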