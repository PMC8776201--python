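# glucodyn

Bayesian calibration and structure selection for ordinary-differential-
equation models of the glucose homeostasis system in type 1 diabetes.

Blood-glucose regulation in an insulin-dependent (type 1) diabetic can be
described by small compartmental ODE models, but competing structures exist:
should a model carry an explicit pancreatic β-cell compartment when the
disease is defined by the destruction of those cells? `glucodyn` implements
the full workflow a modeller needs to answer that question from short
blood-glucose time series: simulate the candidate models, generate
realistic synthetic "virtual mouse" datasets, calibrate either model with a
delayed-rejection adaptive-Metropolis (DRAM) sampler under a Gaussian error
model with conjugate error-variance sampling, and compare structures via
AIC/BIC differences. It is aimed at systems-biology and biostatistics
practitioners studying glucose–insulin dynamics, and doubles as a compact,
fully tested reference implementation of Bayesian ODE calibration.

## The models

Both candidates track insulin *I* (mIU/mL), glucose *GL* (mg/dL) and growth
hormone *GH* (mIU/mL) in time *t* (min), sharing

```
dGL/dt = a − (b + c·I)·GL + c·GH        dGH/dt = ρ − w·GH
```

**Model 1** (no β-cells; insulin only from a constant subcutaneous bolus I0):

```
dI/dt = ψ·I0·I/(1 + I) − δ·I
```

**Model 2** (with a β-cell mass β, mg, secreting insulin sigmoidally):

```
dβ/dt = (h·GL − i·GL² − g)·β        dI/dt = β·d·GL²/(e + GL²) − f·I
```

Calibration varies {δ, ψ} for Model 1 and {a, b, f, i} for Model 2
(uniform priors on bound boxes), with the error precision σ⁻² given a
conjugate Gamma prior so the posterior
p(θ | y, σ²) ∝ exp(−½·SS(θ)/σ²)·p(θ) can be explored with exact σ²
updates; credible intervals are 2.5%/97.5% chain quantiles. Structures are
compared with AIC = n·ln(SS/n) + 2k and BIC = k·ln(n) + n·ln(SS/n) and the
conventional |Δ| ≥ 2 evidence threshold. See `docs/methods.md` for the
complete statistical specification.

## Worked example

Calibrate the β-cell-free model to a hyperglycaemic virtual mouse (seven
noisy observations generated from known parameters δ = 0.025, ψ = 0.02):

```python
import glucodyn as gd

preset = gd.severity_preset("hyperglycaemic")
data = gd.generate_preset_dataset("hyperglycaemic", noise_sd=10.0, seed=1)

est = gd.GlucoseModelCalibrator(model_id=1, fixed_params=preset.params,
                                init_state=preset.init, chain_length=20_000,
                                random_state=1)
est.fit(data.times, data.glucose)
print(est.summary_.round(4))
```

which prints

```
       median   lower   upper
delta  0.0242  0.0188  0.0303
psi    0.0196  0.0174  0.0223
```

Both 95% credible intervals cover the generating values; the posterior
medians land within ~3% (ψ) and ~3% (δ) of truth. The chain reports
`acceptance: 0.844`, a best sum of squares `SS_min: 375.66` (seven points at
noise SD 10 mg/dL), effective sample sizes near 2,850 and no convergence
flags (`est.diagnostics_`). Information criteria for this fit are
AIC = 31.88, BIC = 31.77 (Gaussian-profile scale, k = 2).

The same workflow from the shell, for all four severity presets and both
models, with plots and a selection report:

```
glucodyn run --profiles hyperglycaemic,hypoglycaemic,moderate,controlled \
             --chain-length 20000 --seed 1 --outdir results/run
```

`results/run/selection_report.tsv` then holds one row per dataset with
AIC/BIC per model, ΔAIC = AIC₂ − AIC₁, ΔBIC, and an "equally capable" /
"substantial difference" verdict; `fit_*.png` show the data, the median
model projection and the 95% credible band.

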