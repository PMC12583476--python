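# mesbi — simulation-based inference for middle-ear model tuning

`mesbi` infers subject-specific tissue parameters of a mechanistic
middle-ear model from acoustic measurements, using amortized
simulation-based inference (SBI). It is aimed at auditory-biomechanics
researchers who tune lumped or finite-element middle-ear models against
wideband tympanometry and stapes-velocity data and want posterior
distributions — not hand-tuned point values — for the tissue properties.

## The model and the inference problem

A deterministic surrogate simulator maps seven parameters

| parameter | meaning | prior range |
|---|---|---|
| `e_drum` | eardrum Young's modulus (MPa) | 1–20 |
| `e_sal` | stapes annular ligament modulus (MPa) | 0.005–1 |
| `e_mallear` | mallear ligament modulus (MPa) | 1–10 |
| `e_soft` | suspensory ligaments/tendons modulus (MPa) | 1–10 |
| `e_joint` | ossicular joints modulus (MPa) | 1–10 |
| `damping` | structural loss factor η (–) | 0.05–0.2 |
| `cochlear_load` | cochlear acoustic resistance (GΩ) | 3–30 |

to three measured spectra on 50 log-spaced frequencies (250–8000 Hz):
normalized stapes velocity V_st/P_ec, ear-canal input impedance Z_ec, and
absorbance Abs_ec = 1 − |(Z_ec/Z₀ − 1)/(Z_ec/Z₀ + 1)|² with Z₀ = ρc/a.
The middle ear is an acoustic ladder network (drum branch in series with
the mallear-ligament shunt and the ossicular path to the stapes/cochlea),
driven through a lossless ear-canal transmission line; each modulus E
enters as an acoustic stiffness K = g·E with structural damping K(1+jη).

The spectra are flattened into a 250-element observation vector
x = [|V_st| dB, ∠V_st cycles, |Z_ec| dB, ∠Z_ec cycles, Abs]. Measurement
noise is Gaussian per element, with standard deviations estimated from
replicate (test–retest) measurements. Neural posterior estimation then
approximates q(θ | x): parameters are drawn from the box prior, simulated,
noise-injected, z-scored, and used to train a conditional density
estimator (a Gaussian-mixture density network behind a 3×50 fully
connected embedding) by maximum likelihood. Once trained, the estimator
returns posterior samples, log-densities, and MAP estimates for any new
observation without further simulation.

## Worked example

```python
import numpy as np
from mesbi import (PriorBox, NoiseModel, ArchConfig, MiddleEarParams,
                   build_training_set, train_npe, generate_test_retest,
                   simulate_spectra, assemble_features, spearman_spectra)
from mesbi.features import estimate_noise_std

prior = PriorBox()

# synthetic "specimen": 17 test-retest replicates at a known truth
theta_true = prior.sample(1, seed=101)[0]
ds = generate_test_retest(theta_true, n_replicates=17, seed=102)
sigma = estimate_noise_std(ds)          # per-element noise STD (250,)

# train the amortized posterior on 10,000 noise-injected simulations
ts = build_training_set(prior, 10_000, NoiseModel(sigma, scale=1.0), seed=103)
model = train_npe(ts, ArchConfig(seed=103))

# infer from the replicate mean, re-simulate the MAP, score the fit
theta_map = model.map_estimate(ds.mean, seed=0)
x_map = assemble_features(
    simulate_spectra(MiddleEarParams.from_array(theta_map))).values
rho, mean_rho, mean_abs = spearman_spectra(ds.mean, x_map)
print(np.round(theta_true, 3))
print(np.round(theta_map, 3))
print({k: round(v, 3) for k, v in rho.items()}, round(mean_abs, 3))
```

Output:

```
[18.927  0.363  8.063  6.322  3.649  0.188 26.472]
[18.907  0.356  8.65   6.513  3.495  0.184 26.089]
{'vst_mag_db': 1.0, 'vst_phase_cycles': 0.997, 'zec_mag_db': 0.999,
 'zec_phase_cycles': 0.96, 'abs': 0.997} 0.991
```

The sensitive parameters (`e_drum`, `damping`) are recovered closely;
weakly identified ones (`e_mallear`, `e_soft`) may drift within the prior while
the re-simulated spectra still match the observation — exactly the
behavior the per-feature Spearman ρ values (rank agreement over the 50
frequencies, 1.0 = identical ordering) quantify.

The same pipeline is scriptable from the shell:

```bash
mesbi make-synthetic --config config.yaml --out ds/
mesbi train --config config.yaml --data ds/ --out model/
mesbi infer --model model/ --obs ds/ --out posterior.json
mesbi validate --config config.yaml --suite noise --out noise_report.json
```

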