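# Methods

## The surrogate simulator

The forward model is a lumped-element acoustic network chosen to preserve
the interface and sensitivity structure of a full finite-element
middle-ear model at desk scale: seven tissue/load parameters in, three
measured spectra out, with resonance behavior, passivity, and
frequency-dependent sensitivities that qualitatively match wideband
acoustic-immittance data.

Topology (acoustic impedances, e^{+jωt} convention):

```
Z_drum(ω) = Z_td + Z_ml ∥ ( Z_j + Z_s ∥ ( Z_sal + Z_c / T ) )
```

with branch law `Z = jωM + K(1+jη)/(jω)`. `Z_td` is the tympanic
membrane/drum branch (acoustic mass `M_td`, stiffness `g_td·e_drum`),
`Z_ml` the mallear-ligament shunt, `Z_j` the ossicular branch (mass
`M_os`, joint stiffness), `Z_s` the suspensory-soft-tissue shunt, `Z_sal`
the stapes annular ligament, and `Z_c = cochlear_load·10⁹` a purely
resistive cochlear load referred through the combined ossicular
lever/area transformer factor `T`. The structural loss factor η is shared
by all stiffnesses, realizing the single "damping" parameter; it gives
each branch the dissipative real part `Kη/ω ≥ 0`, which guarantees
passivity of the whole network.

The stapes volume-velocity fraction is the product of the two current
dividers (`Z_ml` vs ossicular path, `Z_s` vs stapes branch). The ear
canal between probe and drum is a lossless cylindrical line; the
measurement plane sits `plane_distance_from_probe` from the probe, and
the impedance seen there is the tube transform of `Z_drum` over the
remaining length. The tube transform is evaluated in the cos/sin form,
which passes analytically through the tan(kl) poles (for the default
geometry, ≤ 10 mm of canal, the first pole is far above 8 kHz anyway).
Absorbance follows from the reflectance against `Z₀ = ρc/a`; the energy
identity `Abs + |Γ|² = 1` holds to machine precision by construction.

Numerical values: the canal radius (3 mm) and probe-to-plane distance
(3 mm) follow the wideband-tympanometry measurement convention; the
acoustic masses, the geometry-to-stiffness gains `g_*` (acoustic
stiffness per MPa of Young's modulus) and `T = 675` are calibration
constants of the surrogate, fixed once so that at prior midpoints the
absorbance peak falls near 1 kHz (drum-branch resonance
`√(g_td·e_drum/M_td)/2π ≈ 1.0 kHz`), peak absorbance is ≈ 0.68, and the
low-frequency impedance magnitude is ≈ 10⁸ Pa·s·m⁻³ — all within the
physiological ballpark for human ears. They are exposed in
`FixedConstants`/the config, but the defaults are the tested conditions.

What the surrogate does **not** model: 3-D ossicular kinematics and the
piston-direction projection of stapes velocity (the scalar
`U_st/A_fp` stands in), middle-ear-cavity acoustics (open cavity),
viscoelastic or anisotropic tissue laws, and canal losses. Conclusions
from the test suite are therefore about the inference method, not about
any particular specimen.

## Observation vector and noise model

The three spectra on the 50-point log grid (250–8000 Hz) are flattened
to 250 elements in the fixed block order `[|Vst| dB, ∠Vst cycles,
|Zec| dB, ∠Zec cycles, Abs]`. Magnitudes are in dB so that multiplicative
measurement error becomes additive; phases are unwrapped along frequency
(first point in (−0.5, 0.5] cycles) so the blocks are smooth in
frequency. Measurement noise is additive, element-wise independent
Gaussian in this space, `x' = x + s·σ⊙ε`, where σ (250 values) is the
per-element sample STD (divisor K−1) of replicate measurements and `s` a
global scale. Per-element σ was preferred over per-block scalars because
replicate variability of real immittance data is strongly
frequency-dependent; a config switch collapses σ to block medians.

The synthetic test-retest generator emulates one specimen measured K=17
times: K independent Gaussian perturbations of the clean simulated
response. Default base variability — 0.5 dB for magnitude blocks, 0.02
cycles for phases, 0.02 for absorbance — is of the order of published
test-retest spreads for wideband immittance; it is a choice, not a fit.
The generator does not model correlated or systematic errors
(probe-position drift, tissue dehydration), so passing tests demonstrate
correct inference under the stated noise model, not robustness to model
misspecification.

## The posterior estimator

Neural posterior estimation with a conditional Gaussian-mixture density
network: a fully connected tanh embedding (3 layers × 50 units by
default) maps the z-scored observation to mixture logits, means and
log-STDs of 8 diagonal-Gaussian components over the z-scored parameters.
The estimator is trained by maximizing the mean log q(θ|x) over the
simulated pairs with Adam (step 5·10⁻⁴, batch 200, 10% validation split,
early stopping with patience 20, at most 500 epochs; on validation
plateau the step is halved from the best weights, down to 2·10⁻⁵). The
mixture head makes log-density, its θ-gradient, and sampling all
analytic, which keeps the whole pipeline in plain numpy with exactly
reproducible seeded training.

z-scoring uses training-set statistics only (standard amortized-SBI
practice); the scaler floors the per-element spread at 10⁻¹² to survive
degenerate columns. The prior is independent-uniform per parameter on the
linear scale (log-uniform available per parameter), the most literal
reading of a table of plausible ranges. Parameters clamped in the prior
(`low == high`, used for slice studies) are excluded from the learned
density and reinserted as constants.

Posterior sampling truncates the mixture to the prior box by rejection
(the rejection fraction is recorded; >99% rejection raises). The MAP is
the best of 10,000 posterior draws followed by L-BFGS-B ascent of the
analytic log-density inside the box — deterministic for a fixed seed.
Inference is fully amortized: no simulator calls occur after training
(asserted in the tests). Only single-round training is implemented; no
sequential refinement, no ensembling.

## Validation program

* **Spearman agreement**: rank correlation per 50-point feature block
  between a MAP re-simulation and the reference, average ranks for ties;
  a constant block has no rank ordering and is excluded from the means.
  Both the signed mean and the mean of absolute values are reported.
* **Coefficient of variation**: posterior STD (divisor n−1) over
  posterior mean, per parameter.
* **Exact grid oracle**: with the simulator deterministic and the noise
  Gaussian, the posterior over a 2-parameter slice is computable exactly
  (in log space) on a grid of cell centers spanning the prior rectangle;
  it is the estimator-independent reference for the cross-check below.
* **Suites**: held-out validation (draw truth, infer, re-simulate),
  noise sweep (scales 0.1/1/10 of the replicate STD), training-size
  sweep (100/1000/10,000), and single-feature vs multi-feature training.

### Study sizes used by the shipped tests

Training-set sizes follow the experiment: 10,000 pairs for the baseline
validation and reference fits, 2,000 for the noise-robustness, recovery
and sweep studies, 100/1,000/10,000 for the size sweep. The
oracle-equivalence slice study trains on 30,000 pairs with the linear
mean-skip readout enabled and a longer early-stop window: on the
2-parameter slice the exact posterior for the sensitive pair (`e_drum`,
`damping`) is nearly as narrow as one 50×50 grid cell, so matching it in
total-variation distance requires the conditional mean to be accurate to
a fraction of a cell. At that accuracy the residual error is dominated by
training-seed scatter of the network's conditional mean at the single
queried observation — a local quantity that the global validation
log-density does not track — so the check is run as three independent
replicates (new observation noise, new training set, new estimator) and
judged on every replicate's mode location plus the median
total-variation distance. These sizes and the replicate design are the
package's chosen study conditions and are stated in the test docstrings.

## Numerical choices and edge cases

* STD convention: divisor K−1 (or n−1) everywhere.
* Spearman ties: average ranks (scipy convention).
* Histograms: 50 bins (1D) and 30×30 (2D) over the full prior ranges;
  marginal-consistency is exact when binned identically.
* tan-pole handling in the tube by the analytic cos/sin form, not
  clamping.
* Zero noise scale is allowed in the generator (degenerate, replicates
  identical); the grid oracle requires strictly positive σ.
* Non-finite training loss aborts with a diagnostic rather than
  continuing silently.
* Frequency grid default 250–8000 Hz; configurable.

## Known limitations

* The mixture head is diagonal per component; strongly curved posterior
  ridges are approximated by multiple components rather than represented
  exactly.
* Weakly identified parameters (soft-tissue and mallear-ligament moduli)
  keep broad posteriors; their MAP values are not individually
  interpretable even when the spectral fit is excellent.
* On purely synthetic in-model references, single-feature training still
  reproduces the held-out feature blocks well: without model–data
  mismatch, any parameter set fitting one block tends to fit the others.
  The cross-feature degradation seen with real measurements is therefore
  not asserted by the tests; the subset suite reports the cross-feature
  correlations without enforcing an ordering.
* CV magnitudes depend on the surrogate's sensitivity structure and are
  treated as ordering diagnostics (across noise scales and training
  sizes), not as absolute targets.
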