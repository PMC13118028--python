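# lungident

Vibration-based identification of regional lung mechanics from externally
measured chest-wall responses.

Conventional pulmonary diagnostics either image static structure or collapse
regional behaviour into whole-lung indices. `lungident` explores a
complementary idea: treat the lung–thorax system as an identifiable
viscoelastic dynamical system, probe it with gentle harmonic excitation at
the chest wall, and infer **regional** mechanical properties — in particular
regional stiffness — from the measured frequency response. The package is a
simulation framework for studying the feasibility of that paradigm: it is
aimed at researchers in respiratory biomechanics and vibration-based
diagnostics, not at clinical use.

## The model

The lung–thorax system is reduced to four lumped compartments, each a single
translational degree of freedom (DOF): the chest wall (DOF 0, the
excitation/measurement interface), the right upper lung region (1), the
right lower lung region (2) and the left lung (3). Compartments are coupled
by linear springs `k_ij` and dampers `c_ij`; the chest wall is tethered to
the body by a ground spring `k_0g`. The equations of motion are

```
M ẍ(t) + C ẋ(t) + K x(t) = F₀ e^{jωt} e₀
```

with diagonal mass matrix `M` and symmetric `K`, `C` assembled by standard
two-node superposition. Steady state reduces to the complex linear system
`(−ω²M + jωC + K) X(ω) = F`, solved directly at each of 300 frequencies over
5–150 Hz. A lumped description is defensible in this band: shear-wave speeds
of 20–50 m/s in aerated lung give wavelengths of 0.13–0.33 m at 150 Hz,
comparable to whole-lung dimensions.

On this forward model the package builds the full identification pipeline:

* **noise model** — relative Gaussian corruption of FRF magnitudes
  (`m → m(1+σε)`, default σ = 2 %), phase untouched;
* **identifiability** — finite-difference log-log sensitivities
  `∂ln|X_i|/∂ln k_j` and the Fisher-information matrix `F = JᵀJ` with its
  eigenvalues, condition number κ and column correlation ρ;
* **inverse fitting** — bounded nonlinear least squares recovering selected
  stiffnesses (default `{k01, k02}`, the chest–right-upper and
  chest–right-lower couplings) from chest-wall magnitude data, with optional
  Tikhonov regularization;
* **cohort classification** — a synthetic three-class cohort (healthy,
  right-upper fibrosis, right-lower fibrosis; 30 noisy realizations each),
  stratified 70/30 split, PCA to six components, multinomial logistic
  regression.

Pathologies are multiplicative stiffness perturbations (fibrosis stiffens,
emphysema softens); all quantities are in arbitrary consistent units, with
frequency (Hz) the only dimensional axis.

## Worked example

```python
import numpy as np
from lungident import (
    default_model, default_grid, solve_frf, add_magnitude_noise, NoiseSpec,
    FitSpec, fit_stiffness, relative_sensitivity, fisher_information,
    run_classification_experiment,
)

model = default_model()          # healthy baseline, k01=240, k02=154
grid = default_grid()            # 300 points, 5-150 Hz

# forward simulation + 2 % magnitude noise, then inverse recovery
frf = solve_frf(model, grid)
noisy = add_magnitude_noise(frf, NoiseSpec(relative_sigma=0.02, seed=1))
fit = fit_stiffness(noisy.magnitude[0], model, FitSpec(), grid)
print("recovered:", {k: round(v, 1) for k, v in fit.estimates.items()})

# local identifiability of {k01, k02} from all four outputs
fim = fisher_information(
    {p: relative_sensitivity(model, p, grid) for p in ("k01", "k02")})
print("FIM eigenvalues:", np.round(fim.eigenvalues, 1),
      "kappa:", round(fim.condition_number, 3),
      "rho:", round(fim.correlation[("k01", "k02")], 3))

# synthetic-cohort classification experiment
report = run_classification_experiment(model)
print("held-out accuracy:", report.accuracy)
print(report.metrics_frame())
```

prints

```
recovered: {'k01': 239.9, 'k02': 154.1}
FIM eigenvalues: [3906.6 3765.4] kappa: 1.038 rho: 0.018
held-out accuracy: 1.0
             precision  recall  f1_score  support
class
fibrosis_RL        1.0     1.0       1.0        9
fibrosis_RU        1.0     1.0       1.0        9
healthy            1.0     1.0       1.0        9
```

Reading the numbers: a single noisy chest-wall measurement pins both
regional stiffnesses to well under 1 % of their true values (240 / 154); the
two strictly positive Fisher eigenvalues with κ ≈ 1 and small ρ say the two
parameters are locally identifiable and nearly decoupled in the multi-output
configuration; and the three simulated conditions are perfectly separable in
the reduced feature space — every one of the 27 held-out realizations is
classified correctly.

## Command line

Each pipeline stage is also a CLI subcommand writing CSV/JSON outputs and a
run manifest:

```sh
lungident simulate   --out out/          # FRF tables per condition
lungident sensitivity --out out/         # log-log sensitivity table
lungident fisher     --out out/          # FIM eigenvalues, kappa, rho
lungident fit        --out out/          # noisy-measurement inverse fit
lungident cohort     --out out/          # labeled feature matrix
lungident classify   --out out/          # classification report
lungident reproduce  --out out/          # all of the above
```

`--config my.yaml` overrides any subset of the default configuration
(`lungident.config.default_config()`); `--seed` overrides the stage seed.

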