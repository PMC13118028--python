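# Methods

## Mechanical model

The lung–thorax system is represented by four point masses in one
generalized coordinate each: chest wall `m0`, right upper lung `m1`, right
lower lung `m2`, left lung `m3`. Linear springs connect the chest wall to
each lung region (`k01`, `k02`, `k03`), the lung regions to one another
(`k12`, `k13`, `k23`), and the chest wall to ground (`k0g`, the elastic
restraint of spine and body). Dampers mirror the spring topology. Assembly
follows the standard two-node rule — a spring `k` between DOFs `i` and `j`
adds `+k` to both diagonal entries and `−k` to the off-diagonal pair;
ground elements add to the diagonal only — which guarantees symmetric `K`
and `C` and internal-force balance (row sums of `K` reduce to the ground
stiffness attached to each DOF).

The model is linear and passive: no nonlinear tissue law, no airflow, no
active muscle forcing. It is a minimal identifiable representation for
feasibility analysis, not an anatomical reconstruction. The lumped
idealization is restricted to the 5–150 Hz band, where effective wave
speeds of 20–50 m/s give wavelengths (0.13–0.33 m at the top of the band)
on the order of whole-lung dimensions (`wavelength_check` documents this).

## Baseline parameters

Only the two chest–lung couplings targeted by inverse fitting have
externally fixed values: `k01 = 240`, `k02 = 154` (arbitrary units). The
remaining defaults are package choices, selected once against three
physical requirements and then frozen:

| parameter | default | role |
|---|---|---|
| `k03` | 180 | chest–left-lung coupling, same order as `k01`/`k02` |
| `k12`, `k13`, `k23` | 10, 8, 12 | weak inter-lung coupling |
| `k0g` | 12 | soft elastic support of the thorax |
| masses | 0.02, 0.003, 0.004, 0.006 | chest wall ≫ lung regions |
| `c_ij` | `2e-4 · k_ij` (s) | stiffness-proportional tissue damping |
| `c0g` | 0.35 | support damping, ~30 % of critical for the support mode |

The requirements: (a) the coupled lung/chest resonances (≈ 31, 37, 50 Hz)
lie inside the excitation band, so FRFs show several well-separated
underdamped peaks; (b) the rigid-body mode of the whole thorax on its
support sits below the band (≈ 3 Hz) — near a strongly shared resonance
every output is dominated by the shift of that common mode, which would
destroy the regional specificity of the low-frequency sensitivities; and
(c) inter-lung coupling is weak relative to the chest–lung couplings, so
each lung region's response over 5–25 Hz depends chiefly on its own chest
coupling. Under (a)–(c) the right-upper response is dominated by `k01` and
the right-lower response by `k02` at every grid point of the 5–25 Hz band.
Note the dominance property cannot hold *through* an in-band resonance of
the observed DOF: the own-parameter log-sensitivity changes sign across its
resonance, so it necessarily crosses zero there. Placing the lung
resonances above 25 Hz is what makes band-wide dominance achievable.

Support damping is kept separate from the stiffness-proportional tissue
rule because the two mechanisms are physically distinct (posture/soft-tissue
losses vs. parenchymal viscosity) and because a proportionally damped
`k0g = 12` support mode would ring for minutes, which is unphysical and
makes time-domain verification needlessly slow.

All defaults are config-overridable (`model:` section).

## Forward solution and verification

The steady-state response is computed by a direct dense solve of
`(−ω²M + jωC + K)X = F` at each frequency (the systems are 4×4; the solves
are batched over the grid). Complex convention `e^{jωt}`, phase in (−π, π].
An exactly-hit undamped resonance raises a singularity error naming the
frequency.

An independent time-domain oracle integrates `Mẍ + Cẋ + Kx = F₀cos(ωt)e₀`
from rest (`scipy.integrate.solve_ivp`, RK45, rtol 1e-9) and reports
half-peak-to-peak amplitudes over the final forcing cycle. The integration
horizon is derived from the slowest eigenvalue of the first-order state
matrix so the free transient is attenuated below 1e-5; a residual
last-two-cycle amplitude drift above 0.2 % raises a convergence error
rather than returning a contaminated amplitude. Frequency- and time-domain
amplitudes agree within 0.5 % across the band (tested at randomly chosen
grid frequencies).

## Noise model

Measurement noise corrupts the magnitude channel only — the observable used
downstream — leaving phase and the complex responses untouched. Default
mode is relative: `m → m(1 + σε)`, ε i.i.d. standard normal per
(DOF, frequency) cell, σ = 0.02. The alternative `additive` mode perturbs
by `σ · mean(m) · ε` with the band-mean magnitude per DOF. Corrupted
magnitudes are clamped below at 1e-12 to preserve positivity; the clamp
visibly truncates the noise distribution only on cells whose magnitude is
within a few σ of zero. σ = 2 % is the package's reading of "moderate
experimental variability"; it is the default for both the fitting and the
cohort experiments and is exposed in the config.

## Identifiability analysis

Relative sensitivities `∂ln|X_i(f)|/∂ln k_j` are computed by forward finite
differences with a 1 % multiplicative step (`[ln|X|(k(1+δ)) − ln|X|(k)] /
ln(1+δ)`); a central scheme and an unnormalized absolute mode are available
by option. The log-log form is dimensionless and invariant to the
excitation amplitude. Stacking all (DOF, frequency) cells
(frequency-major within DOF, DOFs in index order — the FIM is
order-invariant) gives the Jacobian `J`, Fisher matrix `F = JᵀJ`,
eigenvalues in descending order, condition number `κ = λmax/λmin` (∞ when
`λmin` is numerically zero at tolerance `max(n_cells, n_params)·eps·λmax`),
and pairwise column correlations. On the default model with `{k01, k02}`
over the full band: both eigenvalues strictly positive, κ ≈ 1.04,
ρ ≈ 0.018. The *absolute scale* of the eigenvalues depends entirely on the
sensitivity normalization and the baseline parameters, so only the
qualitative conclusions — positivity, κ = O(1), modest ρ — are asserted.

## Inverse fitting

Selected stiffnesses (default `{k01, k02}`) are estimated by bounded
nonlinear least squares on raw-magnitude residuals over the observed DOFs
(default: chest wall only), with masses and damping fixed:

* bounds `[0.5×, 2.0×]` the baseline values;
* primary start at the healthy reference; tolerances `ftol = 1e-10`,
  `xtol = 1e-8`, iteration cap 500 (`scipy.optimize.least_squares`, TRF);
* optional Tikhonov penalty `w·Σ(θ − θ_init)²` implemented as appended
  residual rows `√w(θ − θ_init)`;
* optional log-magnitude residuals for heavy dynamic range.

The chest-wall-only magnitude objective is multimodal when the true
stiffness lies far from the healthy reference (resonance peaks can lock
onto the wrong neighbours). `fit_stiffness` therefore runs a deterministic
multistart — the healthy reference plus the bounds-box corners pulled 20 %
inward (all 2^p for p ≤ 3 parameters; low-discrepancy interior points
beyond that), 5 starts by default — and returns the best optimum. With all
four DOFs observed the problem is unimodal within the bounds and a single
start suffices. The returned objective never exceeds the objective at the
initial values; a free parameter with numerically zero sensitivity over the
observed cells triggers a warning naming it.

At the default conditions (truth `k01 = 240`, `k02 = 154`, σ = 0.02,
chest-wall data), single-realization estimates land within a few tenths of
a percent of truth and the Monte-Carlo mean over 50 noise realizations is
unbiased to well under 1 %.

## Cohort generation and classification

`generate_cohort` emulates a synthetic cross-sectional study: for each of
the three conditions (healthy; right-upper fibrosis = `k01 × 1.5`;
right-lower fibrosis = `k02 × 1.5`) it simulates 30 realizations of the
four-DOF FRF magnitude over the 300-point grid, corrupts them with the
noise model, and flattens DOF-major into 1200-wide feature vectors. One
`numpy` generator seeded from the config drives the whole cohort, so the
dataset is a pure function of its config. Optional inter-subject
variability multiplies every mass/stiffness/damping value by an independent
lognormal factor (`jitter_sigma`, default 0 — the reference conditions have
none).

What the generator does *not* emulate: phase noise, sensor bias or
correlated artifacts, inter-subject anatomical variation beyond the
lognormal jitter, model mismatch (the fitted model is the generating
model), or multi-parametric pathology (stiffness-only perturbations, plus
mass for focal lesions). Perfect classification and sub-percent recovery
under the default conditions therefore demonstrate *theoretical
discriminability* of the mechanical signatures — an upper bound, not
expected clinical performance.

The classifier chain is deliberately standard: stratified 70/30 split
(63/27 on the balanced 90-row cohort, 9 test rows per class), PCA to six
components fitted on training rows only (mean-centering only; the features
share units), multinomial logistic regression with iteration cap 1000
(scikit-learn defaults otherwise), scored by per-class
precision/recall/F1, accuracy and the confusion matrix. Because the
ordering of reduction and splitting is ambiguous in principle, the
leakage-free variant (PCA on train only) is the default; fitting PCA on
all rows before splitting changes nothing at the default noise level.
Label-permutation controls drop held-out accuracy to chance (≈ 1/3), and
accuracy degrades gradually, not catastrophically, as σ grows through
0.02–0.2.

## Numerical choices and degenerate inputs

* Frequency grids must be strictly increasing and positive; 0 Hz is
  disallowed in the grid type itself (the static limit is exercised via
  ω → 0).
* Zero-stiffness springs are legal (vacuous assembly); zero masses are not.
* Noise σ = 0 and jitter = 0 reproduce inputs bit-identically; identical
  seeds give bit-identical datasets, splits and noise draws.
* FIM with duplicated sensitivity columns reports λmin = 0, κ = ∞,
  ρ = 1 — i.e. non-identifiable — rather than raising.
* Problem sizes everywhere default to the reference conditions (300
  frequencies, 90 realizations, 50 Monte-Carlo fits); module-level tests
  run reduced grids (30–60 points) where the property under test does not
  depend on grid density.

## Known limitations

The framework quantifies feasibility within its own generating
assumptions. Absolute Fisher-eigenvalue scales are not comparable across
parameterizations or normalizations; only conditioning and positivity
carry meaning here. The four-compartment partition is one of many
defensible choices, and the inverse problem is solved with the true
forward model — robustness to structural mismatch is untested. Damping and
mass estimation are out of scope (fixed at baseline during fitting), as
are transient analysis and continuum wave propagation.
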