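# Methods

## The model

`spinecomp` implements a one-dimensional reaction-diffusion description of
structural plasticity at dendritic spines after quasi-simultaneous glutamate
stimulation of a set of spines on one dendritic segment. Two molecular
resources drive changes in normalised spine size `S(x, t)`:

* **C** — a fast potentiating resource (calcium and calcium-activated
  molecules). It is deposited at stimulation sites at `t = 0` as a sum of
  narrow Gaussians and then diffuses (`alpha1`, μm²/min) and degrades
  (`alpha2`, 1/min):

  `∂C/∂t = alpha1 · C_xx − alpha2 · C`

* **P** — a slow dual-role resource, produced from an inactive precursor
  `P_in` wherever C is present, diffusing slowly and degrading slowly:

  `∂P_in/∂t = beta1 · (P_in)_xx − beta2 · P_in · C`
  `∂P/∂t = beta1 · P_xx + beta2 · C · P_in − gamma · P`

* **S** — the normalised spine size field, with baseline 1:

  `∂S/∂t = zeta1 · C + zeta2 · P · F(S)`,  `F(S) = −tanh(phi · (S − nu))`

  C always potentiates; P potentiates spines below the size threshold `nu`
  and depresses spines above it, through the smooth switch `F`. This yields
  the characteristic single-spine time course — rapid growth driven by C,
  overshoot past `nu`, then P-driven decay back toward a persistently
  elevated size — without a hard LTP/LTD boundary.

### Competition for shared resources

Each stimulated spine `i` unlocks a private store `C_s` and receives a share
`D_i` of the common dendritic pool `C_d`:

`C(x, 0) = Σ_i (C_s + C_d · D_i) · exp(g_eff · (x − x_i)²)`
`D_i = (1 + d_i) / (n_stim + n_hat)`
`d_i = Σ_{j≠i} ( |x_i − x_j| / (1 + |x_i − x_j|) )^lam`

`d_i` vanishes for tight clusters (full 1/N competition) and approaches
`n_stim − 1` for widely separated sites, so `D_i → 1` when spines stop
interacting. `n_hat` counts unstimulated spines lying within 2 μm (the
configurable interaction radius) of at least two distinct stimulation
sites; it is a single global count entering every `D_i`, and can be
overridden directly when a dataset lacks unstimulated positions.

The precursor pool starts depleted at stimulation sites in proportion to the
dendritic C drawn there, `P_in(x, 0) = rho · (1 − Σ_i (1 − D_i) G_i(x))`,
clamped at zero where overlapping depletion troughs of tight clusters would
drive it negative (concentrations cannot be negative; realistic layouts stay
non-negative anyway).

### Units and conventions

Time is in minutes measured from the end of the 1-min stimulation train;
space in μm; concentrations in arbitrary units fixed by the fit. Nothing
inside the stimulation minute is modelled, and model-data comparisons use
the +2 … +40 min window. Sham stimulation carries zero initial C and
depletes nothing, so `S ≡ 1` is its exact solution.

The Gaussian kernel coefficient is fixed at `g_eff = −4·ln 2` μm⁻², i.e.
FWHM 1 μm — the physical footprint of a spine head on the dendrite. It is
configurable but not fitted.

## Numerics

The integrator uses Strang splitting, second order in `dt`:

1. half-step of the local reactions with the explicit midpoint rule (RK2);
2. full Crank-Nicolson step of the two diffusion operators (C at `alpha1`;
   `P_in` and P share `beta1`), using a finite-volume Laplacian with
   no-flux boundaries whose symmetric tridiagonal factors are Cholesky-
   decomposed once per run. The ones-vector is a left null vector of this
   Laplacian, so `∫(P_in + P) dx` is conserved exactly when `gamma = 0`;
3. second reaction half-step.

Defaults: `dx = 0.125` μm (8 points per kernel FWHM, the minimum the
initial condition tolerates), `dt = 0.02` min for production simulation and
`dt = 0.1` min inside the fitting loop, domain padded 20 μm beyond the
outermost spine so the boundaries sit several diffusion lengths away over
40 min. Halving `dt` moves sampled trajectories by ≈4·10⁻⁵ (sup-norm);
halving `dx` by ≈9·10⁻⁴. Spine sizes are read out by linear interpolation
of the S field at the exact spine position; nearest-node sampling is kept
as an option but aliases the readout position by up to `dx/2`, which is
what the interpolated default avoids (a window-averaged ±0.5 μm readout is
also available). Non-finite field values abort integration with the
offending time in the error.

## Fitting

The cost is `Σ (S_model(x_i, t_k) − L_{i,k})²` over stimulated spines and
post-stimulation snapshots, where `L` is the cohort-mean trajectory (the
model describes the average spine; per-spine targets are also accepted).
Optimisation runs in log-parameter space — which enforces positivity — with
L-BFGS-B inside a bounded box spanning roughly an order of magnitude around
the reference regime (the threshold `nu` is instead bounded by the observed
range of normalised sizes, 0.9–2). Ten restarts from seeded log-uniform
start points are the default; the best restart wins, and results are
bit-reproducible for a given seed.

Gradients are computed by a discrete adjoint: reverse-mode differentiation
of the exact forward scheme, including the Crank-Nicolson solves (transpose
solves reuse the same Cholesky factors), the RK2 reaction stages, the
interpolated readout, and the initial-condition dependence on `C_s`, `C_d`,
`rho` and `lam` (the clamped region of `P_in(x,0)` contributes zero
gradient). The adjoint matches central finite differences to ~10⁻⁶ relative
at generic parameter points; a finite-difference mode is first-class as an
independent cross-check and fallback. Because components carrying under 1%
of the gradient magnitude at a near-stationary point are dominated by
cancellation noise in the finite differences, the gradient-check report
measures those against the 1% scale.

Parameter identifiability is not assumed: on noiseless synthetic targets
the fitted trajectory recovers the truth to sup-norm ≈5·10⁻⁴ while
individual parameters can differ substantially from the generating values.
Acceptance of a fit is therefore trajectory recovery, with parameter values
reported but not asserted.

Pharmacological variants refit only the susceptibilities around a master
fit, with direction-of-change bounds: the calcineurin-blocker condition
(FK506) may only raise `zeta1/zeta2` (weakening the P influence, which
slows the post-peak decay), and the CaMKII-blocker condition (AIP) may only
lower `zeta1/zeta2` and the threshold `nu` (blunting potentiation). All
other parameters stay frozen.

## Reference parameter set

The reference set (`REFERENCE_PARAMS`) is the package's own calibration,
chosen once to express the qualitative multi-spine phenomenology on the
reference layouts and used as the default ground truth of the synthetic
generator — it is not a published parameter set:

| parameter | value | role |
|---|---|---|
| C_s / C_d | 0.1 / 1.0 | private vs shared fast-resource stores |
| lam | 40 | competition exponent: sites within ~30 μm compete, `d`-terms saturate only at mm scales |
| alpha1 / alpha2 | 0.5 μm²/min / 2 min⁻¹ | C stays localised (~0.7 μm range) and decays within minutes |
| beta1 / beta2 / gamma | 0.4 μm²/min / 1 / 0.03 min⁻¹ | P spreads over ~5–10 μm and persists tens of minutes |
| rho | 1.0 | precursor baseline |
| phi / nu | 4 / 1.05 | switch steepness and size threshold |
| zeta1 / zeta2 | 2.0 / 0.25 | susceptibilities to C and P |

At these values: a single spine peaks near 1.6 and decays to ≈1.27; mean
early potentiation at +2 min decreases strictly with cluster size over the
clustered 3-, 7- and 15-spine reference layouts (1.28 > 1.16 > 1.14, the
1/N competition signature); edge spines exceed middle spines from +30 min
in the 7- and 15-spine clusters while the 3-spine cluster shows no
meaningful edge/middle split; and the 15-spine response is a flat,
sustained potentiation.

One structural trade-off is worth recording. The saturating distance metric
`(r/(1+r))^lam` approaches 1 only like `1 − lam/r`, so with any exponent
large enough to produce 1/N competition at realistic ~2 μm spacing, the
allocation factors of spines spaced 30 μm apart remain well below 1
(`D ≈ 0.55` at `lam = 40`), and their trajectories approach the
single-spine curve only in ordering, not to tight numerical tolerance;
sup-norm agreement at the 10⁻² level is reached only at millimetre-scale
separations. Decoupling is therefore a limit statement in this model class,
and the package asserts the monotone approach `D → 1` rather than treating
30 μm as effectively infinite separation.

## Synthetic cohorts

`synthetic_data` emulates the structure of the experimental cohorts:

* **Geometry.** Cluster spans are drawn from distributions matched to the
  printed statistics — triangular(2.2, 3.2, 4.2) μm for three spines;
  Beta(0.694, 2.452) on [4.0, 33.9] μm for seven spines (quartiles 5.6 and
  14.1 μm, mean 10.6 μm, matched exactly); Beta(4.7, 1.3) on [20, 30.6] μm
  for fifteen spines (mean 28.3 μm); three times the clustered seven-spine
  span for the distributed condition. Stimulated spines are evenly spaced
  with jittered interior positions; unstimulated spines are a Poisson
  scatter at 0.5/μm (a plausible dendritic spine density; only those close
  to two stimulation sites matter downstream).
* **Cohort sizes** mirror the experimental dataset (e.g. 7 experiments / 21
  stimulated spines for three-spine, 25/174 for seven-spine, 13/181 for
  fifteen-spine). Where the published totals fall short of the nominal
  paradigm count, a seeded random subset of stimulated-spine observations
  is dropped, mimicking spines excluded from image analysis.
* **Measurement model.** Raw fluorescence is
  `baseline · S · exp(eps)`, `eps ~ N(0, sigma²)` i.i.d. per observation,
  with log-normal per-spine baselines (median 100 a.u., log-sd 0.3) and
  three pre-stimulation snapshots at −6, −4, −2 min; the default post
  schedule is +2 … +40 min every 2 min and the default `sigma` is 0.05.
  Baseline normalisation then inflates the coefficient of variation to
  `sigma · sqrt(1 + 1/3)`.

What the generator does **not** emulate: spine-to-spine parameter
heterogeneity (the model is an effective average-spine description),
temporal drift, spatially correlated noise, z-drift artefacts, or failed
experiments. Passing recovery tests on these cohorts therefore demonstrates
correctness of the pipeline under the stated noise model, not robustness to
every failure mode of real microscopy data.

## Statistics

* **Normalisation** divides each spine's fluorescence by the mean of its
  three pre-stimulation snapshots (positive by contract, enforced).
* **NMSE**: per-snapshot mean-squared error divided by that snapshot's
  observed variance, averaged over snapshots; the per-snapshot-mean
  predictor attains the analytic minimum 1 exactly. **Weighted R²**:
  inverse-variance-weighted comparison of the prediction to per-snapshot
  means against the pooled mean. Zero-variance snapshots are excluded from
  both sums with a warning; both metrics use post-stimulation snapshots by
  default. 
* **Exponential decay**: `a·exp(−b·t) + c` fitted by bounded least squares
  (`b ≥ 0`) to post-stimulation cohort means, with degenerate fits (b ≈ 0 or
  vanishing exponential amplitude — only `a + c` determined) flagged rather
  than reported as identified. Uncertainty comes from resampling ⌈n/2⌉ of
  the n experiments with replacement, averaging their mean trajectories,
  and refitting — 1000 replicates by default, failed replicates excluded
  and counted.
* **Hypothesis tests**: Welch's unequal-variance t tests and
  Kruskal-Wallis/Dunn rank tests, both with Benjamini-Hochberg FDR control
  across the comparison family; Dunn's z statistics use pooled mid-ranks
  with tie correction. Studentised (bootstrap-t) intervals calibrate each
  replicate's mean by its own standard error. All bootstrap operations are
  deterministic given their seed.

## Problem sizes used in the shipped checks

The test-suite and acceptance computations run at desk scale: cohorts of
4–25 experiments, grids of a few hundred to ~2000 nodes, 10-restart fits on
the three-spine paradigm with `dt = 0.1`, and 1000-replicate bootstraps.
These sizes were chosen so every check recomputes its claim from scratch in
seconds to a few minutes on one CPU while leaving the statistical margins
(recovery tolerances, ordering gaps) comfortably resolved.

## Known limitations

* A single dendritic segment in 1-D: no branch points, spine necks, or
  2-D/3-D geometry; no electrical signalling; no synthesis of C or P.
* The distributed-spine decoupling behaves as a limit, not a 30-μm
  threshold (see the reference-parameter trade-off above).
* Fitted parameters are effective, partially identifiable quantities;
  only trajectory-level statements are supported.
* The drug variants encode direction-of-change hypotheses as bounds; they
  do not distinguish mechanistic alternatives with equal trajectories.
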