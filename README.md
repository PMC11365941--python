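# spinecomp

Modelling competitive resource allocation during multi-spine structural
plasticity on dendrites.

When several dendritic spines on the same branch are potentiated at once
(e.g. by quasi-simultaneous glutamate uncaging at 1, 3, 7 or 15 spines),
the resulting structural LTP depends on how many spines were stimulated and
how far apart they sit: larger clusters potentiate less at first but hold
their gains longer, edge spines of a cluster outgrow middle spines at late
times, and widely separated spines behave like isolated ones. `spinecomp`
implements a minimal mechanistic explanation — competition for shared
molecular resources — as a 1-D reaction-diffusion model, together with the
fitting machinery and the statistics needed to analyse spine-volume time
courses. It is aimed at computational neuroscientists and experimentalists
working with normalised spine-fluorescence trajectories.

## The model in brief

A fast potentiating resource *C* (calcium-driven) and a slow dual-role
resource *P* evolve on a dendritic segment after stimulation at positions
`x_i`:

```
∂C/∂t    = α₁ C_xx − α₂ C
∂P_in/∂t = β₁ (P_in)_xx − β₂ P_in C
∂P/∂t    = β₁ P_xx + β₂ C P_in − γ P
∂S/∂t    = ζ₁ C + ζ₂ P F(S),      F(S) = −tanh(φ (S − ν))
```

with initial conditions that encode competition: each stimulated spine
unlocks a private store `C_s` and a share `D_i = (1 + d_i)/(N + N̂)` of the
common dendritic pool `C_d`, where `d_i = Σ_j (|x_i−x_j|/(1+|x_i−x_j|))^λ`
measures how far spine *i* sits from its co-stimulated neighbours, and `N̂`
counts unstimulated spines close to ≥2 stimulation sites. Tight clusters
share resources 1/N; separated spines decouple (`D_i → 1`). The spine size
*S* is normalised to its pre-stimulation baseline; *P* grows spines smaller
than the threshold ν and shrinks larger ones, preventing runaway growth.

Model quality is judged by the snapshot-averaged NMSE (for which the
per-snapshot-mean predictor attains the analytic minimum of exactly 1) and
an inverse-variance-weighted R²; decay kinetics are summarised by a
bootstrapped exponential fit `a·exp(−b·t) + c` with Kruskal-Wallis/Dunn and
Welch tests under Benjamini-Hochberg FDR control.

## Worked example

```python
import numpy as np
from spinecomp import REFERENCE_PARAMS, simulate
from spinecomp.synthetic_data import reference_layout

times = np.arange(2.0, 41.0, 2.0)          # minutes after stimulation
for paradigm in ("single", "three", "seven", "fifteen"):
    lay = reference_layout(paradigm)       # cluster at the mean span
    m = simulate(lay, REFERENCE_PARAMS, times).mean_stim_trajectory()
    print(f"{paradigm:8s} S(+2)={m[0]:.3f}  peak={m.max():.3f}  S(+40)={m[-1]:.3f}")
```

prints

```
single   S(+2)=1.589  peak=1.589  S(+40)=1.273
three    S(+2)=1.278  peak=1.278  S(+40)=1.158
seven    S(+2)=1.161  peak=1.161  S(+40)=1.115
fifteen  S(+2)=1.135  peak=1.135  S(+40)=1.102
```

Read: the isolated spine overshoots strongly (to ~1.6× baseline) and decays
fastest; early potentiation at +2 min falls as more spines compete for the
shared pool (1.28 → 1.16 → 1.14 for 3 → 7 → 15 spines, the 1/N signature);
and larger clusters retain proportionally more of their potentiation at
+40 min because the depressing resource *P* is itself depleted. These
numbers use the package's reference parameter set (`REFERENCE_PARAMS`, see
`docs/methods.md`) — an in-package calibration, not published values.

The same pipeline is scriptable from the shell:

```bash
spinecomp synth --condition three --seed 11 --out cohort.csv
spinecomp fit --data cohort.csv --paradigm three --restarts 10 --seed 17 --out fit.json
spinecomp predict --fit fit.json --paradigm seven --out pred7.csv
spinecomp stats gof --pred pred7.csv --data cohort.csv
spinecomp stats expboot --data cohort.csv --nboot 1000 --seed 7
```

`fit` estimates the 13 model constants from the cohort-mean trajectory by
multi-start L-BFGS-B in log-space, with gradients from a discrete adjoint
of the integrator; `predict` reuses a master fit across paradigms without
refitting (initial conditions rescale only through the competition
factors).

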