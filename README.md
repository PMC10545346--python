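# germorder

Quantitative analysis of **fourfold orientational order generated by
choreographed cell divisions** in growing epithelia, modelled on the trunk
ectodermal germband of the crustacean *Parhyale hawaiensis*: during
germband extension, waves of tightly oriented cell divisions assemble the
ectoderm into a globally ordered grid of cells instead of fluidizing it.

The package is aimed at quantitative developmental biologists and soft
matter physicists working with cell-centroid tracking data. It provides:

- **Bond-orientational order.** Per-cell order parameters
  `psi_n(j) = sum_k l_jk^2 exp(i n theta_jk) / sum_k l_jk^2` over Voronoi
  neighbours `k` of cell `j`, where `l_jk` is the shared Voronoi edge
  length and `theta_jk` the bond angle to the anterior–posterior axis;
  `|psi_4| = 1` for a perfect rectangular neighbourhood, 0 for a disordered
  one. Global order with standard errors, and two-point correlators
  `C_n(r) = <psi_n(r) psi_n*(0)>`.
- **Translational order.** Pair correlation functions `g(r) - 1` (isotropic
  and A–P / D–V restricted) normalized cell-by-cell with an *effective
  volume* (exact annulus-rectangle intersection) correction that removes
  finite-size edge bias.
- **Division choreography statistics.** Nematic circular mean
  `theta_bar = 1/2 arg(sum exp(2 i theta))` and angular dispersion
  `s = sqrt(2 (1 - R2))`, von Mises fits in doubled-angle space, mitotic
  wave-speed fits (position vs. time), exponential doubling-time fits, and
  detection of >45° pre-division axis reorientations.
- **Division-driven tissue flow.** The renormalized active-elastic problem
  `lap(v) + 1/(1-2 nu) grad(div v) = 0` with dividing cells modelled as
  circular Eshelby inclusions with eigenstrain
  `eps* = (M/2) I + q (2 n n^T - I)`; closed-form exterior fields, a P1
  finite-element Dirichlet solver on punctured domains, deterministic
  fitting of the amplitudes (M, q), and the scale-invariant velocity
  residual `R` used to score predictions.
- **Vertex-model division waves.** A 2D vertex model (target shape index
  `p0 = P/sqrt(A) = 4`, the perfect square) that reproduces the generation
  of fourfold order by oriented division waves — and its destruction by
  randomly oriented divisions.
- **Synthetic germband generator.** Track-level emulation of the study
  conditions (sequential parasegment rows, two orthogonal mitotic phase
  waves with distinct A–P and D–V speeds, von Mises division axes,
  exponential growth with a ~10 h doubling time), plus Poisson-disc nulls
  and noisy-lattice ordered controls with a two-sample Kolmogorov–Smirnov
  comparison.
- **Curved-surface support.** Discrete Gaussian/mean curvature and
  heat-method geodesics on triangulated surfaces, so distances and areas
  can be taken on curved tissue domains.

## Worked example

```python
import numpy as np
from germorder import (SyntheticGermbandParams, synth_germband,
                       voronoi_neighbors, psi_n, global_order,
                       fit_wave_speed, doubling_time)

rz = synth_germband(SyntheticGermbandParams(n_rows=8, cells_per_row=8, seed=0))

snap = rz.snapshots[-1]
graph = voronoi_neighbors(snap)
mag, se = global_order(psi_n(snap, graph, 4))
print(f"final global |psi4| = {mag:.3f} +/- {se:.3f}  ({len(snap)} cells)")

ap = fit_wave_speed(rz.events, "AP", wave="wave1")
dv = fit_wave_speed(rz.events, "DV", wave="wave1")
t, n = rz.cell_counts()
tau = doubling_time(t, n)
print(f"wave-1 speeds: A-P {ap.value:.2f} +/- {ap.stderr:.2f} um/h, "
      f"D-V {dv.value:.2f} +/- {dv.stderr:.2f} um/h")
print(f"doubling time {tau.value:.2f} h")
```

prints

```
final global |psi4| = 0.841 +/- 0.014  (256 cells)
wave-1 speeds: A-P 7.23 +/- 0.18 um/h, D-V 18.59 +/- 0.48 um/h
doubling time 10.43 h
```

The oriented division waves leave the synthetic germband strongly fourfold
ordered, and the wave-speed and growth fits recover the configured
choreography (A–P 7.5 um/h, D–V 19.2 um/h, doubling time 10 h) to within
two standard errors; the slight attenuation of the A–P slope is the
expected errors-in-variables effect of the within-row D–V propagation
delay, which adds timing scatter to the across-row fit. The D–V fit pools
both sides of the ventral midline and uses times relative to the first
division of each parasegment's wave.

A single TOML config drives the same analysis from the shell:

```bash
germorder run config.toml      # synth -> order -> correlate -> divstats -> flow -> simulate
germorder fixtures --outdir fixtures --seed 0
```

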