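# recres — recurrence resonance in small stochastic recurrent networks

`recres` is a research toolkit for studying **recurrence resonance (RR)**:
the noise-induced maximization of temporal mutual information in a recurrent
neural network at intermediate noise strength, where stochastic fluctuations
unmask attractors that the deterministic dynamics cannot reach.  It is aimed
at computational-neuroscience and neuromorphic-computing researchers who
want a fully generative, seed-reproducible pipeline for small (5- and
10-neuron) networks: no external data is needed — connectivity, dynamics and
statistics are all generated and analyzed by the package.

## The model

A network of `n` neurons with continuous states `u_i ∈ [−1, 1]` evolves
synchronously as

```
u_i(t+1) = tanh( Σ_j w_ij u_j(t) + r η_i(t) ),    η_i(t) ~ N(0, 1) i.i.d.
```

with noise strength `r ≥ 0`.  States are binarized post hoc (`s_i = 1` iff
`u_i > 0`) and encoded as integers `z = Σ_k s_k 2^(k−1)`.  From the symbol
sequence the package estimates, with plugin (maximum-likelihood) estimators
in bits:

* entropy `H(X) = −Σ P(x) log₂ P(x)` and temporal mutual information
  `I(z_t ; z_{t+1})` — RR is detected where `I` has an interior maximum in
  `r` while `H` is elevated but not saturated;
* first-order transfer entropy `TE(A→B) = H(B'|B) − H(B'|B,A)` between the
  subsystems A (neurons 1–5) and B (neurons 6–10);
* the empirical state-transition matrix (STM)
  `T_xy = N_xy / Σ_k N_xk`, its visitation marginal `P_x`, the gain
  `G(x) = P_x · 2^m` against the uniform baseline `P_uni = 1/2^m`, and the
  diagonal stability `T_xx`, from which states are classified as **strong
  attractors** (`G > 2` and `T_xx > 1.5 ×` the mean diagonal), **weak
  attractors** (`G > 1` otherwise; subtypes: high-stability traps vs
  low-stability *structural hubs*), or **transient noise** (`G ≤ 1`).

Connectivity comes in three conditions: **quantum logic** (an order-theoretic
topology mirroring the pasting of Boolean algebras into a non-distributive
orthomodular lattice — strong self-coupling, one weight class on the
within-block squares, another on the cross-block background), a strictly
**diagonal** control, and a **broken quantum logic** control whose background
cells are permuted while conserving per-class counts.  Weights are sampled
from truncated normal distributions confined to per-class intervals (e.g.
strong 0.7–1.0 at 5 neurons, 0.95–1.05 at 10) and scaled by a global factor
`W ∈ {1, 2, 5, 10}`.  A companion `lattice` module builds the rough-set
closure lattice of any thresholded weight matrix — fixed points of
`Cl(F) = R*(r*(F))` ordered by inclusion — and exports Hasse diagrams.

## Worked example

```python
import numpy as np
from recres import (condition_spec, build_weight_matrix, scale,
                    SimulationConfig, simulate, build_stm, classify,
                    noise_scan, find_peak)

# 10-neuron quantum-logic network, weights doubled (W = 2)
spec = condition_spec("ten_ql", seed=3)
wm = scale(build_weight_matrix(spec), 2.0)

# where does mutual information resonate?
scan = noise_scan(spec, W=2.0, grid=range(0, 7), trials=5,
                  steps=100_000, observables=("entropy", "mi"), seed=0)
print(find_peak(scan, "mi"))      # -> (1.0, 6.3664..., 0.1593...)

# attractor landscape at the resonance peak
traj = simulate(wm, SimulationConfig(steps=100_000, noise_strength=1.0, seed=7))
model = build_stm(traj.encoded, m=10)
cls = classify(model)
strong = cls.states_with("strong")
print(len(strong), model.diag[strong].mean())   # -> 136 0.7678...
```

The scan reports the recurrence-resonance peak at noise strength `r = 1.0`
with a mean temporal MI of ≈6.4 bits (well above the ≈3.5-bit plugin floor
of a 10-bit state space at 10⁵ samples).  At that noise level 136 of the
1024 states classify as strong attractors, and their mean self-transition
probability ≈0.77 — the system hops between many moderately deep wells, the
"edge of chaos" regime the quantum-logic topology produces.

From the shell, the same machinery is exposed as subcommands:

```bash
recres lattice --blocks 3,2              # 10-element pasted lattice, non-distributive
recres scan --condition five_ql_inhibitory --steps 20000 --trials 20 --out scan.csv
recres te --trials 20 --out te_stats.json
recres replicate fig8 --outdir runs      # STM heatmaps at the resonance peak
```

## Layout

```
src/recres/
  lattice.py        rough-set closures, pasted lattices, Hasse diagrams
  connectivity.py   truncated-normal weight sampling, condition specs, I/O
  dynamics.py       stochastic tanh simulation, binarization, encoding
  infometrics.py    plugin H / MI / TE estimators, ensemble noise scans
  attractors.py     STM estimation, gain/stability classification, energies
  experiments.py    figure protocols, ANOVA / t-test condition comparisons
  plotting.py       STM heatmaps, scan curves, rasters, classification maps
  cli.py            thin `recres` command-line surface
docs/methods.md     modelling assumptions, parameter choices, limitations
```
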