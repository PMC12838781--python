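# Methods

This note records the model, the parameter choices that matter, the design
decisions made where the construction was genuinely open, and what the
package's synthetic conditions do and do not establish.

## Dynamics

The network is a stochastic continuous-state recurrent net,
`u(t+1) = tanh(W_eff u(t) + r η(t))` with `W_eff = W · w`, `w` the sampled
coupling matrix, `W` a global scaling factor and `η` i.i.d. standard normal
per neuron per step (one draw per neuron per step, inside the tanh argument).
Binarization (`s_i = 1 iff u_i > 0`, ties to 0) is applied after simulation;
encoding is least-significant-bit-first, so neuron 1 contributes `2⁰`.

* **Initial state**: drawn uniformly from `[−1, 1]^n` from the run's seed.
  The zero state is a fixed point of the noiseless dynamics, so a
  deterministic zero start would be degenerate; a random start is the
  neutral choice.  Configurable (`"zero"` or an explicit vector).
* **Burn-in**: none by default — all recorded steps enter the statistics;
  a configurable burn-in exists.  Run lengths are 20,000 steps for 5-neuron
  systems and subsystem observations (the 2⁵-state space is ergodically
  sampled well before that) and 100,000 steps for the 10-neuron global
  state space, which at 2¹⁰ states is still undersampled — deliberately so,
  see the plugin-bias discussion below.
* **Ensembles**: 20 trials per condition.  Each trial draws its own weight
  matrix from a per-trial seed and keeps it fixed across the noise grid; the
  noise stream is independent per grid point.  All per-trial/per-point seeds
  derive from one master seed through a `SeedSequence` tree, so every
  ensemble is exactly reproducible and any sub-computation can be replayed.
  The ensemble path (`simulate_ensemble`) advances all trials in lock-step
  from a single shared noise stream (one column per trial), which is what
  makes 20 × 10⁵-step scans run in seconds per grid point.

## Connectivity conditions

Weights are sampled per cell class from a truncated normal on `[p, q]` with
`μ = (p+q)/2`.  The class intervals are: 5-neuron — strong 0.7–1.0,
intermediate 0.2–0.3, weak/negligible 0.0–0.05, inhibitory −0.8…−0.4
(−0.26…−0.16 for the diagonal-control inhibitory variant); 10-neuron —
strong 0.95–1.05, negligible 0.02–0.08, inhibitory −0.75…−0.55.

* **σ of the class distributions** is not fixed by the ranges; the default
  is `σ = (q−p)/4`, which puts ≈95% of the untruncated mass inside `[p, q]`
  so the truncation reshapes the tails rather than the bulk.  Configurable
  per class.  Sampling is exact (inverse-CDF truncated normal), not
  clipping, which would pile mass on the interval edges.
* **Cell layout of the quantum-logic condition.**  The block partitions are
  3+2 (5 neurons) and 2+5+3 (10 neurons).  The layout adopted is: strong
  weights on the *diagonal* (self-coupling); one class on the within-block
  off-diagonal squares; another on the cross-block background.  For the
  excitatory 5-neuron variant the block squares are weak and the background
  intermediate; in the inhibitory variants the block squares are inhibitory
  and the background negligible.  This reading was selected from the
  candidate layouts by three structural constraints that must hold
  simultaneously: (i) thresholding the weights must reproduce the pasted
  relation (diagonal plus cross-block pairs), which is provably the unique
  block-structured relation whose closure fixed points form the pasted
  orthomodular lattice (a full block-diagonal relation yields only the 2^b
  unions of blocks); (ii) the resonance peak must sit near `r = 1` at
  `W = 1` — layouts with all-to-all strong blocks give per-neuron drives of
  ≈5–8 and freeze completely (entropy 0) for `r ≲ 2.5`; (iii) within-block
  E/I balance must keep the network metastable rather than bistable, which
  is what produces the many moderately-sticky strong attractors
  (`T_xx ≈ 0.8`, `G` up to ~5–20) observed at the `W = 2` resonance.  The
  layout is a declared reconstruction — the cell-level pattern is
  figure-only information — and remains a configuration input
  (`class_assignment`).
* **Diagonal control**: strong self-coupling only; the 10-neuron control
  eliminates off-diagonal entries exactly (class `None` → 0.0), the
  5-neuron variants keep weak or mildly inhibitory off-diagonals.
* **Broken quantum logic**: all non-strong cells (block squares plus
  background) are jointly permuted among their positions with values and
  class labels moving together, so the entry multiset, per-class counts and
  density are conserved while the block topology is destroyed.  Each trial
  draws its own permutation.
* **Symmetry**: entries are sampled independently per directed cell (the
  construction does not imply `w_ij = w_ji`); a symmetric mode exists.

## Information estimators

All estimators are plugin (maximum-likelihood) with base-2 logs, zero cells
skipped, and **no bias correction**.  This is a feature, not an oversight:
at 2¹⁰ states and 10⁵ samples the temporal-MI estimate of an i.i.d. uniform
sequence is ≈3.5 bits of pure finite-sample bias, and the analysis reads
resonance off the curve's interior peak *above* that floor.  Correcting the
bias would change every reported magnitude.  A shuffle-surrogate utility
(`shuffle_surrogate`) isolates the bias when needed.  Mutual information of
a trajectory always means the consecutive-state pairing
`I(z_t ; z_{t+1})` over the `T−1` transitions; transfer entropy is
first-order (one step of target history), estimated from the joint of
`(B_{t+1}, B_t, A_t)`.

## Noise grids

The default scan grid is the integers 0–18.  The unit resolution is itself
part of the protocol reconstruction: the reported facts "resonance at
r = 1.0" and "the `W = 2` inhibitory peak more than doubles the `W = 1`
peak" are only mutually consistent at unit resolution — on a fine grid the
`W = 1` peak sits near `r ≈ 0.4–0.6` with nearly the same height as the
`W = 2` peak, while a unit grid samples it at `r = 1` on its decaying flank.
Transfer-entropy comparisons use `{0, 0.25, …, 3} ∪ {4, 5, 6}`, fine where
the peaks live.  Peak values are therefore grid-resolution-sensitive, and
the grids are fixed constants (`DEFAULT_NOISE_GRID`, `TE_NOISE_GRID`)
rather than per-call defaults chosen ad hoc.

## Attractor classification

From the STM (rows of unvisited states are left all-zero and flagged —
normalizing a zero row is undefined and a uniform fill would fabricate
transitions): transient iff `G(x) ≤ 1`; strong iff `G(x) > 2` **and**
`T_xx > 1.5 ×` baseline; weak otherwise, with subtypes high-stability
(`T_xx ≥` baseline) and structural hub (`T_xx <` baseline).  The baseline is
the arithmetic mean of `T_xx` over *visited* states (unvisited diagonals are
undefined).  Classification defaults to visited states only; an all-states
option exists.  The Hopfield-style energy `E(s) = −½ Σ_{i≠j} w_ij s_i s_j`
and its strict Hamming-1 local minima are reported descriptively (with
barrier heights as minimum neighbor excess); classification uses only the
operational STM thresholds.

## Statistics

Peak-TE comparisons across connectivity conditions take, per trial, the TE
at the grid point maximizing the ensemble-mean curve (one shared `r*` per
condition keeps trials comparable), then one-way ANOVA across conditions and
pairwise independent t-tests (pooled variance by default, Welch optional).
Degenerate inputs (all-identical groups) are reported as such rather than
producing spurious statistics.

## What the synthetic conditions do and do not show

The generator emulates the stated study conditions: class intervals, block
structure, scaling factors, run lengths, trial counts.  Passing tests
establish that the estimators are exact (they match direct-summation oracles
to 1e−10), that the closure operator satisfies the closure axioms and
produces the pasted lattices, and that the simulated ensembles reproduce the
resonance phenomenology — monotone entropy with an interior MI peak, the
inhibitory amplification, the TE ordering at `W = 1`, and strong-attractor
stability near 0.8 at the `W = 2` resonance.  They do not establish
anything about real neural or memristive hardware data, and two quantities
are protocol-sensitive by nature: peak values depend on grid resolution, and
the `W = 2` TE ordering between the broken and intact quantum-logic
conditions is not stable under the weight-ensemble protocol — the per-draw
spread of the quantum-logic condition at `W = 2` (SD ≈ 0.1 bits) exceeds the
ordering margin, so that comparison is meaningful only for fixed draws.

## Known limitations

* Enumeration-based components (`build_lattice`, `local_minima`) are capped
  at universe size 20.
* The lattice module constructs the fixed-point lattice and Hasse diagram
  only; orthocomplement machinery (full orthomodularity verification) is out
  of scope.
* TE is first-order and discrete (no k-history, no continuous-state
  estimators); surrogate testing is limited to the shuffle utility.
* The ensemble path shares one noise stream across trials for speed; single
  trials replayed in isolation use their own stream and therefore match the
  ensemble statistically, not bitwise.
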