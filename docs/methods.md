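# Methods

## Dynamics

The latent state of a simulated individual is one vector of absolute
abundances over all node dimensions (D = Σᵢ dᵢ). It evolves by the
multiplicative gLV equation

dz/dt = z ⊙ (g + M z + Σⱼ uⱼ(t) bⱼ + ε), ε ~ N(0, σI),

integrated by forward Euler with a fixed step `dt`. Choices and their
rationale:

* **Integrator.** Plain forward Euler, no adaptive control. The model is
  presented as a discrete-time recursion and the noise term is redrawn
  independently at every integration step, which only has clean semantics on
  a fixed grid. `noise_var` (σ) is a *variance*; the per-step draw is
  `sqrt(noise_var) * N(0, 1)` per coordinate. Noise enters inside the
  parenthesis, i.e. it is multiplied by the abundance, so quiescent
  dimensions stay quiet.
* **Nonnegativity.** Euler steps can overshoot below zero; results are
  clamped to 0 after each step. Zero is the absorbing state of the
  multiplicative form, so a dimension with zero abundance (initially or by
  clamping) stays exactly zero forever — this is asserted, not approximated,
  and holds under any noise or intervention.
* **Divergence.** Random communities can be unstable (strong mutualistic
  pairs overpowering the self-interaction penalty). Any non-finite abundance
  aborts with an error naming the step and coordinates; there is no silent
  capping, since a capped trajectory would be a different model.
* **Sampling grid.** `burn_in` integration steps are discarded ("time to
  first sample"), then every `downsample`-th step is recorded until
  `n_timepoints` rows exist. With `burn_in=0`, row 0 is the initial state.
  Intervention magnitude series are indexed by recorded time point; between
  records (and during burn-in) the most recent (or first) magnitude applies,
  so an always-on intervention acts from the very first integration step.
* **Matrix orientation.** `M[r, c]` is the effect of dimension *c*'s
  abundance on dimension *r*'s per-capita growth; interaction blocks are
  (target-dim × source-dim).

Observation: X is the row-normalization of Z (an all-zero row — an extinct
community — yields an all-zero X and Y row with a logged warning rather than
an error, so harsh parameter sweeps complete); Y draws one multinomial of
size `n_reads` per time point. Read depth is deliberately the *only*
sequencing artifact modeled — no PCR bias or sequencing error.

## Random parameters

Defaults when the user supplies none: growth rates U(−1, 1); initial
abundances Lognormal(0, 1), independently zeroed with probability `p_zero`.
The interaction ensemble draws symmetric-position off-diagonal pairs from a
bivariate normal with per-coordinate variance `pair_var` and correlation
`pair_corr` (an analytic Cholesky keeps ρ = ±1 exact, so ρ = 1 gives exactly
symmetric pairs), then zeroes each off-diagonal entry independently with
probability 1 − C, then sets the diagonal to −`self_penalty`. The order
matters: pairs → sparsify → diagonal; the diagonal is never sparsified, and
the two members of a pair are sparsified independently, so a correlated pair
can lose one member. The sign convention (user supplies d ≥ 0, diagonal is
−d) guarantees self-limitation. No spectral rescaling is applied: stability
is the user's responsibility, and the classic random-matrix criterion
(√(D·C·pair_var) < d) is a useful guide. The bundled tests and examples use
`pair_var = 0.25` for communities of D ≈ 10–20 precisely to sit in the
stable regime; at `pair_var = 1` such communities frequently diverge.

## Cohorts and case-control

A cohort shares growth rates, interactions and interventions bit-for-bit
across individuals; only initial abundances are resampled, plus independent
noise and read streams. Seeding uses a spawning hierarchy from one master
seed, one substream per individual, so enlarging a cohort never perturbs
existing individuals (prefix stability, tested).

Case-control mode draws **one** response vector per cohort, coordinatewise
U(−s/2, s/2) on the intervention node, applied to cases as an always-on
(u ≡ 1) intervention; a per-individual response would confound the meaning
of the effect size s. Case count is round-half-away-from-zero of
n·case_ratio. `matched_seeds=True` pairs case k with control k on identical
initial abundances and noise/read streams — at s = 0 the two arms are then
bitwise identical, which isolates the intervention as the only difference;
the default is unmatched (fully independent draws), since real cohorts are
unpaired.

## Inference

Dividing the gLV equation by z linearizes it: d(ln z)/dt = g + M z + u b.
The fit regresses F (rows: per-unit-time changes between successive samples)
on a design stacking the abundances, a row of ones and the intervention
magnitudes, solving (M, g, b) = Fᵀ Ydesᵀ (Ydes Ydesᵀ + λI)⁻¹ via a
symmetric linear solve, never an explicit inverse. Multiple individuals'
designs are concatenated before solving.

* **F definition.** Default is log-increments `(ln(z_{t+1}+c) − ln(z_t+c))/Δt`
  — the transform under which parameters enter linearly. A `linear` mode
  (`Δz/Δt/(z_t+c)`) is exposed; on noiseless Euler-generated data it inverts
  the generator nearly exactly, whereas log-increments carry an O(dt)
  discretization bias. The pseudocount c defaults to 10⁻⁶ × mean positive
  abundance, required because zeros are legal abundances but not legal
  logarithm arguments.
* **Regularizer.** λ·identity on all coefficients — the minimal reading;
  per-block penalties are out of scope. λ = 0 with a singular design raises
  an error advising a positive penalty.
* **Identifiability.** The method presumes absolute abundances, dense
  sampling and little noise. A column of M multiplying an extinct taxon is
  mathematically unidentifiable, so recovery experiments screen for
  persistence (all taxa alive at the end). On persistent noiseless 3-taxon
  systems at dt = 0.01 the default mode recovers M to a few percent; the
  error is bias-dominated, grows with the magnitude of per-capita rates, and
  degrades quickly with observation noise.

## Realism metrics

Alpha diversity (Shannon default; Simpson and richness selectable), exact
zero fraction (sparsity), and per-feature differential abundance: two-sided
Wilcoxon rank-sum on per-sample relative abundances with Benjamini-Hochberg
adjustment across features. Identical constant features get p = 1 (no
evidence) rather than NaN. The default sample unit is each individual's
final time point (endpoint comparison); all-points pooling is an option.
The procedure is a deliberately simple, replaceable default — the package
makes no claim that it is the best differential-abundance test, only a
consistent yardstick between two datasets.

## Visualization and projection

PCA is fit once on the pooled rows of all individuals so every trajectory
lives in one plane; per-individual fits would destroy comparability. It
consumes X by default (the observable scale; Z selectable). Axis signs are
fixed by making each component's largest-magnitude loading positive, making
the projection deterministic. Stacked bars renormalize within the chosen
node so single-node views of multi-node simulations still stack to 1.

## Power analysis

For a fixed simulated cohort, the latent endpoint X of every individual is
held fixed and only read sampling is replicated at each depth; power is the
fraction of replicates in which a rank-sum test on the most-affected feature
reaches p < 0.05. "Most affected" is the feature with the largest
standardized case-control shift in latent X — the noiseless truth a power
analysis conditions on — not the largest response-vector coordinate, because
interactions redistribute the perturbation away from its drive target. This
isolates sequencing depth as the variable under study; between-individual
biological variance is part of the fixed cohort. The bundled experiment
(n = 30, one 10-dimensional node, noiseless dynamics, effect size s = 3,
50 replicates per depth at R ∈ {30, 300, 3000}) places the detection
threshold inside the scanned range: power is moderate at 30 reads and
saturates by 300. At much smaller effect sizes biological variance dominates
and no read depth helps; at much larger ones even 30 reads suffice.

## What the synthetic data does and does not emulate

The generator reproduces the structural features of longitudinal
relative-abundance studies: compositionality, fixed read depth, zero
inflation via `p_zero` and extinctions, biological noise, interventions and
case-control designs. It does not emulate taxonomic structure, PCR or
sequencing error, nonuniform sampling times, between-individual parameter
variation, or strongly mutualistic ecosystems (where gLV itself misbehaves).
Passing tests therefore certify the pipeline's internal correctness and the
qualitative phenomena above, not distributional fidelity to any particular
empirical dataset — for that, compare against your own pilot data with the
realism metrics.

## Problem sizes

Test and example simulations use communities of 3–20 dimensions, 10–60
recorded time points, cohorts of 4–30 individuals, and Monte-Carlo sizes of
10⁵ draws for distribution checks and 50 replicates per condition for power
curves — sizes at which every reported quantity is stable to well within the
tolerances asserted, while the full suite runs in seconds.
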