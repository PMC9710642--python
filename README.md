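# glvsim

Synthetic longitudinal microbiome data from generalized Lotka-Volterra (gLV)
dynamics, for study design and power analysis.

Microbial relative-abundance timecourses are longitudinal, compositional,
noisy and stochastic, which makes classical closed-form power analysis a poor
fit — especially away from steady state. `glvsim` takes the direct route: it
simulates the full generative process (ecological dynamics → relative
abundances → sequencing reads), so any analysis you would run on real data
can be rehearsed on synthetic data under controlled, fully known conditions.

## The model

A simulated system is a set of *nodes* (data layers such as metagenomics and
metabolomics of one ecosystem, or two interacting ecosystems), with total
dimension *D*. Latent absolute abundances *z* evolve by the multiplicative
gLV equation with biological noise ε and interventions *j*:

    dz/dt = z ⊙ ( g + M z + Σ_j u_j(t) b_j + ε ),    ε ~ N(0, σI)

integrated by forward Euler with step *dt*. Observation mimics sequencing:
relative abundances *X_t = Z_t / Σ Z_t*, and counts at fixed read depth *R*

    Y_t ~ Multinomial(R, X_t).

When the user supplies no parameters, defaults are drawn as *g ~ U(−1, 1)*
and *z₀ ~ Lognormal(0, 1)*, and the interaction matrix follows the classic
random-community ensemble: symmetric-position pairs (M_ij, M_ji) from a
correlated bivariate normal, independent Bernoulli(*C*) sparsification of
off-diagonal entries, and a −*d* self-interaction diagonal.

Around that core:

* **cohorts** — many individuals sharing all gLV parameters, with initial
  abundances resampled per individual;
* **case-control splits** — cases receive an always-on intervention with one
  cohort-level random response vector *b_c ~ U(−s/2, s/2)* (effect size *s*);
* **inference** — ridge regression of time-scaled log-abundance changes,
  `(M, g, b) = F Yᵀ (Y Yᵀ + λI)⁻¹`, to fit gLV parameters from pilot
  timecourses;
* **realism metrics** — alpha-diversity distributions, per-feature rank-sum
  differential abundance with Benjamini-Hochberg correction, and sparsity;
* **power analysis** — detection power of a case-control difference as a
  function of sequencing read depth;
* **plots** — stacked-bar compositions and PCA trajectory projections.

## Worked example

`examples/case_control_power.py` asks the tool's central question — how deep
must sequencing be to detect an intervention in a 30-person cohort?

```text
cohort: 15 cases, 15 controls
most-affected feature: mg_2
  read depth    30: power 0.54
  read depth   300: power 0.98
  read depth  3000: power 1.00
```

At 30 reads per sample the case-control difference is found about half the
time; by 300 reads detection is nearly certain, and deeper sequencing buys
nothing — the read-depth decision for this hypothetical study. The other
examples cover single-timecourse simulation, gLV parameter recovery
(`relative Frobenius error of M: 0.0127` on noiseless data) and realism
comparison between cohorts.

## Command line

Every simulation parameter is exposed as a flag, a YAML config file, or both
(flags win); each run echoes its resolved configuration for byte-exact
reproduction:

```sh
glvsim generate --mode case-control --node-names mg,mb --node-dims 10,10 \
    --n-individuals 30 --intervention-node mb --effect-size 3 \
    --seed 1 --output-dir run1
glvsim infer --input-dir run1/cohort/controls --lam 1e-4 --output-dir fit1
glvsim metrics --dataset-a run1/cohort/cases --dataset-b run1/cohort/controls
glvsim plot --input-dir run1/cohort --kind pca --out trajectories.png
```

Outputs are plain TSV: per-node `<node>_Z.tsv` / `_X.tsv` / `_Y.tsv` matrices
per individual, parameter files, and a cohort manifest.

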