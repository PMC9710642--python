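"""Noisy generalized Lotka-Volterra integration and read sampling.

The latent dynamics follow the multiplicative gLV form

    dz/dt = z * (g + M z + sum_j u_j(t) b_j + eps),   eps ~ N(0, sigma I)

integrated by forward Euler with step ``dt``; biological noise ``eps`` is
redrawn every integration step (``sigma`` = ``noise_var`` is a variance).
Zero abundance is absorbing: a dimension that starts at 0 stays at exactly 0.
Negative Euler excursions are clamped to 0, the physical absorbing state.

Observation follows the sequencing model: relative abundances
``X_t = Z_t / sum(Z_t)`` and counts ``Y_t ~ Multinomial(R, X_t)`` with fixed
read depth ``R`` per time point.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import ConfigurationError, DivergenceError, DomainError
from .types import (
    InteractionMap,
    InterventionSpec,
    NodeSpec,
    SimulationConfig,
    Timecourse,
)

__all__ = ["glv_step", "simulate_timecourse", "to_relative", "sample_reads"]

logger = logging.getLogger(__name__)


def glv_step(
    z_prev: np.ndarray,
    growth: np.ndarray,
    M: np.ndarray,
    intervention_drive: np.ndarray,
    noise_draw: np.ndarray,
    dt: float,
    step: int | None = None,
) -> np.ndarray:
    """One forward-Euler step of the multiplicative gLV system.

    Returns ``z_prev + dt * z_prev * (growth + M @ z_prev + drive + noise)``
    with negative results clamped to 0.  Coordinates at exactly 0 remain 0.

    Raises
    ------
    DivergenceError
        If any coordinate becomes non-finite (overflow / blow-up).
    """
    z_prev = np.asarray(z_prev, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        rate = growth + M @ z_prev + intervention_drive + noise_draw
        z_new = z_prev + dt * z_prev * rate
    bad = ~np.isfinite(z_new)
    if bad.any():
        raise DivergenceError(step, np.flatnonzero(bad).tolist())
    return np.maximum(z_new, 0.0)


def simulate_timecourse(
    nodes: list[NodeSpec],
    interactions: InteractionMap,
    interventions: list[InterventionSpec] | None = None,
    config: SimulationConfig | None = None,
) -> Timecourse:
    """Integrate one individual and derive its Z, X, Y matrices.

    ``burn_in`` integration steps are discarded, then every
    ``downsample``-th step is recorded until ``n_timepoints`` rows are
    collected (the first record is the post-burn-in state; with
    ``burn_in=0`` row 0 holds the initial abundances).  Intervention
    magnitudes are indexed by recorded time point; during burn-in and
    between records the most recent (or first) magnitude applies, so an
    always-on intervention acts from the very first step.  Fully
    reproducible from ``config.seed``: noise and read sampling use
    independent seeded substreams.
    """
    if config is None:
        raise ConfigurationError("a SimulationConfig is required")
    interventions = interventions or []
    node_dims = {n.name: n.dim for n in nodes}
    if len(node_dims) != len(nodes):
        raise ConfigurationError("node names must be unique")
    interactions.validate(node_dims)

    D = sum(node_dims.values())
    g = np.concatenate([n.growth_rates for n in nodes])
    z0 = np.concatenate([n.initial_abundances for n in nodes])
    M = interactions.to_dense(node_dims)

    # per-recorded-step drive, summed over interventions on each target node
    T = config.n_timepoints
    drive = np.zeros((T, D))
    offsets = {}
    start = 0
    for n in nodes:
        offsets[n.name] = slice(start, start + n.dim)
        start += n.dim
    for iv in interventions:
        if iv.node not in node_dims:
            raise ConfigurationError(f"intervention targets unknown node {iv.node!r}")
        if iv.magnitudes.shape != (T,):
            raise ConfigurationError(
                f"intervention on {iv.node!r}: magnitudes has length "
                f"{iv.magnitudes.size}, expected n_timepoints={T}"
            )
        if iv.responses.shape != (node_dims[iv.node],):
            raise ConfigurationError(
                f"intervention on {iv.node!r}: responses has length "
                f"{iv.responses.size}, expected dim={node_dims[iv.node]}"
            )
        drive[:, offsets[iv.node]] += np.outer(iv.magnitudes, iv.responses)

    noise_ss, reads_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng_noise = np.random.default_rng(noise_ss)
    noise_sd = np.sqrt(config.noise_var)

    n_steps = config.burn_in + (T - 1) * config.downsample
    Z = np.empty((T, D))
    times = (config.burn_in + np.arange(T) * config.downsample) * config.dt
    z = z0.copy()
    k = 0
    for s in range(n_steps + 1):
        if s >= config.burn_in and (s - config.burn_in) % config.downsample == 0:
            Z[k] = z
            k += 1
        if s == n_steps:
            break
        r = min(max((s - config.burn_in) // config.downsample, 0), T - 1)
        noise = noise_sd * rng_noise.standard_normal(D)
        z = glv_step(z, g, M, drive[r], noise, config.dt, step=s)

    X = to_relative(Z)
    Y = sample_reads(X, config.n_reads, reads_ss)
    return Timecourse(
        node_names=[n.name for n in nodes],
        node_dims=node_dims,
        Z=Z,
        X=X,
        Y=Y,
        times=times,
    )


def to_relative(Z: np.ndarray) -> np.ndarray:
    """Row-normalize abundances to compositions.

    All-zero rows (extinct communities) map to all-zero rows with a logged
    warning rather than an error, so parameter sweeps do not abort.
    """
    Z = np.asarray(Z, dtype=float)
    if np.any(Z < 0):
        raise DomainError("abundances must be nonnegative")
    sums = Z.sum(axis=-1, keepdims=True)
    zero_rows = (sums == 0).ravel()
    if zero_rows.any():
        logger.warning(
            "to_relative: %d all-zero row(s) mapped to zero compositions", zero_rows.sum()
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(sums > 0, Z / np.where(sums == 0, 1.0, sums), 0.0)
    return X


def sample_reads(X: np.ndarray, n_reads: int, seed=0) -> np.ndarray:
    """Draw one multinomial of size ``n_reads`` per row of ``X``.

    Rows must sum to 1 within 1e-9 or be all zero (yielding an all-zero
    count row).  Draws across rows are independent.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if n_reads < 1:
        raise ConfigurationError("n_reads must be >= 1")
    sums = X.sum(axis=1)
    ok = np.isclose(sums, 1.0, rtol=0.0, atol=1e-9) | (sums == 0)
    if not ok.all():
        bad = int(np.flatnonzero(~ok)[0])
        raise DomainError(
            f"row {bad} sums to {sums[bad]!r}; rows must sum to 1 within 1e-9 or be all zero"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.zeros(X.shape, dtype=np.int64)
    for t in range(X.shape[0]):
        if sums[t] > 0:
            Y[t] = rng.multinomial(n_reads, X[t] / sums[t])
    return Y
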