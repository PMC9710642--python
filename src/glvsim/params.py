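"""Default gLV parameter samplers and the random interaction-matrix ensemble.

When no user-supplied parameters are given, growth rates are drawn uniformly
on (-1, 1) and initial abundances from a standard log-normal (optionally
zeroed with probability ``p_zero``).  Interaction matrices follow the classic
random-community construction: symmetric-position off-diagonal pairs
``(M[i, j], M[j, i])`` are drawn jointly from a bivariate normal with
per-coordinate variance ``pair_var`` and correlation ``pair_corr``, each
off-diagonal entry is independently zeroed with probability ``1 - C``
(``C`` is the connectivity), and every diagonal entry is set to the negative
self-interaction penalty ``-d`` so each dimension limits its own growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .types import InteractionMap, NodeSpec

__all__ = [
    "MatrixGenConfig",
    "sample_growth_rates",
    "sample_initial_abundances",
    "sample_interaction_matrix",
    "random_nodes",
]


@dataclass
class MatrixGenConfig:
    """Settings for the random interaction-matrix ensemble.

    Parameters
    ----------
    connectivity
        Probability ``C`` in [0, 1] that an off-diagonal entry is retained.
    self_penalty
        Nonnegative ``d``; the diagonal is set to ``-d``.
    pair_var
        Per-coordinate variance of the bivariate normal generating
        symmetric-position pairs.  ``pair_var=1`` gives the unit-variance
        ensemble.
    pair_corr
        Correlation ``rho`` in [-1, 1] between ``M[i, j]`` and ``M[j, i]``;
        ``rho=1`` yields symmetric (mutualistic/competitive) pairs, ``rho=-1``
        predator-prey pairs.
    seed
        Seed for pair draws and sparsification.
    """

    connectivity: float = 0.5
    self_penalty: float = 1.0
    pair_var: float = 1.0
    pair_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.connectivity <= 1.0:
            raise ConfigurationError("connectivity must be in [0, 1]")
        if self.self_penalty < 0:
            raise ConfigurationError("self_penalty must be >= 0")
        if self.pair_var <= 0:
            raise ConfigurationError("pair_var must be > 0")
        if not -1.0 <= self.pair_corr <= 1.0:
            raise ConfigurationError("pair_corr must be in [-1, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_growth_rates(dim: int, seed=0) -> np.ndarray:
    """Draw ``dim`` growth rates uniformly on (-1, 1)."""
    if dim < 1:
        raise ConfigurationError(f"dim must be >= 1, got {dim}")
    return _rng(seed).uniform(-1.0, 1.0, size=dim)


def sample_initial_abundances(dim: int, p_zero: float = 0.0, seed=0) -> np.ndarray:
    """Draw ``dim`` initial abundances from log-normal(0, 1), zeroed w.p. ``p_zero``.

    Zeros model dimensions absent from an individual; in the multiplicative
    gLV dynamics they stay extinct for the whole timecourse.
    """
    if dim < 1:
        raise ConfigurationError(f"dim must be >= 1, got {dim}")
    if not 0.0 <= p_zero <= 1.0:
        raise ConfigurationError(f"p_zero must be in [0, 1], got {p_zero}")
    rng = _rng(seed)
    z0 = rng.lognormal(mean=0.0, sigma=1.0, size=dim)
    if p_zero > 0:
        z0 = np.where(rng.random(dim) < p_zero, 0.0, z0)
    return z0


def sample_interaction_matrix(node_dims: dict[str, int], config: MatrixGenConfig) -> InteractionMap:
    """Build a random block interaction map over the given nodes.

    The full ``D x D`` matrix (``D`` = sum of node dimensions) is drawn first —
    correlated pairs, then sparsification, then the ``-d`` diagonal — and
    partitioned into node-pair blocks along the node boundaries, so
    cross-node and within-node interactions come from one ensemble.
    """
    for name, dim in node_dims.items():
        if dim < 1:
            raise ConfigurationError(f"node {name!r}: dim must be >= 1, got {dim}")
    rng = _rng(config.seed)
    D = sum(node_dims.values())
    M = np.zeros((D, D))

    # correlated symmetric-position pairs, upper/lower triangle
    iu, ju = np.triu_indices(D, k=1)
    n_pairs = iu.size
    if n_pairs:
        # analytic Cholesky of pair_var * [[1, rho], [rho, 1]]: exact at rho = +/-1
        rho = config.pair_corr
        sd = np.sqrt(config.pair_var)
        L = sd * np.array([[1.0, 0.0], [rho, np.sqrt(max(1.0 - rho * rho, 0.0))]])
        pairs = rng.standard_normal((n_pairs, 2)) @ L.T
        M[iu, ju] = pairs[:, 0]
        M[ju, iu] = pairs[:, 1]

    # independent Bernoulli(C) retention of each off-diagonal entry
    keep = rng.random((D, D)) < config.connectivity
    off = ~np.eye(D, dtype=bool)
    M[off & ~keep] = 0.0

    np.fill_diagonal(M, -config.self_penalty)
    return InteractionMap.from_dense(M, node_dims)


def random_nodes(
    node_dims: dict[str, int], p_zero: float = 0.0, seed=0
) -> list[NodeSpec]:
    """Convenience: nodes with default-sampled growth rates and initial abundances."""
    rng = _rng(seed)
    return [
        NodeSpec(
            name=name,
            dim=dim,
            growth_rates=sample_growth_rates(dim, rng),
            initial_abundances=sample_initial_abundances(dim, p_zero, rng),
        )
        for name, dim in node_dims.items()
    ]
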