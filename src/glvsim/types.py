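"""Domain types for the gLV synthetic-data engine.

A simulated system is a collection of *nodes* — data layers such as a
metagenomics and a metabolomics view of the same ecosystem — each with its own
dimensionality, growth rates and initial abundances.  Directed interactions
between (and within) nodes live in an :class:`InteractionMap`; external
perturbations are :class:`InterventionSpec` objects.  One simulated individual
is a :class:`Timecourse` holding the latent absolute abundances ``Z``, the
latent relative abundances ``X`` and the multinomially sampled read counts
``Y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "NodeSpec",
    "InteractionMap",
    "InterventionSpec",
    "SimulationConfig",
    "Timecourse",
]


@dataclass
class NodeSpec:
    """One data layer of the simulated system.

    Parameters
    ----------
    name
        Identifier used in interaction blocks, interventions and file names.
    dim
        Number of dimensions (taxa, metabolites, ...) in this node.
    growth_rates
        Intrinsic per-capita growth rates, length ``dim`` (per unit time).
    initial_abundances
        Nonnegative abundances at time zero, length ``dim`` (arbitrary units).
    """

    name: str
    dim: int
    growth_rates: np.ndarray
    initial_abundances: np.ndarray

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigurationError(f"node {self.name!r}: dim must be >= 1, got {self.dim}")
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.initial_abundances = np.asarray(self.initial_abundances, dtype=float)
        if self.growth_rates.shape != (self.dim,):
            raise ConfigurationError(
                f"node {self.name!r}: growth_rates has shape {self.growth_rates.shape}, "
                f"expected ({self.dim},)"
            )
        if self.initial_abundances.shape != (self.dim,):
            raise ConfigurationError(
                f"node {self.name!r}: initial_abundances has shape "
                f"{self.initial_abundances.shape}, expected ({self.dim},)"
            )
        if np.any(self.initial_abundances < 0):
            raise ConfigurationError(f"node {self.name!r}: initial abundances must be >= 0")


class InteractionMap:
    """Block-structured directed interactions between node pairs.

    ``blocks[(target, source)]`` is a matrix of shape ``(dim_target, dim_source)``
    whose entry ``(r, c)`` is the effect of source dimension ``c`` on the
    per-capita growth of target dimension ``r``.  Missing pairs act as zero
    matrices.
    """

    def __init__(self, blocks: dict[tuple[str, str], np.ndarray] | None = None):
        self.blocks: dict[tuple[str, str], np.ndarray] = {}
        if blocks:
            for key, mat in blocks.items():
                self.blocks[key] = np.asarray(mat, dtype=float)

    def validate(self, node_dims: dict[str, int]) -> None:
        for (target, source), mat in self.blocks.items():
            if target not in node_dims or source not in node_dims:
                raise ConfigurationError(
                    f"interaction block ({target!r}, {source!r}) references an unknown node"
                )
            expected = (node_dims[target], node_dims[source])
            if mat.shape != expected:
                raise ConfigurationError(
                    f"interaction block ({target!r}, {source!r}) has shape {mat.shape}, "
                    f"expected {expected}"
                )

    def block(self, target: str, source: str, node_dims: dict[str, int]) -> np.ndarray:
        """Return the stored block, or a zero matrix for a missing pair."""
        if (target, source) in self.blocks:
            return self.blocks[(target, source)]
        return np.zeros((node_dims[target], node_dims[source]))

    def to_dense(self, node_dims: dict[str, int]) -> np.ndarray:
        """Assemble the full D x D matrix in the given node order."""
        self.validate(node_dims)
        names = list(node_dims)
        offsets = _offsets(node_dims)
        D = sum(node_dims.values())
        M = np.zeros((D, D))
        for target in names:
            for source in names:
                r0, r1 = offsets[target]
                c0, c1 = offsets[source]
                M[r0:r1, c0:c1] = self.block(target, source, node_dims)
        return M

    @classmethod
    def from_dense(cls, M: np.ndarray, node_dims: dict[str, int]) -> "InteractionMap":
        """Partition a dense D x D matrix into node-pair blocks."""
        M = np.asarray(M, dtype=float)
        D = sum(node_dims.values())
        if M.shape != (D, D):
            raise ConfigurationError(f"dense matrix has shape {M.shape}, expected ({D}, {D})")
        offsets = _offsets(node_dims)
        blocks = {}
        for target in node_dims:
            for source in node_dims:
                r0, r1 = offsets[target]
                c0, c1 = offsets[source]
                blocks[(target, source)] = M[r0:r1, c0:c1].copy()
        return cls(blocks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMap):
            return NotImplemented
        if set(self.blocks) != set(other.blocks):
            return False
        return all(np.array_equal(self.blocks[k], other.blocks[k]) for k in self.blocks)


def _offsets(node_dims: dict[str, int]) -> dict[str, tuple[int, int]]:
    out, start = {}, 0
    for name, dim in node_dims.items():
        out[name] = (start, start + dim)
        start += dim
    return out


@dataclass
class InterventionSpec:
    """A time-varying perturbation of one node.

    ``magnitudes`` is a length-``|T|`` series (one value per recorded time
    point); ``responses`` is a per-dimension response vector for the target
    node.  The drive added to the gLV growth term at recorded step ``t`` is
    ``magnitudes[t] * responses``.
    """

    node: str
    magnitudes: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.magnitudes.ndim != 1 or self.responses.ndim != 1:
            raise ConfigurationError("intervention magnitudes and responses must be 1-D")


@dataclass
class SimulationConfig:
    """Integration and read-sampling settings for one timecourse.

    Parameters
    ----------
    n_timepoints
        Number of recorded time points ``|T|``.
    dt
        Euler step size (time units).
    noise_var
        Variance of the per-coordinate Gaussian biological noise added inside
        the growth term at every integration step.
    n_reads
        Total reads ``R`` drawn per time point by the multinomial sampler.
    downsample
        Record every ``downsample``-th integration step.
    burn_in
        Integration steps discarded before the first recorded sample
        ("time to first sample").
    seed
        Seed for the noise and read-sampling streams.
    """

    n_timepoints: int
    dt: float = 0.01
    noise_var: float = 0.01
    n_reads: int = 10_000
    downsample: int = 1
    burn_in: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ConfigurationError("n_timepoints must be >= 1")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.noise_var < 0:
            raise ConfigurationError("noise_var must be >= 0")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        if self.downsample < 1:
            raise ConfigurationError("downsample must be >= 1")
        if self.burn_in < 0:
            raise ConfigurationError("burn_in must be >= 0")


@dataclass
class Timecourse:
    """Simulated data for one individual.

    ``Z`` holds latent absolute abundances, ``X`` latent relative abundances
    (rows sum to 1, or are all zero for an extinct community), and ``Y`` the
    observed read counts (rows sum to the read depth ``R``).  All three are
    ``|T| x D`` with columns ordered by node.
    """

    node_names: list[str]
    node_dims: dict[str, int]
    Z: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    times: np.ndarray
    label: str = field(default="")

    @property
    def D(self) -> int:
        return self.Z.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.Z.shape[0]

    def node_slice(self, node: str) -> slice:
        """Column slice of the named node within Z/X/Y."""
        if node not in self.node_dims:
            raise ConfigurationError(f"unknown node {node!r}")
        start = 0
        for name, dim in self.node_dims.items():
            if name == node:
                return slice(start, start + dim)
            start += dim
        raise AssertionError("unreachable")

    def column_names(self) -> list[str]:
        return [f"{n}_{i}" for n in self.node_names for i in range(self.node_dims[n])]
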