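"""Exception hierarchy for glvsim."""

from __future__ import annotations


class GlvsimError(Exception):
    """Base class for all glvsim errors."""


class ConfigurationError(GlvsimError, ValueError):
    """A configuration value or shape is invalid."""


class DomainError(GlvsimError, ValueError):
    """An input violates a mathematical precondition (e.g. negative abundance)."""


class DivergenceError(GlvsimError, FloatingPointError):
    """The integrator produced a non-finite abundance.

    Carries the integration step index and the offending coordinate so harsh
    parameter sweeps can report exactly where a community blew up.
    """

    def __init__(self, step: int | None, coordinates: list[int]):
        self.step = step
        self.coordinates = coordinates
        where = f"step {step}" if step is not None else "unknown step"
        super().__init__(
            f"non-finite abundance at {where}, coordinate(s) {coordinates}; "
            "the community diverged (try a larger self-interaction penalty, "
            "smaller interaction variance, or smaller dt)"
        )


class InferenceError(GlvsimError, ValueError):
    """The ridge normal equations could not be solved."""
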