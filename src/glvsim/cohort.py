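"""Multi-individual cohorts and case-control splits.

A cohort shares all gLV parameters (growth rates, interaction matrix,
interventions) across individuals; only initial abundances are resampled per
individual, together with independent noise and read-sampling streams.  The
case-control mode perturbs the case arm with an always-on intervention
(magnitude 1 at every time point) whose response vector is drawn once per
cohort, coordinatewise uniform on (-s/2, s/2) for effect size ``s``.

Seeding uses a spawning hierarchy: the cohort master seed deterministically
derives one substream per individual, so adding an individual never perturbs
the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .dynamics import simulate_timecourse
from .exceptions import ConfigurationError, GlvsimError
from .params import sample_initial_abundances
from .types import (
    InteractionMap,
    InterventionSpec,
    NodeSpec,
    SimulationConfig,
    Timecourse,
)

__all__ = ["CohortConfig", "CaseControlCohort", "generate_cohort", "generate_case_control"]


@dataclass
class CohortConfig:
    """Cohort-level settings.

    ``matched_seeds`` pairs case k with control k on identical initial
    abundances and noise/read streams, isolating the intervention effect;
    default is unmatched (fully independent individuals).
    """

    n_individuals: int
    p_zero: float = 0.0
    case_ratio: float = 0.5
    intervention_node: str | None = None
    effect_size: float = 1.0
    seed: int = 0
    matched_seeds: bool = False

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if not 0.0 <= self.p_zero <= 1.0:
            raise ConfigurationError("p_zero must be in [0, 1]")
        if not 0.0 <= self.case_ratio <= 1.0:
            raise ConfigurationError("case_ratio must be in [0, 1]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")


class CaseControlCohort(NamedTuple):
    cases: list[Timecourse]
    controls: list[Timecourse]
    response: np.ndarray


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _simulate_individual(
    index: int,
    label: str,
    indiv_ss: np.random.SeedSequence,
    nodes: list[NodeSpec],
    interactions: InteractionMap,
    interventions: list[InterventionSpec],
    sim_config: SimulationConfig,
    p_zero: float,
) -> Timecourse:
    # rebuild from entropy + spawn_key: SeedSequence.spawn is stateful, and a
    # matched case/control pair must derive identical substreams from one stream
    fresh = np.random.SeedSequence(entropy=indiv_ss.entropy, spawn_key=indiv_ss.spawn_key)
    init_ss, sim_ss = fresh.spawn(2)
    rng_init = np.random.default_rng(init_ss)
    resampled = [
        replace(n, initial_abundances=sample_initial_abundances(n.dim, p_zero, rng_init))
        for n in nodes
    ]
    cfg = replace(sim_config, seed=_seed_int(sim_ss))
    try:
        tc = simulate_timecourse(resampled, interactions, interventions, cfg)
    except GlvsimError as exc:
        exc.add_note(f"while simulating individual {index} ({label or 'cohort'})")
        raise
    tc.label = label
    return tc


def generate_cohort(
    nodes: list[NodeSpec],
    interactions: InteractionMap,
    interventions: list[InterventionSpec] | None,
    sim_config: SimulationConfig,
    cohort_config: CohortConfig,
) -> list[Timecourse]:
    """Simulate ``n_individuals`` timecourses with shared gLV parameters.

    Growth rates and the interaction map are identical across individuals;
    each individual's initial abundances are independently redrawn from the
    log-normal default (zeroed with probability ``p_zero``).
    """
    master = np.random.SeedSequence(cohort_config.seed)
    streams = master.spawn(cohort_config.n_individuals)
    return [
        _simulate_individual(
            k, "", ss, nodes, interactions, interventions or [], sim_config,
            cohort_config.p_zero,
        )
        for k, ss in enumerate(streams)
    ]


def _n_cases(n: int, ratio: float) -> int:
    # round half away from zero
    return int(np.floor(n * ratio + 0.5))


def generate_case_control(
    nodes: list[NodeSpec],
    interactions: InteractionMap,
    sim_config: SimulationConfig,
    cohort_config: CohortConfig,
) -> CaseControlCohort:
    """Simulate a case-control cohort under a random always-on intervention.

    ``round(n_individuals * case_ratio)`` cases receive an intervention with
    magnitude 1 at every time point and a single cohort-level response vector
    drawn coordinatewise from U(-s/2, s/2) on ``intervention_node``; the
    remaining individuals are untreated controls.  The response vector is
    returned for downstream power analysis.
    """
    node_dims = {n.name: n.dim for n in nodes}
    target = cohort_config.intervention_node
    if target is None or target not in node_dims:
        raise ConfigurationError(
            f"intervention_node {target!r} does not name a node "
            f"(available: {list(node_dims)})"
        )
    n = cohort_config.n_individuals
    n_cases = _n_cases(n, cohort_config.case_ratio)
    n_controls = n - n_cases

    master = np.random.SeedSequence(cohort_config.seed)
    response_ss, indiv_master = master.spawn(2)
    s = cohort_config.effect_size
    response = np.random.default_rng(response_ss).uniform(
        -s / 2.0, s / 2.0, size=node_dims[target]
    )
    intervention = InterventionSpec(
        node=target,
        magnitudes=np.ones(sim_config.n_timepoints),
        responses=response,
    )

    if cohort_config.matched_seeds:
        pair_streams = indiv_master.spawn(max(n_cases, n_controls))
        case_streams = pair_streams[:n_cases]
        control_streams = pair_streams[:n_controls]
    else:
        streams = indiv_master.spawn(n)
        case_streams = streams[:n_cases]
        control_streams = streams[n_cases:]

    cases = [
        _simulate_individual(
            k, "case", ss, nodes, interactions, [intervention], sim_config,
            cohort_config.p_zero,
        )
        for k, ss in enumerate(case_streams)
    ]
    controls = [
        _simulate_individual(
            k, "control", ss, nodes, interactions, [], sim_config,
            cohort_config.p_zero,
        )
        for k, ss in enumerate(control_streams)
    ]
    return CaseControlCohort(cases=cases, controls=controls, response=response)
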