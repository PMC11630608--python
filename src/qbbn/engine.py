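"""Iterative belief propagation over signed qualitative networks.

The model works on the probability that each node *increases*, P(Xi); the
probability of a decrease is always its complement (P(Xi) + P(Xd) = 1).
Integer inputs on the -4..4 scale map linearly onto [0.1, 0.9] — extreme
probabilities of 0 and 1 are never used because some uncertainty always
remains in complex systems.

Each iteration updates every node synchronously from the previous state:

1. For every *informative* parent Y (P(Yi) != 0.5) of child X, a conditional
   P(Xi|Y) = P(Xi|Yi)·P(Yi) + P(Xi|Yd)·P(Yd) is computed, with the
   complement rule P(Xi|Yd) = 1 - P(Xi|Yi).
2. Two candidate posteriors are formed: one that folds the evidence into the
   node's current prior, and one that is the plain mean of the conditionals
   (ignoring the prior).  The candidate furthest from 0.5 — the more
   *certain* one — wins.  This max-certainty selection is what stops signals
   fading away as they propagate through deep networks.
3. Nodes whose scenario priors are nonzero are *pinned*: they never drift
   back towards 0.5 below their initial certainty.  A directly manipulated
   node represents a known change, so the network cannot talk it out of it.

After the final iteration, probabilities convert back to a change score of
10 × (P(Xi) − 0.5), a real number in [-4, 4] comparable (ordinally) across
scenarios.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .network_io import InteractionNetwork, Scenario

P_MIN = 0.1
P_MAX = 0.9
NEUTRAL = 0.5
CHANGE_SCALE = 10.0
#: a parent counts as informative when its probability differs from 0.5 by more
INFORMATIVE_TOL = 1e-9
DEFAULT_ITERATIONS = 4
MAX_PLOTTED_SCENARIOS = 12


def clamp(p: float) -> float:
    """Clamp a probability to the model's working range [0.1, 0.9]."""
    return min(P_MAX, max(P_MIN, p))


def to_probability(value: int) -> float:
    """Map an integer change/strength in -4..4 to a probability of increase.

    The mapping is linear: -4 -> 0.1, 0 -> 0.5, 4 -> 0.9.
    """
    if not isinstance(value, int) or isinstance(value, bool):
        raise ValueError(f"expected an integer in -4..4, got {value!r}")
    if not -4 <= value <= 4:
        raise ValueError(f"value {value} outside -4..4")
    return (5 + value) / 10


def from_probability(p: float) -> float:
    """Convert a probability of increase back to the -4..4 change scale."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return CHANGE_SCALE * (p - NEUTRAL)


def conditional_given_parent(edge_p: float, parent_p: float) -> float:
    """P(child increases | one parent), marginalised over the parent's state.

    ``edge_p`` is P(Xi|Yi); the complement rule supplies P(Xi|Yd) = 1 - edge_p.
    """
    return edge_p * parent_p + (1.0 - edge_p) * (1.0 - parent_p)


def posterior_with_prior(prior_p: float, conditionals: Sequence[float]) -> float:
    """Prior-bearing posterior: evidence adds to the certainty of the prior."""
    n = len(conditionals)
    if n == 0:
        raise ValueError("posterior_with_prior requires at least one conditional")
    total = sum(prior_p * (c - NEUTRAL) for c in conditionals)
    return clamp(prior_p + (1.0 - prior_p) * total / n)


def posterior_from_interactions(conditionals: Sequence[float]) -> float:
    """Interactions-only posterior: the mean conditional, prior ignored."""
    if not conditionals:
        raise ValueError("posterior_from_interactions requires at least one conditional")
    return clamp(sum(conditionals) / len(conditionals))


#: certainties closer than this count as tied (floating point makes exact
#: ties like |0.7-0.5| vs |0.3-0.5| unreliable)
CERTAINTY_TIE_TOL = 1e-12


def select_most_certain(a: float, b: float) -> float:
    """Return whichever probability lies furthest from 0.5 (ties favour ``a``)."""
    return a if abs(a - NEUTRAL) >= abs(b - NEUTRAL) - CERTAINTY_TIE_TOL else b


@dataclass(frozen=True)
class ProbabilityState:
    """The engine's evolving state: P(increase) per node, plus pinning data.

    ``pinned`` holds the nodes with nonzero scenario priors; ``pin_values``
    their initial probabilities, the certainty floor they may never drop
    below.
    """

    p_inc: Mapping[str, float]
    pinned: frozenset[str]
    pin_values: Mapping[str, float]


@dataclass(frozen=True)
class PredictionResult:
    """Final change per node on the -4..4 scale, optionally with CI bounds."""

    scenario_name: str
    change: Mapping[str, float]
    ci_low: Mapping[str, float] | None = None
    ci_high: Mapping[str, float] | None = None


def edge_probabilities(network: InteractionNetwork) -> dict[tuple[str, str], float]:
    """Convert a network's integer strengths to edge probabilities."""
    return {edge: to_probability(s) for edge, s in network.edges.items()}


def build_parent_map(
    nodes: Sequence[str], edge_probs: Mapping[tuple[str, str], float]
) -> dict[str, list[tuple[str, float]]]:
    """Group probability-scale edges by child for fast lookup during updates."""
    parents: dict[str, list[tuple[str, float]]] = {n: [] for n in nodes}
    for (parent, child), p in edge_probs.items():
        parents[child].append((parent, p))
    return parents


def initial_state(network: InteractionNetwork, scenario: Scenario) -> ProbabilityState:
    """Build the starting state for a scenario: priors mapped to probabilities."""
    scenario.validate_for(network)
    p_inc = {node: to_probability(scenario.priors.get(node, 0)) for node in network.nodes}
    pinned = frozenset(scenario.priors)
    pin_values = {node: p_inc[node] for node in pinned}
    return ProbabilityState(p_inc, pinned, pin_values)


def _step(
    state: ProbabilityState, parents: Mapping[str, Sequence[tuple[str, float]]]
) -> ProbabilityState:
    """One synchronous update: every node reads the previous state's values."""
    p = state.p_inc
    new_p: dict[str, float] = {}
    for node, current in p.items():
        conditionals = [
            conditional_given_parent(edge_p, p[parent])
            for parent, edge_p in parents.get(node, ())
            if abs(p[parent] - NEUTRAL) > INFORMATIVE_TOL
        ]
        if not conditionals:
            posterior = current
        else:
            posterior = select_most_certain(
                posterior_with_prior(current, conditionals),
                posterior_from_interactions(conditionals),
            )
        if node in state.pinned:
            pin = state.pin_values[node]
            if abs(posterior - NEUTRAL) < abs(pin - NEUTRAL):
                posterior = pin  # a known change never loses certainty
        new_p[node] = posterior
    return ProbabilityState(new_p, state.pinned, state.pin_values)


def step(state: ProbabilityState, network: InteractionNetwork) -> ProbabilityState:
    """Advance the state one iteration over the given network."""
    return _step(state, build_parent_map(network.nodes, edge_probabilities(network)))


def run_state(
    state: ProbabilityState,
    parents: Mapping[str, Sequence[tuple[str, float]]],
    iterations: int,
) -> ProbabilityState:
    """Apply ``iterations`` synchronous updates to an explicit starting state."""
    for _ in range(iterations):
        state = _step(state, parents)
    return state


def predict(
    network: InteractionNetwork,
    scenarios: Sequence[Scenario],
    iterations: int = DEFAULT_ITERATIONS,
) -> list[PredictionResult]:
    """Predict each node's change under one or more scenarios.

    Every scenario starts from its own priors (unlisted nodes neutral),
    propagates for ``iterations`` synchronous updates (default 4 — a signal
    travels one edge per iteration), and reports 10 × (posterior − 0.5).
    """
    if not scenarios:
        raise ValueError("predict requires at least one scenario")
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    if len(scenarios) > MAX_PLOTTED_SCENARIOS:
        warnings.warn(
            f"{len(scenarios)} scenarios given; results beyond "
            f"{MAX_PLOTTED_SCENARIOS} cannot be combined on one plot",
            stacklevel=2,
        )
    parents = build_parent_map(network.nodes, edge_probabilities(network))
    results = []
    for scenario in scenarios:
        state = run_state(initial_state(network, scenario), parents, iterations)
        change = {node: from_probability(state.p_inc[node]) for node in network.nodes}
        results.append(PredictionResult(scenario.name, change))
    return results
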