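"""Stepwise dynamics for visualising the order in which changes propagate.

This mode deliberately drops the signal-loss machinery (the prior-bearing
posterior and the max-certainty selection): each timestep every node simply
takes the mean of its per-parent conditionals.  Values therefore attenuate
along long paths and do NOT match the headline prediction function — which
is the point: the output shows *when* each node first responds (a change at
timestep 2 happens before one at timestep 3), in the manner of a trophic
cascade, not how big the final response is.

Two disturbance modes are supported.  A **press** re-imposes the scenario at
every step: each manipulated node is restored to its prior whenever the
computed value is less certain.  A **pulse** applies the scenario at the
first timestep only; afterwards nodes with no informative parents relax to
neutral, so the disturbance travels through the network as a peak.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import engine
from .network_io import InteractionNetwork, Scenario

DEFAULT_TIMESTEPS = 5
PRESS = "press"
PULSE = "pulse"


@dataclass(frozen=True)
class TimeseriesResult:
    """Node × timestep matrix of change values on the -4..4 scale.

    ``values`` is indexed by node with integer columns 1..timesteps; column 1
    is the scenario itself (the initial state).
    """

    values: pd.DataFrame
    disturbance: str

    @property
    def timesteps(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="node")


def timeseries(
    network: InteractionNetwork,
    scenario: Scenario,
    timesteps: int = DEFAULT_TIMESTEPS,
    disturbance: str = PRESS,
) -> TimeseriesResult:
    """Propagate one scenario stepwise, recording every intermediate state.

    Exactly one scenario is supported.  Timesteps are ordinal, not real time
    units: the first column is the initial state and each further column is
    one synchronous mean-of-conditionals update.
    """
    if timesteps < 1:
        raise ValueError("timesteps must be >= 1")
    if disturbance not in (PRESS, PULSE):
        raise ValueError(f"disturbance must be {PRESS!r} or {PULSE!r}, got {disturbance!r}")
    scenario.validate_for(network)

    parents = engine.build_parent_map(network.nodes, engine.edge_probabilities(network))
    prior_p = {node: engine.to_probability(scenario.priors.get(node, 0)) for node in network.nodes}
    manipulated = set(scenario.priors)

    p = dict(prior_p)
    columns = {1: {n: engine.from_probability(p[n]) for n in network.nodes}}
    for t in range(2, timesteps + 1):
        new_p: dict[str, float] = {}
        for node in network.nodes:
            conditionals = [
                engine.conditional_given_parent(edge_p, p[parent])
                for parent, edge_p in parents[node]
                if abs(p[parent] - engine.NEUTRAL) > engine.INFORMATIVE_TOL
            ]
            if conditionals:
                new_p[node] = engine.posterior_from_interactions(conditionals)
            elif disturbance == PRESS:
                new_p[node] = p[node]
            else:
                # pulse: with nothing driving it, a node relaxes to neutral,
                # letting the disturbance pass through as a travelling peak
                new_p[node] = engine.NEUTRAL
        if disturbance == PRESS:
            for node in manipulated:
                new_p[node] = engine.select_most_certain(prior_p[node], new_p[node])
        p = new_p
        columns[t] = {n: engine.from_probability(p[n]) for n in network.nodes}

    frame = pd.DataFrame(columns, index=list(network.nodes))
    frame.index.name = "node"
    return TimeseriesResult(frame, disturbance)
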