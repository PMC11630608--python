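"""Synthetic networks, scenarios and hand-built toy models.

Random networks follow an Erdős–Rényi-style scheme over ordered node pairs
(no self-edges), with integer strengths drawn uniformly from a chosen set —
enough structure to exercise every part of the pipeline without claiming
ecological realism.  The toys are small hand-built models whose expected
outputs were traced by hand from the update rules, used throughout the test
suite; ``web8`` is an explicitly synthetic food-web-style stand-in with the
structural motifs typical of coastal management models (top-down trophic
edges, reciprocal grazer competition, a policy input node and a revenue
output node) — it reproduces no published parameter values.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import network_io
from .network_io import DiagramNetwork, InteractionNetwork, Scenario

FULL_STRENGTH_SET = (-4, -3, -2, -1, 1, 2, 3, 4)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random network/scenario generator."""

    n_nodes: int
    density: float = 0.3
    strength_set: tuple[int, ...] = FULL_STRENGTH_SET
    n_manipulated: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if not self.strength_set or any(
            s == 0 or not -4 <= s <= 4 for s in self.strength_set
        ):
            raise ValueError("strength_set must be a nonempty subset of {-4..-1, 1..4}")
        if not 1 <= self.n_manipulated <= self.n_nodes:
            raise ValueError("n_manipulated must be in 1..n_nodes")


def _node_labels(n: int) -> tuple[str, ...]:
    if n <= 26:
        return tuple(string.ascii_uppercase[:n])
    return tuple(f"N{i:03d}" for i in range(n))


def random_network(spec: GeneratorSpec) -> InteractionNetwork:
    """Draw a random signed network: each ordered non-self pair carries an
    edge with probability ``density``, strength uniform over ``strength_set``.

    Deterministic given the seed.  If the density draw happens to produce no
    edges at all, one uniformly chosen edge is inserted so the network is
    never degenerate.
    """
    rng = np.random.default_rng([spec.seed, 0])
    nodes = _node_labels(spec.n_nodes)
    strengths = list(spec.strength_set)
    edges: dict[tuple[str, str], int] = {}
    pairs = [(p, c) for p in nodes for c in nodes if p != c]
    draws = rng.random(len(pairs))
    picks = rng.integers(0, len(strengths), size=len(pairs))
    for (pair, draw, pick) in zip(pairs, draws, picks):
        if draw < spec.density:
            edges[pair] = strengths[int(pick)]
    if not edges:
        pair = pairs[int(rng.integers(0, len(pairs)))]
        edges[pair] = strengths[int(rng.integers(0, len(strengths)))]
    return InteractionNetwork(nodes, edges)


def random_scenario(network: InteractionNetwork, spec: GeneratorSpec) -> Scenario:
    """Draw a scenario with ``n_manipulated`` distinct nonzero priors."""
    rng = np.random.default_rng([spec.seed, 1])
    chosen = rng.choice(len(network.nodes), size=spec.n_manipulated, replace=False)
    strengths = list(spec.strength_set)
    priors = {
        network.nodes[int(i)]: strengths[int(rng.integers(0, len(strengths)))]
        for i in chosen
    }
    return Scenario(priors, name=f"random_seed{spec.seed}")


@dataclass(frozen=True)
class ToyCollection:
    """The canonical hand-built toy models used across the test suite."""

    networks: Mapping[str, InteractionNetwork]
    scenarios: Mapping[str, Scenario]
    diagrams: Mapping[str, DiagramNetwork]
    #: hand-traced expected outputs of the default 4-iteration prediction
    expected_changes: Mapping[str, Mapping[str, float]]


def toy_fixtures() -> ToyCollection:
    """Build the bundled toys: chain2, chain6, recip2 and the web8 stand-in."""
    chain2 = InteractionNetwork(("A", "B"), {("A", "B"): 4})
    chain6_nodes = ("A", "B", "C", "D", "E", "F")
    chain6 = InteractionNetwork(
        chain6_nodes,
        {(chain6_nodes[i], chain6_nodes[i + 1]): 4 for i in range(5)},
    )
    recip2 = InteractionNetwork(("A", "B"), {("A", "B"): -4, ("B", "A"): -4})

    web8_nodes = (
        "Protection Policy",
        "Fishing",
        "Predator",
        "Grazer",
        "Competitor Grazer",
        "Algae",
        "Filter Feeder",
        "Revenue",
    )
    web8 = InteractionNetwork(
        web8_nodes,
        {
            ("Protection Policy", "Fishing"): -4,
            ("Fishing", "Predator"): -3,
            ("Predator", "Grazer"): -3,
            ("Predator", "Competitor Grazer"): -2,
            ("Grazer", "Algae"): -4,
            ("Competitor Grazer", "Algae"): -2,
            ("Grazer", "Competitor Grazer"): -2,
            ("Competitor Grazer", "Grazer"): -2,
            ("Algae", "Filter Feeder"): -1,
            ("Predator", "Revenue"): 2,
            ("Algae", "Revenue"): 1,
            ("Fishing", "Revenue"): 3,
        },
    )
    web8_diagram = DiagramNetwork(
        web8,
        tuple(f"s{i + 1:02d}" for i in range(8)),
        {
            "Protection Policy": 4,
            "Fishing": 4,
            "Predator": 2,
            "Grazer": 3,
            "Competitor Grazer": 3,
            "Algae": 1,
            "Filter Feeder": 2,
            "Revenue": 4,
        },
    )

    scenarios = {
        "chain2_raise_A": Scenario({"A": 4}, name="chain2_raise_A"),
        "chain6_raise_A": Scenario({"A": 4}, name="chain6_raise_A"),
        "recip2_raise_A": Scenario({"A": 4}, name="recip2_raise_A"),
        "web8_protect": Scenario({"Protection Policy": 4}, name="web8_protect"),
    }

    # hand-traced: B follows 0.5 -> 0.82 -> 0.867232 -> clamp 0.9 -> 0.9
    expected = {
        "chain2_raise_A": {"A": 4.0, "B": 4.0},
    }

    return ToyCollection(
        networks={"chain2": chain2, "chain6": chain6, "recip2": recip2, "web8": web8},
        scenarios=scenarios,
        diagrams={"web8": web8_diagram},
        expected_changes=expected,
    )


def export_fixtures(out_dir) -> list[Path]:
    """Write every toy as CSV files in the three dialects; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    toys = toy_fixtures()
    written: list[Path] = []
    for name, network in toys.networks.items():
        path = out_dir / f"{name}_network.csv"
        network_io.write_network(network, path)
        written.append(path)
    for name, scenario in toys.scenarios.items():
        network_name = name.split("_")[0]
        network = toys.networks[network_name]
        path = out_dir / f"{name}.csv"
        network_io.write_scenario(scenario, network, path)
        written.append(path)
    for name, diagram in toys.diagrams.items():
        path = out_dir / f"{name}_diagram.csv"
        network_io.write_diagram_network(diagram, path)
        written.append(path)
    return written
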