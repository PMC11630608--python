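"""Edge-sensitivity ranking by bootstrap frequency.

Which interaction strengths most deserve scrutiny?  Each replicate jitters a
random 10% of edges and 10% of node priors (both by up to ±0.1 on the
probability scale), re-runs the prediction, and measures the total absolute
deviation of the chosen outcome nodes from the unperturbed baseline.  An
edge scores a point each time it was jittered in a replicate that landed in
the top 25% of those deviations.  High-frequency edges are the ones whose
exact values most influence the outcomes of interest — the place to spend
further data collection or expert elicitation effort.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import engine
from .bootstrap import BootstrapSettings, perturb_network
from .network_io import InteractionNetwork, Scenario, _unknown_label_message

DEFAULT_BOOT_MAX = 1000
TOP_FRACTION = 0.25
RECOMMENDED_MAX_NODES = 3


@dataclass(frozen=True)
class SensitivityResult:
    """Per-edge importance counts from the bootstrap ranking.

    ``frequency`` maps (parent, child) to the number of top-quartile
    replicates in which that edge was perturbed, sorted descending; only
    edges that were perturbed at least once in a top replicate appear.
    """

    frequency: Mapping[tuple[str, str], int]
    nodes_of_interest: tuple[str, ...]
    replicates: int


def _perturb_priors(
    base: Mapping[str, float],
    nodes: Sequence[str],
    settings: BootstrapSettings,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Jitter ceil(edge_fraction · n) node priors, mirroring the edge rule."""
    n_perturb = math.ceil(settings.edge_fraction * len(nodes))
    chosen_idx = rng.choice(len(nodes), size=n_perturb, replace=False)
    deltas = rng.uniform(-settings.max_delta, settings.max_delta, size=n_perturb)
    perturbed = dict(base)
    for idx, delta in zip(chosen_idx, deltas):
        node = nodes[int(idx)]
        perturbed[node] = engine.clamp(perturbed[node] + float(delta))
    return perturbed


def sensitivity(
    network: InteractionNetwork,
    nodes_of_interest: Sequence[str],
    scenario: Scenario | None = None,
    settings: BootstrapSettings | None = None,
    iterations: int = engine.DEFAULT_ITERATIONS,
) -> SensitivityResult:
    """Rank edges by how often perturbing them drives the outcome nodes.

    ``nodes_of_interest`` must be spelled exactly as in the network (spaces
    included); misspellings raise with a nearest-label suggestion.  The
    optional ``scenario`` drives the system during the analysis; by default
    the network starts neutral and only the perturbations inject change.
    """
    if not nodes_of_interest:
        raise ValueError("sensitivity requires at least one node of interest")
    if len(nodes_of_interest) > RECOMMENDED_MAX_NODES:
        warnings.warn(
            f"{len(nodes_of_interest)} nodes of interest given; no more than "
            f"{RECOMMENDED_MAX_NODES} are recommended",
            stacklevel=2,
        )
    nodes_of_interest = tuple(str(n).strip() for n in nodes_of_interest)
    for label in nodes_of_interest:
        if label not in network.nodes:
            raise ValueError(_unknown_label_message(label, network.nodes))
    if scenario is None:
        scenario = Scenario({}, name="neutral")
    if settings is None:
        settings = BootstrapSettings(boot_max=DEFAULT_BOOT_MAX)

    baseline = engine.predict(network, [scenario], iterations=iterations)[0]
    edge_probs = engine.edge_probabilities(network)
    start = engine.initial_state(network, scenario)
    rng = np.random.default_rng(settings.seed)

    impacts: list[float] = []
    modified_sets: list[list[tuple[str, str]]] = []
    for _ in range(settings.boot_max):
        perturbed_edges, modified = perturb_network(edge_probs, settings, rng)
        p_inc = _perturb_priors(start.p_inc, network.nodes, settings, rng)
        # perturbed priors are noise, not known changes: they are not pinned;
        # scenario pins keep their (possibly jittered) starting values
        pin_values = {node: p_inc[node] for node in start.pinned}
        state = engine.ProbabilityState(p_inc, start.pinned, pin_values)
        parents = engine.build_parent_map(network.nodes, perturbed_edges)
        state = engine.run_state(state, parents, iterations)
        impact = sum(
            abs(engine.from_probability(state.p_inc[node]) - baseline.change[node])
            for node in nodes_of_interest
        )
        impacts.append(impact)
        modified_sets.append(modified)

    n_top = math.ceil(TOP_FRACTION * settings.boot_max)
    cutoff = sorted(impacts, reverse=True)[n_top - 1]
    counts: dict[tuple[str, str], int] = {}
    for impact, modified in zip(impacts, modified_sets):
        if impact >= cutoff:  # ties at the cutoff all count
            for edge in modified:
                counts[edge] = counts.get(edge, 0) + 1
    ordered = dict(sorted(counts.items(), key=lambda item: (-item[1], item[0])))
    return SensitivityResult(ordered, nodes_of_interest, settings.boot_max)
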