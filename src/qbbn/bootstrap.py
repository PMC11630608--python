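"""Bootstrap uncertainty for predictions via random edge perturbation.

Edge strengths are rarely known exactly, so confidence intervals are built
by re-running the prediction on jittered copies of the network: each
replicate perturbs 10% of the edges (rounded up) by a uniform amount of up
to ±0.1 *on the probability scale*, and the spread of the replicate
predictions per node gives an empirical interval.  The reported point
estimate is always the unperturbed run, never a bootstrap mean.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import engine
from .network_io import InteractionNetwork, Scenario


@dataclass(frozen=True)
class BootstrapSettings:
    """Knobs of the edge-perturbation bootstrap.

    boot_max: number of replicates; 1 means no bootstrapping (point only).
    edge_fraction: fraction of edges perturbed per replicate (default 10%).
    max_delta: half-width of the uniform jitter on the probability scale.
    tail: fraction trimmed from each tail of the replicate distribution
        (default 0.025, i.e. a 95% interval).
    seed: seed for the replicate random stream.
    """

    boot_max: int = 1
    edge_fraction: float = 0.10
    max_delta: float = 0.10
    tail: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boot_max < 1:
            raise ValueError("boot_max must be >= 1")
        if not 0.0 < self.edge_fraction <= 1.0:
            raise ValueError("edge_fraction must be in (0, 1]")
        if not 0.0 <= self.max_delta < 0.4:
            raise ValueError("max_delta must be in [0, 0.4)")
        if not 0.0 <= self.tail < 0.5:
            raise ValueError("tail must be in [0, 0.5)")


def perturb_network(
    edge_probs: Mapping[tuple[str, str], float],
    settings: BootstrapSettings,
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], float], list[tuple[str, str]]]:
    """Jitter a random subset of edges; returns the new map and who moved.

    ceil(edge_fraction · E) distinct edges are drawn uniformly without
    replacement; each gets Uniform(−max_delta, +max_delta) added on the
    probability scale, clamped to [0.1, 0.9].  The caller owns the RNG so
    replicate streams stay reproducible.
    """
    if not edge_probs:
        raise ValueError("cannot perturb an empty network")
    edges = list(edge_probs)
    n_perturb = math.ceil(settings.edge_fraction * len(edges))
    chosen_idx = rng.choice(len(edges), size=n_perturb, replace=False)
    deltas = rng.uniform(-settings.max_delta, settings.max_delta, size=n_perturb)
    perturbed = dict(edge_probs)
    modified: list[tuple[str, str]] = []
    for idx, delta in zip(chosen_idx, deltas):
        edge = edges[int(idx)]
        perturbed[edge] = engine.clamp(perturbed[edge] + float(delta))
        modified.append(edge)
    return perturbed, modified


def trimmed_interval(values: Sequence[float], tail: float) -> tuple[float, float]:
    """Nearest-rank interval: drop floor(tail·B) values from each tail.

    The bounds are the extreme *surviving* replicates, e.g. with B = 1000
    and tail = 0.025 the 26th and 975th order statistics.
    """
    ordered = np.sort(np.asarray(values, dtype=float))
    size = ordered.size
    if size == 0:
        raise ValueError("trimmed_interval needs at least one value")
    k = min(int(math.floor(tail * size)), (size - 1) // 2)
    return float(ordered[k]), float(ordered[size - 1 - k])


def bootstrap_predict(
    network: InteractionNetwork,
    scenario: Scenario,
    settings: BootstrapSettings = BootstrapSettings(),
    iterations: int = engine.DEFAULT_ITERATIONS,
) -> engine.PredictionResult:
    """Predict with bootstrap confidence intervals for one scenario.

    Replicate 0 runs the unperturbed network and supplies the point
    estimates.  Replicates 1..boot_max each perturb the edge probabilities
    and re-run; per node the interval is the trimmed nearest-rank spread of
    the replicate changes.  With boot_max = 1 no replicates are run and no
    intervals are attached.
    """
    point = engine.predict(network, [scenario], iterations=iterations)[0]
    if settings.boot_max <= 1:
        return point

    rng = np.random.default_rng(settings.seed)
    edge_probs = engine.edge_probabilities(network)
    start = engine.initial_state(network, scenario)
    replicate_changes: dict[str, list[float]] = {node: [] for node in network.nodes}
    for _ in range(settings.boot_max):
        perturbed, _modified = perturb_network(edge_probs, settings, rng)
        parents = engine.build_parent_map(network.nodes, perturbed)
        state = engine.run_state(start, parents, iterations)
        for node in network.nodes:
            replicate_changes[node].append(engine.from_probability(state.p_inc[node]))

    ci_low: dict[str, float] = {}
    ci_high: dict[str, float] = {}
    for node in network.nodes:
        low, high = trimmed_interval(replicate_changes[node], settings.tail)
        ci_low[node] = low
        ci_high[node] = high
    return engine.PredictionResult(point.scenario_name, point.change, ci_low, ci_high)
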