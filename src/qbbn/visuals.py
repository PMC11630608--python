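"""Network diagrams and prediction plots.

Three renderers:

* :func:`network_diagram` — the whole network: node fill by functional
  class (four colour-blind-safe colours), red arrows for negative and black
  for positive influences, arrow width proportional to |strength|.
* :func:`visualise_flow` — one frame per timestep of a stepwise run: nodes
  shaded by the *ordinal rank* of their change (biggest increase black,
  smallest white), and outgoing edges drawn only for nodes whose |change|
  exceeds a threshold, so the information front is visible.
* :func:`plot_predictions` — per-scenario panels of change per node with
  bootstrap error bars, panels filled column-first (scenario 2 sits below
  scenario 1).

Vector output is deterministic: identical inputs and options produce
byte-identical SVG files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.rcParams["svg.hashsalt"] = "qbbn"

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .network_io import DiagramNetwork, InteractionNetwork
from .engine import PredictionResult
from .timeseries import TimeseriesResult

LAYOUTS = ("grid", "sphere", "circle", "random", "fruchterman_reingold")

#: Okabe-Ito colour-blind-safe fills for the four node.type classes
NODE_TYPE_COLOURS = {1: "#FFFFFF", 2: "#999999", 3: "#E69F00", 4: "#F0E442"}

NEGATIVE_EDGE_COLOUR = "red"
POSITIVE_EDGE_COLOUR = "black"
MAX_PANELS = 12


@dataclass(frozen=True)
class RenderOptions:
    """Shared rendering knobs (defaults follow the tool's conventions)."""

    font_scale: float = 0.7
    arrow_scale: float = 4.0
    threshold: float = 0.2
    layout: str = "sphere"
    seed: int = 0
    overwrite: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 4.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 4]")
        if self.font_scale <= 0 or self.arrow_scale <= 0:
            raise ValueError("font_scale and arrow_scale must be positive")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")


def edge_width(strength: int, arrow_scale: float) -> float:
    """Line width for an edge: proportional to |strength| times the scale."""
    return abs(strength) / 4.0 * arrow_scale


def ordinal_shades(values: Mapping[str, float]) -> dict[str, float]:
    """Rank-based grey level per node: 0.0 = black (max), 1.0 = white (min).

    Shading is ordinal, never value-scaled: ranks are spaced linearly and
    tied values share a shade.  A constant map renders mid-grey.
    """
    distinct = sorted(set(values.values()))
    if len(distinct) == 1:
        return {node: 0.5 for node in values}
    rank = {v: i for i, v in enumerate(distinct)}
    top = len(distinct) - 1
    return {node: 1.0 - rank[v] / top for node, v in values.items()}


def flow_edges(
    network: InteractionNetwork, ts: TimeseriesResult, timestep: int, threshold: float
) -> list[tuple[str, str, int]]:
    """Edges drawn at a timestep: outgoing edges of nodes with |change| > threshold."""
    column = ts.values[timestep]
    return [
        (parent, child, strength)
        for (parent, child), strength in network.edges.items()
        if abs(column[parent]) > threshold
    ]


def layout_positions(
    network: InteractionNetwork, layout: str, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Node coordinates for a layout; ``grid`` preserves input node order."""
    nodes = network.nodes
    n = len(nodes)
    if layout == "grid":
        ncol = math.ceil(math.sqrt(n))
        return {node: (i % ncol, -(i // ncol)) for i, node in enumerate(nodes)}
    if layout == "circle":
        return {
            node: (math.cos(2 * math.pi * i / n), math.sin(2 * math.pi * i / n))
            for i, node in enumerate(nodes)
        }
    if layout == "sphere":
        # Fibonacci sphere projected to the plane: even spread, deterministic
        golden = math.pi * (3.0 - math.sqrt(5.0))
        pos = {}
        for i, node in enumerate(nodes):
            z = 1.0 - 2.0 * (i + 0.5) / n
            radius = math.sqrt(max(0.0, 1.0 - z * z))
            pos[node] = (radius * math.cos(golden * i), z)
        return pos
    if layout == "random":
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-1.0, 1.0, size=(n, 2))
        return {node: (float(x), float(y)) for node, (x, y) in zip(nodes, coords)}
    if layout == "fruchterman_reingold":
        graph = nx.DiGraph()
        graph.add_nodes_from(nodes)
        graph.add_edges_from(network.edges)
        return {k: (float(x), float(y)) for k, (x, y) in nx.spring_layout(graph, seed=seed).items()}
    raise ValueError(f"unknown layout {layout!r}")


def _save(fig, path, overwrite: bool) -> Path:
    path = Path(path)
    if not overwrite and path.exists():
        plt.close(fig)
        raise FileExistsError(f"{path} exists and overwriting is disabled")
    if path.suffix.lower() == ".svg":
        fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)
    return path


def _draw_network(
    ax,
    network: InteractionNetwork,
    positions: Mapping[str, tuple[float, float]],
    node_colours: Mapping[str, str] | Mapping[str, float],
    edges: Sequence[tuple[str, str, int]],
    opts: RenderOptions,
) -> None:
    graph = nx.DiGraph()
    graph.add_nodes_from(network.nodes)
    for parent, child, strength in edges:
        graph.add_edge(parent, child, strength=strength)
    colours = [
        str(node_colours[n]) if not isinstance(node_colours[n], str) else node_colours[n]
        for n in network.nodes
    ]
    nx.draw_networkx_nodes(
        graph, positions, ax=ax, node_color=colours, edgecolors="black", node_size=600
    )
    for parent, child, strength in edges:
        nx.draw_networkx_edges(
            graph,
            positions,
            edgelist=[(parent, child)],
            ax=ax,
            width=edge_width(strength, opts.arrow_scale),
            edge_color=NEGATIVE_EDGE_COLOUR if strength < 0 else POSITIVE_EDGE_COLOUR,
            connectionstyle="arc3,rad=0.12",
            arrows=True,
            arrowsize=8 + 2 * opts.arrow_scale,
            node_size=600,
        )
    nx.draw_networkx_labels(graph, positions, ax=ax, font_size=10 * opts.font_scale)
    ax.set_axis_off()


def network_diagram(
    diagram: DiagramNetwork, path, opts: RenderOptions = RenderOptions()
) -> Path:
    """Render the full network: all nodes and edges, fills by node.type class."""
    network = diagram.network
    positions = layout_positions(network, opts.layout, opts.seed)
    node_colours = {n: NODE_TYPE_COLOURS[diagram.node_types[n]] for n in network.nodes}
    edges = [(p, c, s) for (p, c), s in network.edges.items()]
    fig, ax = plt.subplots(figsize=(7, 7))
    _draw_network(ax, network, positions, node_colours, edges, opts)
    return _save(fig, path, opts.overwrite)


def visualise_flow(
    network: InteractionNetwork,
    ts: TimeseriesResult,
    out_dir,
    opts: RenderOptions = RenderOptions(layout="grid"),
    prefix: str = "flow",
    fmt: str = "svg",
) -> list[Path]:
    """Render one frame per timestep, shading nodes by ordinal rank of change.

    Only nodes whose |change| exceeds ``opts.threshold`` show their outgoing
    edges, so each frame displays where information has reached.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    positions = layout_positions(network, opts.layout, opts.seed)
    paths = []
    for t in ts.values.columns:
        shades = ordinal_shades(dict(ts.values[t]))
        edges = flow_edges(network, ts, t, opts.threshold)
        fig, ax = plt.subplots(figsize=(7, 7))
        _draw_network(ax, network, positions, shades, edges, opts)
        ax.set_title(f"timestep {t}", fontsize=12 * opts.font_scale)
        paths.append(_save(fig, out_dir / f"{prefix}_t{t}.{fmt}", opts.overwrite))
    return paths


def plot_predictions(
    results: Sequence[PredictionResult], path, opts: RenderOptions = RenderOptions()
) -> Path:
    """One panel per scenario: horizontal point chart of change per node.

    Panels fill column-major (scenario 2 below scenario 1); error bars appear
    when bootstrap intervals are present.  At most 12 scenarios fit one plot.
    """
    if not results:
        raise ValueError("plot_predictions needs at least one result")
    if len(results) > MAX_PANELS:
        raise ValueError(f"at most {MAX_PANELS} scenarios fit on one plot")
    n = len(results)
    nrows = min(n, 4)
    ncols = math.ceil(n / nrows)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.5 * ncols, 2.2 * nrows), squeeze=False, sharex=True
    )
    for i, result in enumerate(results):
        ax = axes[i % nrows][i // nrows]
        nodes = list(result.change)
        values = [result.change[n_] for n_ in nodes]
        y = np.arange(len(nodes))
        if result.ci_low is not None and result.ci_high is not None:
            xerr = np.array(
                [
                    [result.change[n_] - result.ci_low[n_] for n_ in nodes],
                    [result.ci_high[n_] - result.change[n_] for n_ in nodes],
                ]
            )
            xerr = np.clip(xerr, 0.0, None)  # point may sit outside a one-sided spread
            ax.errorbar(values, y, xerr=xerr, fmt="o", color="black", ecolor="grey")
        else:
            ax.plot(values, y, "o", color="black")
        ax.axvline(0.0, color="lightgrey", linewidth=0.8, zorder=0)
        ax.set_yticks(y, nodes, fontsize=9 * opts.font_scale / 0.7)
        ax.set_xlim(-4.5, 4.5)
        ax.set_title(result.scenario_name, fontsize=10 * opts.font_scale / 0.7)
        ax.invert_yaxis()
    for j in range(n, nrows * ncols):
        axes[j % nrows][j // nrows].set_axis_off()
    fig.tight_layout()
    return _save(fig, path, opts.overwrite)


def plot_sensitivity(frequency: Mapping[tuple[str, str], int], path, opts: RenderOptions = RenderOptions()) -> Path:
    """Horizontal bar chart of edge importance counts, most frequent on top."""
    labels = [f"{p} → {c}" for p, c in frequency]
    counts = list(frequency.values())
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(1, len(labels)) + 1.5))
    y = np.arange(len(labels))
    ax.barh(y, counts, color="#56B4E9", edgecolor="black")
    ax.set_yticks(y, labels, fontsize=9 * opts.font_scale / 0.7)
    ax.invert_yaxis()
    ax.set_xlabel("frequency in top-quartile replicates")
    fig.tight_layout()
    return _save(fig, path, opts.overwrite)


def plot_timeseries(
    ts: TimeseriesResult, path, opts: RenderOptions = RenderOptions()
) -> Path:
    """One panel per node: per-timestep points with a smoothed trend line.

    The trend is a low-order polynomial fit; if fitting fails (too few
    points, degenerate values) the panel degrades to plain points.
    """
    nodes = list(ts.values.index)
    n = len(nodes)
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.0 * ncols, 2.2 * nrows), squeeze=False, sharex=True
    )
    t = np.asarray(ts.values.columns, dtype=float)
    for i, node in enumerate(nodes):
        ax = axes[i // ncols][i % ncols]
        y = ts.values.loc[node].to_numpy(dtype=float)
        ax.plot(t, y, "o", color="black", markersize=4)
        if len(t) >= 3:
            try:
                degree = min(3, len(t) - 1)
                coeffs = np.polyfit(t, y, degree)
                dense = np.linspace(t[0], t[-1], 50)
                ax.plot(dense, np.polyval(coeffs, dense), color="#0072B2")
            except Exception:
                pass  # smoothing is cosmetic; the points still show the shape
        ax.set_ylim(-4.5, 4.5)
        ax.axhline(0.0, color="lightgrey", linewidth=0.8, zorder=0)
        ax.set_title(node, fontsize=10 * opts.font_scale / 0.7)
    for j in range(n, nrows * ncols):
        axes[j // ncols][j % ncols].set_axis_off()
    fig.supxlabel("timestep")
    fig.tight_layout()
    return _save(fig, path, opts.overwrite)
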