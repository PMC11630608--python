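"""Readers and writers for the CSV dialects of qualitative interaction models.

Three dialects are supported:

* **interaction matrix** — an (n+1) x n table: header row gives the node
  names, each data row starts with a node label followed by the signed
  integer edge strengths (-4..-1, 1..4) from that row's node (parent) to
  each column's node (child).  Blank cells mean "no edge".
* **scenario** — two columns, node label and integer prior change in -4..4,
  where 0 means "no known change".
* **diagram matrix** — the interaction matrix preceded by ``id`` (an ``s``
  plus two digits) and ``node.type`` (an integer colour class 1-4) columns,
  used for rendering grouped network diagrams.

Node names are matched exactly after trimming leading/trailing whitespace;
names may contain spaces.
"""
from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from difflib import get_close_matches
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MIN_STRENGTH = -4
MAX_STRENGTH = 4

_ID_PATTERN = re.compile(r"s\d{2}")


class NetworkFormatError(ValueError):
    """A CSV file violates the interaction/scenario/diagram dialect."""


@dataclass(frozen=True)
class InteractionNetwork:
    """A signed directed network of qualitative influences.

    ``nodes`` is the ordered tuple of unique node labels (header order of the
    source matrix); ``edges`` maps ``(parent, child)`` to an integer strength
    in {-4..-1, 1..4}.  Absent pairs carry no influence.
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(str(n).strip() for n in self.nodes))
        object.__setattr__(self, "edges", dict(self.edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkFormatError("duplicate node labels after trimming whitespace")
        node_set = set(self.nodes)
        for (parent, child), strength in self.edges.items():
            if parent not in node_set or child not in node_set:
                raise NetworkFormatError(
                    f"edge ({parent!r}, {child!r}) references a label not in the node list"
                )
            if parent == child:
                raise NetworkFormatError(f"self-edge on node {parent!r} is not allowed")
            if not isinstance(strength, int) or isinstance(strength, bool):
                raise NetworkFormatError(
                    f"edge ({parent!r}, {child!r}) has non-integer strength {strength!r}"
                )
            if strength == 0 or not MIN_STRENGTH <= strength <= MAX_STRENGTH:
                raise NetworkFormatError(
                    f"edge ({parent!r}, {child!r}) strength {strength} outside "
                    f"{{-4..-1, 1..4}}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parent_map(self) -> dict[str, list[tuple[str, int]]]:
        """Map each child to its ``(parent, strength)`` list, in node order."""
        parents: dict[str, list[tuple[str, int]]] = {n: [] for n in self.nodes}
        for (parent, child), strength in self.edges.items():
            parents[child].append((parent, strength))
        return parents


@dataclass(frozen=True)
class Scenario:
    """Known prior changes for a subset of nodes, on the -4..4 scale.

    Nodes absent from ``priors`` are implicitly 0 (no prior knowledge).
    Zero-valued entries are dropped at construction so that ``priors`` holds
    only genuinely manipulated nodes.
    """

    priors: Mapping[str, int]
    name: str = "scenario"

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for label, value in dict(self.priors).items():
            label = str(label).strip()
            if not isinstance(value, int) or isinstance(value, bool):
                raise NetworkFormatError(
                    f"prior for {label!r} must be an integer, got {value!r}"
                )
            if not MIN_STRENGTH <= value <= MAX_STRENGTH:
                raise NetworkFormatError(
                    f"prior for {label!r} is {value}, outside -4..4"
                )
            if value != 0:
                cleaned[label] = value
        object.__setattr__(self, "priors", cleaned)

    def validate_for(self, network: InteractionNetwork) -> None:
        for label in self.priors:
            if label not in network.nodes:
                raise NetworkFormatError(
                    _unknown_label_message(label, network.nodes)
                )


@dataclass(frozen=True)
class DiagramNetwork:
    """An interaction network plus per-node diagram metadata.

    ``ids`` follow the ``s`` + two-digit pattern (s01, s02, ...);
    ``node_types`` assign each node one of four colour classes.
    """

    network: InteractionNetwork
    ids: tuple[str, ...]
    node_types: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "node_types", dict(self.node_types))
        if len(self.ids) != self.network.n_nodes:
            raise NetworkFormatError("one id per node is required")
        if len(set(self.ids)) != len(self.ids):
            raise NetworkFormatError("node ids must be unique")
        for node_id in self.ids:
            if not _ID_PATTERN.fullmatch(node_id):
                raise NetworkFormatError(
                    f"id {node_id!r} does not match the 's' + 2-digit pattern (e.g. s01)"
                )
        for node in self.network.nodes:
            node_type = self.node_types.get(node)
            if node_type not in (1, 2, 3, 4):
                raise NetworkFormatError(
                    f"node.type for {node!r} must be an integer 1-4, got {node_type!r}"
                )


def _unknown_label_message(label: str, nodes: Sequence[str]) -> str:
    close = get_close_matches(label, nodes, n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    return f"unknown node label {label!r}{hint}"


def _parse_strength(cell: str, parent: str, child: str) -> int | None:
    """Parse one matrix cell; None means no edge (blank or explicit 0)."""
    text = cell.strip()
    if text == "":
        return None
    try:
        value = int(text)
    except ValueError:
        raise NetworkFormatError(
            f"cell ({parent!r} -> {child!r}) is {text!r}; edge strengths must be "
            f"whole numbers in -4..4 (decimal values are not valid)"
        ) from None
    if value == 0:
        warnings.warn(
            f"cell ({parent!r} -> {child!r}) is 0; treated as no edge "
            f"(leave the cell blank instead)",
            stacklevel=3,
        )
        return None
    if not MIN_STRENGTH <= value <= MAX_STRENGTH:
        raise NetworkFormatError(
            f"cell ({parent!r} -> {child!r}) is {value}, outside -4..4"
        )
    if parent == child:
        raise NetworkFormatError(
            f"diagonal cell for {parent!r} is {value}; self-edges are not allowed"
        )
    return value


def _read_rows(path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as handle:
        return [row for row in csv.reader(handle) if any(c.strip() for c in row)]


def read_network(path) -> InteractionNetwork:
    """Read an (n+1) x n interaction-matrix CSV.

    Row labels are parents; column headers are children.  Blank cells are
    absent edges; an explicit 0 is accepted with a warning.
    """
    rows = _read_rows(path)
    if len(rows) < 2:
        raise NetworkFormatError(f"{path}: expected a header row and at least one data row")
    header = [c.strip() for c in rows[0][1:]]
    if len(set(header)) != len(header):
        raise NetworkFormatError(f"{path}: duplicate node names in the header row")
    row_labels = [r[0].strip() for r in rows[1:]]
    if len(set(row_labels)) != len(row_labels):
        raise NetworkFormatError(f"{path}: duplicate node names in the row labels")
    if set(row_labels) != set(header):
        missing = sorted(set(header) - set(row_labels))
        extra = sorted(set(row_labels) - set(header))
        raise NetworkFormatError(
            f"{path}: row labels and column headers must name the same nodes "
            f"(missing rows: {missing}; unexpected rows: {extra})"
        )
    edges: dict[tuple[str, str], int] = {}
    for row in rows[1:]:
        parent = row[0].strip()
        cells = row[1:]
        if len(cells) > len(header):
            raise NetworkFormatError(
                f"{path}: row {parent!r} has more cells than the header has columns"
            )
        for child, cell in zip(header, cells):
            strength = _parse_strength(cell, parent, child)
            if strength is not None:
                edges[(parent, child)] = strength
    return InteractionNetwork(tuple(header), edges)


def read_scenario(path, network: InteractionNetwork) -> Scenario:
    """Read a two-column (node, prior change) scenario CSV.

    A header row is detected and skipped if its second field is not an
    integer.  Nodes listed with value 0 and nodes absent from the file are
    both treated as "no known change"; absent nodes additionally trigger a
    warning so typos do not pass silently.
    """
    rows = _read_rows(path)
    if not rows:
        raise NetworkFormatError(f"{path}: scenario file is empty")
    first_label = rows[0][0].strip()
    first_value = rows[0][1].strip() if len(rows[0]) > 1 else ""
    try:
        int(first_value)
    except ValueError:
        # a non-integer value on a row naming a real node is a data error,
        # not a header; only drop rows that look like column titles
        if first_label not in network.nodes:
            rows = rows[1:]
    priors: dict[str, int] = {}
    seen: set[str] = set()
    for row in rows:
        if len(row) < 2:
            raise NetworkFormatError(f"{path}: scenario rows need a label and a value")
        label = row[0].strip()
        if label not in network.nodes:
            raise NetworkFormatError(f"{path}: " + _unknown_label_message(label, network.nodes))
        text = row[1].strip()
        try:
            value = int(text)
        except ValueError:
            raise NetworkFormatError(
                f"{path}: prior for {label!r} is {text!r}; must be an integer in -4..4"
            ) from None
        if not MIN_STRENGTH <= value <= MAX_STRENGTH:
            raise NetworkFormatError(
                f"{path}: prior for {label!r} is {value}, outside -4..4"
            )
        seen.add(label)
        if value != 0:
            priors[label] = value
    unlisted = [n for n in network.nodes if n not in seen]
    if unlisted:
        warnings.warn(
            f"{path}: nodes {unlisted} not listed in the scenario; treated as no known change",
            stacklevel=2,
        )
    return Scenario(priors, name=Path(path).stem)


def read_diagram_network(path) -> DiagramNetwork:
    """Read the diagram dialect: ``id, node.type, node.name`` + edge columns."""
    rows = _read_rows(path)
    if len(rows) < 2:
        raise NetworkFormatError(f"{path}: expected a header row and at least one data row")
    header = [c.strip() for c in rows[0]]
    if header[:3] != ["id", "node.type", "node.name"]:
        raise NetworkFormatError(
            f"{path}: first three columns must be named id, node.type, node.name "
            f"(got {header[:3]})"
        )
    edge_cols = header[3:]
    ids: list[str] = []
    names: list[str] = []
    node_types: dict[str, int] = {}
    data: list[list[str]] = []
    for row in rows[1:]:
        if len(row) < 3:
            raise NetworkFormatError(f"{path}: diagram rows need id, node.type and node.name")
        node_id, type_text, name = row[0].strip(), row[1].strip(), row[2].strip()
        try:
            node_type = int(type_text)
        except ValueError:
            raise NetworkFormatError(
                f"{path}: node.type for {name!r} is {type_text!r}; must be an integer 1-4"
            ) from None
        if node_type not in (1, 2, 3, 4):
            raise NetworkFormatError(
                f"{path}: node.type for {name!r} is {node_type}, outside 1-4"
            )
        ids.append(node_id)
        names.append(name)
        node_types[name] = node_type
        data.append(row[3:])
    if names != edge_cols:
        raise NetworkFormatError(
            f"{path}: node.name entries must match the edge columns in order "
            f"(rows: {names}; columns: {edge_cols})"
        )
    edges: dict[tuple[str, str], int] = {}
    for parent, cells in zip(names, data):
        for child, cell in zip(edge_cols, cells):
            strength = _parse_strength(cell, parent, child)
            if strength is not None:
                edges[(parent, child)] = strength
    network = InteractionNetwork(tuple(names), edges)
    return DiagramNetwork(network, tuple(ids), node_types)


def write_network(network: InteractionNetwork, path) -> None:
    """Write an interaction network back to the matrix dialect (blank = no edge)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow([""] + list(network.nodes))
        for parent in network.nodes:
            row: list[str] = [parent]
            for child in network.nodes:
                strength = network.edges.get((parent, child))
                row.append("" if strength is None else str(strength))
            writer.writerow(row)


def write_scenario(scenario: Scenario, network: InteractionNetwork, path) -> None:
    """Write a scenario listing every network node (0 for no known change)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["node", "change"])
        for node in network.nodes:
            writer.writerow([node, scenario.priors.get(node, 0)])


def write_diagram_network(diagram: DiagramNetwork, path) -> None:
    """Write the diagram dialect with id / node.type / node.name columns."""
    network = diagram.network
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "node.type", "node.name"] + list(network.nodes))
        for node_id, parent in zip(diagram.ids, network.nodes):
            row = [node_id, str(diagram.node_types[parent]), parent]
            for child in network.nodes:
                strength = network.edges.get((parent, child))
                row.append("" if strength is None else str(strength))
            writer.writerow(row)


def write_predictions(results: Iterable, path) -> None:
    """Write prediction results as CSV: one row per node, one column block per scenario.

    Each scenario contributes a point-estimate column named after the
    scenario; when confidence bounds are present they follow as
    ``<name>_ci_low`` / ``<name>_ci_high`` columns.
    """
    results = list(results)
    if not results:
        raise ValueError("write_predictions needs at least one result")
    nodes = list(results[0].change.keys())
    frame = pd.DataFrame(index=pd.Index(nodes, name="node"))
    for result in results:
        frame[result.scenario_name] = [result.change[n] for n in nodes]
        if result.ci_low is not None and result.ci_high is not None:
            frame[f"{result.scenario_name}_ci_low"] = [result.ci_low[n] for n in nodes]
            frame[f"{result.scenario_name}_ci_high"] = [result.ci_high[n] for n in nodes]
    frame.to_csv(path)
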