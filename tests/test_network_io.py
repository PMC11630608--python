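import csv

import pandas as pd
import pytest

from qbbn import network_io
from qbbn.network_io import (
    InteractionNetwork,
    NetworkFormatError,
    Scenario,
    read_diagram_network,
    read_network,
    read_scenario,
    write_diagram_network,
    write_network,
    write_predictions,
)
from qbbn.engine import PredictionResult


def write_csv(path, rows):
    with open(path, "w", newline="", encoding="utf-8") as handle:
        csv.writer(handle).writerows(rows)
    return path


@pytest.fixture
def net_ab(tmp_path):
    return read_network(write_csv(tmp_path / "net.csv", [["", "A", "B"], ["A", "", "4"], ["B", "", ""]]))


class TestReadNetwork:
    def test_minimal_matrix(self, net_ab):
        assert net_ab.nodes == ("A", "B")
        assert dict(net_ab.edges) == {("A", "B"): 4}

    def test_decimal_cell_rejected_with_location(self, tmp_path):
        path = write_csv(tmp_path / "net.csv", [["", "A", "B"], ["A", "", "2.5"], ["B", "", ""]])
        with pytest.raises(NetworkFormatError, match="'A'.*'B'.*2.5"):
            read_network(path)

    def test_edge_count_matches_independent_cell_scan(self, tmp_path):
        # 7 nodes, 12 filled off-diagonal cells, blank diagonal
        nodes = list("ABCDEFG")
        filled = [(i, (i + k) % 7) for i in range(7) for k in (1, 2)][:12]
        rows = [[""] + nodes]
        for i, parent in enumerate(nodes):
            row = [parent] + [""] * 7
            for (pi, ci) in filled:
                if pi == i:
                    row[ci + 1] = "3"
            rows.append(row)
        path = write_csv(tmp_path / "net7.csv", rows)
        # independent scan of the raw CSV
        with open(path, newline="") as handle:
            raw = list(csv.reader(handle))
        n_filled = sum(1 for row in raw[1:] for cell in row[1:] if cell.strip())
        network = read_network(path)
        assert network.n_edges == n_filled == 12
        assert network.nodes == tuple(nodes)

    @pytest.mark.parametrize(
        "rows, match",
        [
            ([["", "A", "A"], ["A", "", ""], ["A", "", ""]], "duplicate"),
            ([["", "A", "B"], ["A", "", "4"], ["C", "", ""]], "same nodes"),
            ([["", "A", "B"], ["A", "5", ""], ["B", "", ""]], "outside"),
            ([["", "A", "B"], ["A", "2", ""], ["B", "", ""]], "self-edge"),
        ],
    )
    def test_malformed_matrices_rejected(self, tmp_path, rows, match):
        with pytest.raises(NetworkFormatError, match=match):
            read_network(write_csv(tmp_path / "bad.csv", rows))

    def test_zero_cell_warns_and_is_dropped(self, tmp_path):
        path = write_csv(tmp_path / "net.csv", [["", "A", "B"], ["A", "", "0"], ["B", "", ""]])
        with pytest.warns(UserWarning, match="no edge"):
            network = read_network(path)
        assert network.n_edges == 0

    def test_names_with_spaces_survive(self, tmp_path):
        rows = [["", "Green Algae", " Limpet "], ["Green Algae", "", "-2"], ["Limpet", "3", ""]]
        network = read_network(write_csv(tmp_path / "net.csv", rows))
        assert network.nodes == ("Green Algae", "Limpet")
        assert network.edges[("Limpet", "Green Algae")] == 3

    def test_round_trip_preserves_cell_set(self, tmp_path, net_ab):
        out = tmp_path / "again.csv"
        write_network(net_ab, out)
        again = read_network(out)
        assert again.nodes == net_ab.nodes
        assert dict(again.edges) == dict(net_ab.edges)


class TestReadScenario:
    def test_single_removal(self, tmp_path, net_ab):
        path = write_csv(tmp_path / "s.csv", [["node", "change"], ["A", "0"], ["B", "-4"]])
        scenario = read_scenario(path, net_ab)
        assert dict(scenario.priors) == {"B": -4}
        assert scenario.name == "s"

    def test_all_zero_is_empty(self, tmp_path, net_ab):
        path = write_csv(tmp_path / "null.csv", [["A", "0"], ["B", "0"]])
        assert dict(read_scenario(path, net_ab).priors) == {}

    def test_unknown_node_suggests_nearest(self, tmp_path):
        network = InteractionNetwork(("Dogwhelk", "Limpet"), {("Dogwhelk", "Limpet"): -3})
        path = write_csv(tmp_path / "s.csv", [["Dogwelk", "-4"], ["Limpet", "0"]])
        with pytest.raises(NetworkFormatError, match="Dogwhelk"):
            read_scenario(path, network)

    def test_missing_node_warns_and_defaults_to_zero(self, tmp_path, net_ab):
        path = write_csv(tmp_path / "s.csv", [["A", "2"]])
        with pytest.warns(UserWarning, match="no known change"):
            scenario = read_scenario(path, net_ab)
        assert dict(scenario.priors) == {"A": 2}

    @pytest.mark.parametrize("value", ["7", "-5", "1.5", "high"])
    def test_invalid_values_rejected(self, tmp_path, net_ab, value):
        path = write_csv(tmp_path / "s.csv", [["A", value], ["B", "0"]])
        with pytest.raises(NetworkFormatError):
            read_scenario(path, net_ab)


class TestDiagram:
    def rows(self, types=("1", "2", "2")):
        return [
            ["id", "node.type", "node.name", "A", "B", "C"],
            ["s01", types[0], "A", "", "4", ""],
            ["s02", types[1], "B", "", "", "-2"],
            ["s03", types[2], "C", "", "", ""],
        ]

    def test_colour_classes(self, tmp_path):
        dn = read_diagram_network(write_csv(tmp_path / "d.csv", self.rows()))
        assert dn.node_types == {"A": 1, "B": 2, "C": 2}
        assert dn.ids == ("s01", "s02", "s03")

    def test_bad_node_type_rejected(self, tmp_path):
        with pytest.raises(NetworkFormatError, match="outside 1-4"):
            read_diagram_network(write_csv(tmp_path / "d.csv", self.rows(("1", "5", "2"))))

    def test_bad_id_pattern_rejected(self, tmp_path):
        rows = self.rows()
        rows[1][0] = "node1"
        with pytest.raises(NetworkFormatError, match="2-digit"):
            read_diagram_network(write_csv(tmp_path / "d.csv", rows))

    def test_agrees_with_matrix_parser(self, tmp_path):
        dn = read_diagram_network(write_csv(tmp_path / "d.csv", self.rows()))
        matrix_rows = [["", "A", "B", "C"], ["A", "", "4", ""], ["B", "", "", "-2"], ["C", "", "", ""]]
        plain = read_network(write_csv(tmp_path / "m.csv", matrix_rows))
        assert dict(dn.network.edges) == dict(plain.edges)
        assert dn.network.nodes == plain.nodes

    def test_diagram_round_trip(self, tmp_path):
        dn = read_diagram_network(write_csv(tmp_path / "d.csv", self.rows()))
        out = tmp_path / "again.csv"
        write_diagram_network(dn, out)
        again = read_diagram_network(out)
        assert dict(again.network.edges) == dict(dn.network.edges)
        assert again.node_types == dn.node_types


class TestWritePredictions:
    def test_columns_follow_scenario_order(self, tmp_path):
        results = [
            PredictionResult(f"scenario{i}", {"A": float(i), "B": -float(i)})
            for i in (1, 2, 3)
        ]
        out = tmp_path / "pred.csv"
        write_predictions(results, out)
        frame = pd.read_csv(out, index_col="node")
        assert list(frame.columns) == ["scenario1", "scenario2", "scenario3"]
        assert list(frame.index) == ["A", "B"]

    def test_round_trip_to_six_decimals(self, tmp_path):
        result = PredictionResult(
            "s", {"A": 1.2345678, "B": -0.7654321},
            ci_low={"A": 1.0, "B": -1.0}, ci_high={"A": 1.5, "B": -0.5},
        )
        out = tmp_path / "pred.csv"
        write_predictions([result], out)
        frame = pd.read_csv(out, index_col="node")
        assert frame.loc["A", "s"] == pytest.approx(1.2345678, abs=1e-6)
        assert frame.loc["B", "s_ci_low"] == pytest.approx(-1.0, abs=1e-6)
        assert frame.loc["B", "s_ci_high"] == pytest.approx(-0.5, abs=1e-6)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_predictions([], tmp_path / "pred.csv")


def test_scenario_type_validation():
    with pytest.raises(NetworkFormatError):
        Scenario({"A": 2.5})
    with pytest.raises(NetworkFormatError):
        Scenario({"A": 9})
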