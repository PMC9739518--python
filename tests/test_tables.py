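"""Table I/O: unit handling, validation, calibration, network export."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from odorbalance import (
    fit_calibration,
    invert_calibration,
    read_groups,
    read_odor_map,
    read_quant_table,
    read_threshold_table,
    write_network,
    write_quant_table,
)
from odorbalance.exceptions import (
    InsufficientDataError,
    TableFormatError,
    ValidationError,
)
from odorbalance.tables import read_network_graphml


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestQuantTable:
    def test_mg_per_l_converted_to_ug_per_l(self, tmp_path):
        p = _write(tmp_path, "q.csv", "sample,a,b\ns1,1,2\ns2,3,4\ns3,5,6\n")
        table = read_quant_table(p, unit="mg/L")
        assert table.to_numpy().tolist() == [[1000, 2000], [3000, 4000], [5000, 6000]]

    def test_ug_per_l_is_identity(self, tmp_path):
        p = _write(tmp_path, "q.csv", "sample,a\ns1,7.5\n")
        assert read_quant_table(p, unit="ug/L").loc["s1", "a"] == 7.5

    def test_duplicate_compound_column_rejected_by_name(self, tmp_path):
        p = _write(tmp_path, "q.csv", "sample,a,a\ns1,1,2\n")
        with pytest.raises(TableFormatError, match="a"):
            read_quant_table(p)

    def test_negative_value_names_the_cell(self, tmp_path):
        p = _write(tmp_path, "q.csv", "sample,a,b\ns1,1,2\ns2,-3,4\n")
        with pytest.raises(ValidationError, match="s2'.*'a'"):
            read_quant_table(p)

    def test_round_trip_is_bit_exact(self, tmp_path):
        table = pd.DataFrame(
            {"a": [0.1234567890123, np.nan], "b": [1e-7, 44000.0]}, index=["s1", "s2"]
        )
        path = tmp_path / "q.csv"
        write_quant_table(table, path)
        back = read_quant_table(path)
        pd.testing.assert_frame_equal(back, table, check_exact=True, check_names=False)

    def test_unknown_unit_rejected(self, tmp_path):
        p = _write(tmp_path, "q.csv", "sample,a\ns1,1\n")
        with pytest.raises(ValidationError, match="unit"):
            read_quant_table(p, unit="ng/L")

    def test_empty_cells_become_missing(self, tmp_path):
        p = _write(tmp_path, "q.csv", "sample,a,b\ns1,,2\n")
        table = read_quant_table(p)
        assert np.isnan(table.loc["s1", "a"]) and table.loc["s1", "b"] == 2


class TestMapTables:
    def test_reference_furfural_threshold(self, tmp_path, reference_thresholds):
        assert reference_thresholds["Furfural"] == 44000.0

    def test_threshold_csv_round(self, tmp_path):
        p = _write(tmp_path, "t.csv", "compound,threshold_ug_per_L\nFurfural,44000\n")
        assert read_threshold_table(p)["Furfural"] == 44000.0

    def test_nonpositive_threshold_rejected(self, tmp_path):
        p = _write(tmp_path, "t.csv", "compound,threshold_ug_per_L\nx,0\n")
        with pytest.raises(ValidationError, match="x"):
            read_threshold_table(p)

    def test_descriptor_cell_splits_and_normalises(self, tmp_path):
        p = _write(tmp_path, "o.csv", 'compound,descriptors\nFurfural,"Nutty, sweet, bread"\n')
        assert read_odor_map(p)["Furfural"] == ("nutty", "sweet", "bread")

    def test_reference_furfural_descriptors(self, reference_odor_map):
        assert reference_odor_map["Furfural"] == ("nutty", "sweet", "bread")

    def test_empty_descriptor_cell_excluded_with_warning(self, tmp_path):
        p = _write(tmp_path, "o.csv", "compound,descriptors\nx,\ny,malt\n")
        with pytest.warns(UserWarning, match="x"):
            odors = read_odor_map(p)
        assert "x" not in odors and odors["y"] == ("malt",)

    def test_groups_need_exactly_two_labels(self, tmp_path):
        p = _write(tmp_path, "g.csv", "sample,group\ns1,A\ns2,A\n")
        with pytest.raises(ValidationError, match="two group"):
            read_groups(p)

    def test_unknown_sample_in_groups_warned_and_ignored(self, tmp_path):
        p = _write(tmp_path, "g.csv", "sample,group\ns1,A\ns2,B\nzz,B\n")
        with pytest.warns(UserWarning, match="zz"):
            groups = read_groups(p, samples=["s1", "s2"])
        assert list(groups.index) == ["s1", "s2"]


class TestCalibration:
    def test_exact_line_recovered(self):
        curve = fit_calibration([(1, 2), (2, 4), (3, 6)])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_inversion(self):
        curve = fit_calibration([(1, 2), (2, 4), (3, 6)])
        assert invert_calibration(curve, 4.0) == pytest.approx(2.0)

    def test_matches_normal_equations_on_noisy_points(self):
        # independent closed-form least squares: beta = (X'X)^-1 X'y
        rng = np.random.default_rng(42)
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        y = 3.1 * x + 0.7 + rng.normal(0, 0.2, size=5)
        design = np.column_stack([x, np.ones_like(x)])
        slope_ref, intercept_ref = np.linalg.solve(design.T @ design, design.T @ y)
        curve = fit_calibration(list(zip(x, y)))
        assert curve.slope == pytest.approx(slope_ref, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept_ref, rel=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([(1, 2), (2, 4)])

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration([(1, 2), (1, 3), (2, 4)])


class TestNetworkExport:
    def _net(self):
        g = nx.Graph()
        g.add_node("A", mean_RG=1.0)
        g.add_node("B", mean_RG=2.0)
        g.add_edge("A", "B", r=0.8, sign="pos", group="RG", p=0.001)
        return g

    def test_sif_minimal_graph(self, tmp_path):
        path = tmp_path / "net.sif"
        write_network(self._net(), path, format="sif")
        assert path.read_text().strip() == "A\tpos\tB"

    def test_graphml_round_trip_preserves_counts(self, tmp_path):
        path = tmp_path / "net.graphml"
        write_network(self._net(), path, format="graphml")
        back = read_network_graphml(path)
        assert back.number_of_nodes() == 2 and back.number_of_edges() == 1
        assert back.edges["A", "B"]["r"] == pytest.approx(0.8)

    def test_edge_csv_columns(self, tmp_path):
        path = tmp_path / "net.csv"
        write_network(self._net(), path, format="edge-csv")
        df = pd.read_csv(path)
        assert list(df.columns) == ["source", "target", "r", "p", "sign", "group"]
        assert len(df) == 1

    def test_empty_network_is_valid_zero_edge_file(self, tmp_path):
        path = tmp_path / "net.csv"
        write_network(nx.Graph(), path, format="edge-csv")
        assert len(pd.read_csv(path)) == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="format"):
            write_network(self._net(), tmp_path / "x", format="gexf")
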