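import numpy as np
import pandas as pd
import pytest

from cytonet import build_network, fold_changes, pearson_matrix, ward_cluster
from cytonet.io import DayMatrix
from cytonet.markers import NETWORK_CLUSTER
from cytonet.network import CorrelationMatrix
from oracles import pearson_r_formula, ward_linkage_naive


def _panel_matrix(df: pd.DataFrame, day: int = 1) -> DayMatrix:
    df = df.copy()
    df.index.name = "subject_id"
    sev = pd.DataFrame(index=df.index, columns=["sofa", "jaam", "isth"], dtype=float)
    return DayMatrix(day=day, log10=df, raw=10.0**df, severity=sev)


class TestPearsonMatrix:
    def test_diagonal_is_exact(self, day1):
        corr = pearson_matrix(day1)
        assert np.allclose(np.diag(corr.r), 1.0)
        assert np.allclose(np.diag(corr.p), 0.0)

    def test_antisymmetric_pair(self):
        x = np.array([0.1, 0.5, 0.9, 1.3, 2.0])
        dm = _panel_matrix(pd.DataFrame({"a": x, "b": -x}))
        corr = pearson_matrix(dm)
        assert corr.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_five_subject_panel_against_formula_oracle(self):
        data = pd.DataFrame(
            {
                "IL-6": [1.2, 2.4, 1.9, 3.1, 2.2],
                "IL-8": [0.9, 2.1, 1.5, 2.8, 2.4],
                "IL-4": [1.0, 0.7, 1.4, 0.9, 1.1],
            }
        )
        corr = pearson_matrix(_panel_matrix(data))
        for a in data.columns:
            for b in data.columns:
                if a < b:
                    expected = pearson_r_formula(list(data[a]), list(data[b]))
                    assert corr.r.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_counts(self):
        data = pd.DataFrame(
            {
                "a": [1.0, 2.0, np.nan, 4.0, 5.0],
                "b": [2.0, 1.0, 3.0, np.nan, 5.0],
                "c": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        corr = pearson_matrix(_panel_matrix(data))
        assert corr.n.loc["a", "b"] == 3
        ok = data[["a", "b"]].dropna()
        assert corr.r.loc["a", "b"] == pytest.approx(
            pearson_r_formula(list(ok["a"]), list(ok["b"]))
        )

    def test_zero_variance_marker_unavailable_with_reason(self):
        data = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        corr = pearson_matrix(_panel_matrix(data))
        assert np.isnan(corr.r.loc["a", "b"])
        assert corr.unavailable["a"] == "zero variance"

    def test_too_few_pairs_unavailable(self):
        data = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, 1.5, 2.0, 3.0]}
        )
        corr = pearson_matrix(_panel_matrix(data))
        assert np.isnan(corr.r.loc["a", "b"])

    def test_subject_permutation_invariance(self, day1):
        corr = pearson_matrix(day1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(day1.log10))
        shuffled = DayMatrix(
            day=day1.day,
            log10=day1.log10.iloc[perm],
            raw=day1.raw.iloc[perm],
            severity=day1.severity.iloc[perm],
        )
        corr2 = pearson_matrix(shuffled)
        pd.testing.assert_frame_equal(corr.r, corr2.r)


class TestWardClustering:
    @staticmethod
    def _corr_from_r(r: np.ndarray, markers: list[str]) -> CorrelationMatrix:
        idx = pd.Index(markers, name="marker")
        k = len(markers)
        return CorrelationMatrix(
            day=1,
            markers=markers,
            r=pd.DataFrame(r, index=idx, columns=idx),
            p=pd.DataFrame(np.zeros((k, k)), index=idx, columns=idx),
            n=pd.DataFrame(np.full((k, k), 10.0), index=idx, columns=idx),
        )

    def test_two_separated_blocks_recovered(self):
        markers = ["a", "b", "c", "x", "y", "z"]
        r = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    r[i, j] = r[j, i] = 0.9
                    r[i + 3, j + 3] = r[j + 3, i + 3] = 0.9
        corr = self._corr_from_r(r, markers)
        clustering = ward_cluster(corr, cut_height=0.8)
        assert set(clustering.clusters()) == {
            frozenset({"a", "b", "c"}),
            frozenset({"x", "y", "z"}),
        }

    def test_equal_correlations_deterministic(self):
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 1.0)
        corr = self._corr_from_r(r, ["a", "b", "c", "d"])
        z1 = ward_cluster(corr).linkage_matrix
        z2 = ward_cluster(corr).linkage_matrix
        assert np.array_equal(z1, z2)
        assert np.allclose(z1[0, :2], [0, 1])  # first merge is the lowest index pair

    def test_merge_heights_match_naive_lance_williams(self):
        """scipy Ward heights equal a naive O(n^3) reference on 6 markers."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(40, 6))
        x[:, 1] = x[:, 0] + rng.normal(scale=0.6, size=40)
        x[:, 4] = x[:, 3] + rng.normal(scale=0.9, size=40)
        r = np.corrcoef(x, rowvar=False)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        markers = [f"m{i}" for i in range(6)]
        z = ward_cluster(self._corr_from_r(r, markers)).linkage_matrix
        ref = ward_linkage_naive(d)
        assert np.allclose(np.sort(z[:, 2]), np.sort(ref[:, 2]), atol=1e-10)

    def test_single_marker_degenerates_to_one_cluster(self):
        corr = self._corr_from_r(np.array([[1.0]]), ["solo"])
        clustering = ward_cluster(corr)
        assert clustering.labels == {"solo": 1}

    def test_marker_with_unavailable_pairs_dropped(self):
        r = np.array([[1.0, np.nan, 0.2], [np.nan, 1.0, 0.1], [0.2, 0.1, 1.0]])
        corr = self._corr_from_r(r, ["a", "b", "c"])
        clustering = ward_cluster(corr)
        assert "a" in clustering.dropped or "b" in clustering.dropped
        assert len(clustering.markers) == 2


class TestFoldChanges:
    @staticmethod
    def _pair(sepsis_mean: float, control_mean: float):
        sep = _panel_matrix(pd.DataFrame({"IL-6": np.log10([sepsis_mean] * 4)}))
        ctrl = DayMatrix(
            day=None,
            log10=pd.DataFrame({"IL-6": np.log10([control_mean] * 4)}),
            raw=pd.DataFrame({"IL-6": [control_mean] * 4}),
            severity=pd.DataFrame(columns=["sofa", "jaam", "isth"], dtype=float),
        )
        return sep, ctrl

    @pytest.mark.parametrize(
        "ratio,expected_fc,included",
        [(1.0, 0.0, False), (2.0, 1.0, False), (3.0, 1.58496250072115618, True)],
    )
    def test_threshold_arithmetic(self, ratio, expected_fc, included):
        sep, ctrl = self._pair(10.0 * ratio, 10.0)
        fc = fold_changes(sep, ctrl)
        row = fc.set_index("marker").loc["IL-6"]
        assert row["log2fc"] == pytest.approx(expected_fc, abs=1e-12)
        assert bool(row["included"]) is included

    def test_raw_scale_arithmetic_means_used(self):
        # skewed sample: raw-scale mean differs from the geometric mean
        sep = _panel_matrix(pd.DataFrame({"IL-6": np.log10([10.0, 10.0, 1000.0])}))
        _, ctrl = self._pair(1.0, 10.0)
        fc = fold_changes(sep, ctrl)
        expected = np.log2(np.mean([10.0, 10.0, 1000.0]) / 10.0)
        assert fc.set_index("marker").loc["IL-6", "log2fc"] == pytest.approx(expected)

    def test_missing_control_marker_excluded_with_reason(self, day1, controls):
        ctrl = DayMatrix(
            day=None,
            log10=controls.log10.drop(columns=["IL-6"]),
            raw=controls.raw.drop(columns=["IL-6"]),
            severity=controls.severity,
        )
        fc = fold_changes(day1, ctrl)
        row = fc.set_index("marker").loc["IL-6"]
        assert not row["included"] and row["reason"] == "no control data"

    def test_significance_classes(self, day1, controls):
        fc = fold_changes(
            day1,
            controls,
            sepsis_p={"IL-6": 0.001},
            critical_p={"IL-8": 0.01, "IL-6": 0.01},
        )
        cls = fc.set_index("marker")["sig_class"]
        assert cls["IL-6"] == "sepsis_up"  # sepsis comparison wins
        assert cls["IL-8"] == "critical_up"
        assert cls["IL-4"] == "none"


class TestBuildNetwork:
    def test_edge_subset_property(self, day1, controls):
        corr = pearson_matrix(day1)
        fc = fold_changes(day1, controls)
        net = build_network(corr, fc, alpha=0.05)
        included = set(fc.loc[fc["included"], "marker"])
        assert set(net.nodes) == included
        for a, b in net.edges:
            assert a in included and b in included
            assert corr.p.loc[a, b] < 0.05

    def test_no_significant_correlations_yields_empty_edge_set(self):
        data = pd.DataFrame(
            {"a": [1.0, 2.0, 1.5, 2.5], "b": [2.0, 1.0, 2.5, 1.2]}
        )
        dm = _panel_matrix(data)
        corr = pearson_matrix(dm)
        fc = pd.DataFrame(
            {
                "day": [1, 1],
                "marker": ["a", "b"],
                "log2fc": [2.0, 2.0],
                "included": [True, True],
                "sig_class": ["none", "none"],
            }
        )
        net = build_network(corr, fc, alpha=1e-6)
        assert set(net.nodes) == {"a", "b"} and net.edges == []

    def test_subthreshold_fold_change_excluded_despite_correlations(self, day1, controls):
        corr = pearson_matrix(day1)
        fc = fold_changes(day1, controls)
        fc.loc[fc["marker"] == "IL-6", "log2fc"] = 1.2
        fc.loc[fc["marker"] == "IL-6", "included"] = False
        net = build_network(corr, fc)
        assert "IL-6" not in net.nodes

    def test_planted_cluster_forms_one_component(self, cohort200):
        from cytonet import build_day_matrix, control_matrix

        dm = build_day_matrix(cohort200, 1)
        ctrl = control_matrix(cohort200)
        net = build_network(pearson_matrix(dm), fold_changes(dm, ctrl))
        assert set(NETWORK_CLUSTER) <= set(net.nodes)
        assert net.connected_component_of("IL-6") >= set(NETWORK_CLUSTER)

    def test_graph_exports(self, tmp_path, day1, controls):
        net = build_network(pearson_matrix(day1), fold_changes(day1, controls))
        net.write_graphml(tmp_path / "net.graphml")
        net.write_sif(tmp_path / "net.sif")
        sif = (tmp_path / "net.sif").read_text()
        for a, b in net.edges:
            assert f"{a}\tcorrelates\t{b}" in sif
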