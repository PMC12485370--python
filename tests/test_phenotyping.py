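"""Clustering, cluster-to-type mapping, gating and checkpoint calls."""

import numpy as np
import pandas as pd
import pytest

from spatialtme.cell_data import DEFAULT_PANEL
from spatialtme.phenotyping import (
    GateRule,
    apply_gates,
    call_checkpoints,
    cluster_cells,
    phenotype_proportions,
    suggest_phenotype_map,
    summarize_cluster_expression,
)
from spatialtme.synthetic_cohort import MAIN_OF_PHENOTYPE

from conftest import make_cells


def intensity_table(X, markers=DEFAULT_PANEL.markers):
    n = len(X)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n)],
            "sample_id": "s0",
            "patient_id": "p0",
            "x": np.linspace(0, 100, n),
            "y": 0.0,
        }
    )
    for j, m in enumerate(markers):
        df[m] = X[:, j]
    return df


class TestClusterCells:
    def test_two_blobs_low_resolution_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = np.exp(
            np.r_[
                rng.normal(0, 0.1, (500, len(DEFAULT_PANEL.markers))),
                rng.normal(1.0, 0.1, (500, len(DEFAULT_PANEL.markers))),
            ]
        )
        cells = intensity_table(X)
        lab = cluster_cells(cells, k=100, seed=0, resolution=0.1)
        assert lab.nunique() == 2
        assert lab[:500].nunique() == 1 and lab[500:].nunique() == 1

    def test_two_blobs_default_resolution_pure(self):
        # at default (PhenoGraph-like) resolution communities may subdivide
        # a population, but never mix the two separated populations
        rng = np.random.default_rng(1)
        X = np.exp(
            np.r_[
                rng.normal(0, 0.1, (500, len(DEFAULT_PANEL.markers))),
                rng.normal(1.0, 0.1, (500, len(DEFAULT_PANEL.markers))),
            ]
        )
        cells = intensity_table(X)
        lab = cluster_cells(cells, k=100, seed=0)
        blobs = np.repeat([0, 1], 500)
        for c in lab.unique():
            assert len(set(blobs[lab == c])) == 1

    def test_identical_cells_single_cluster(self):
        X = np.ones((150, len(DEFAULT_PANEL.markers)))
        lab = cluster_cells(intensity_table(X), k=100, seed=0)
        assert lab.nunique() == 1

    def test_too_few_cells_errors(self):
        X = np.ones((50, len(DEFAULT_PANEL.markers)))
        with pytest.raises(ValueError, match="reduce k"):
            cluster_cells(intensity_table(X), k=100)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        X = np.exp(rng.normal(0, 0.5, (300, len(DEFAULT_PANEL.markers))))
        cells = intensity_table(X)
        lab1 = cluster_cells(cells, k=30, seed=0)
        shuffled = cells.sample(frac=1.0, random_state=9).reset_index(drop=True)
        lab2 = cluster_cells(shuffled, k=30, seed=0)
        merged = pd.DataFrame(
            {"a": lab1.to_numpy(), "cell_id": cells["cell_id"]}
        ).merge(
            pd.DataFrame({"b": lab2.to_numpy(), "cell_id": shuffled["cell_id"]}),
            on="cell_id",
        )
        assert (merged["a"] == merged["b"]).all()


class TestClusterSummaryAndMap:
    def test_mean_expression_arithmetic(self):
        X = np.ones((2, len(DEFAULT_PANEL.markers)))
        X[0, 0], X[1, 0] = 2.0, 4.0  # CD20
        cells = intensity_table(X)
        summary = summarize_cluster_expression(cells, pd.Series([0, 0]))
        assert summary.loc[0, "CD20"] == 3.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = np.exp(rng.normal(0, 0.4, (60, len(DEFAULT_PANEL.markers))))
        cells = intensity_table(X)
        cl = pd.Series(rng.integers(0, 3, 60))
        s1 = summarize_cluster_expression(cells, cl)
        perm = rng.permutation(60)
        s2 = summarize_cluster_expression(
            cells.iloc[perm].reset_index(drop=True),
            pd.Series(cl.to_numpy()[perm]),
        )
        pd.testing.assert_frame_equal(s1, s2)

    def test_planted_b_cluster_maps_to_b_and_peaks_at_cd20(self, phenotyped_cohort):
        labeled, truth = phenotyped_cohort
        summary = summarize_cluster_expression(labeled, labeled["cluster"])
        mapping = suggest_phenotype_map(summary)
        truth_main = truth.cells.set_index("cell_id")["phenotype"].map(
            MAIN_OF_PHENOTYPE
        )
        merged = labeled.assign(true_main=truth_main.reindex(labeled["cell_id"]).to_numpy())
        b_clusters = [
            c
            for c, grp in merged.groupby("cluster")
            if (grp["true_main"] == "B cell").mean() > 0.9
        ]
        assert b_clusters, "no pure B-cell cluster found"
        for c in b_clusters:
            assert mapping[c] == "B cell"
            lineage = summary.loc[c, ["CD20", "CD3", "CD4", "CD8", "Foxp3", "CD68", "CD163"]]
            assert lineage.idxmax() == "CD20"


class TestGates:
    def test_simple_gate_assigns_label(self):
        X = np.ones((2, len(DEFAULT_PANEL.markers)))
        cells = intensity_table(X)
        cells.loc[0, "CD4"] = 10.0
        main = pd.Series(["nonimmune", "nonimmune"])
        out = apply_gates(
            cells, main, mixed_clusters=[0], clusters=pd.Series([0, 1]),
            rules=[GateRule("CD4", 5.0, "CD4 T cell")],
        )
        assert out.tolist() == ["CD4 T cell", "nonimmune"]

    def test_empty_rules_identity(self):
        X = np.ones((3, len(DEFAULT_PANEL.markers)))
        cells = intensity_table(X)
        main = pd.Series(["B cell"] * 3)
        out = apply_gates(cells, main, [0], pd.Series([0, 0, 0]), rules=[])
        assert (out == main).all()

    def test_hand_computed_fixture(self):
        # 20 cells in one mixed cluster; first-match-wins in rule order
        rng = np.random.default_rng(0)
        X = np.ones((20, len(DEFAULT_PANEL.markers)))
        cells = intensity_table(X)
        cd4 = [8.0] * 6 + [1.0] * 14
        cd8 = [1.0] * 6 + [8.0] * 5 + [1.0] * 9
        cd20 = [1.0] * 11 + [8.0] * 4 + [1.0] * 5
        cd163 = [1.0] * 15 + [8.0] * 3 + [1.0] * 2
        cells["CD4"], cells["CD8"] = cd4, cd8
        cells["CD20"], cells["CD163"] = cd20, cd163
        rules = [
            GateRule("CD4", 3.0, "CD4 T cell"),
            GateRule("CD8", 3.0, "CD8 T cell"),
            GateRule("CD20", 3.0, "B cell"),
            GateRule("CD163", 3.0, "M2 macrophage"),
        ]
        out = apply_gates(
            cells, pd.Series(["other immune"] * 20), [0],
            pd.Series([0] * 20), rules, fallback="nonimmune",
        )
        expected = (
            ["CD4 T cell"] * 6 + ["CD8 T cell"] * 5 + ["B cell"] * 4
            + ["M2 macrophage"] * 3 + ["nonimmune"] * 2
        )
        assert out.tolist() == expected

    def test_unknown_marker_rejected(self):
        X = np.ones((2, len(DEFAULT_PANEL.markers)))
        cells = intensity_table(X)
        with pytest.raises(ValueError, match="unknown marker"):
            apply_gates(cells, pd.Series(["B cell"] * 2), [0],
                        pd.Series([0, 0]), [GateRule("CD99", 1.0, "B cell")])


class TestCheckpoints:
    def test_threshold_above_all_gives_no_positives(self):
        X = np.ones((10, len(DEFAULT_PANEL.markers)))
        cells = intensity_table(X)
        out = call_checkpoints(
            cells, pd.Series(["CD4 T cell"] * 10), {"PD-1": 100.0}
        )
        assert (out == "CD4 T cell").all()

    def test_threshold_is_inclusive(self):
        X = np.ones((1, len(DEFAULT_PANEL.markers)))
        cells = intensity_table(X)
        cells.loc[0, "PD-1"] = 3.0
        out = call_checkpoints(cells, pd.Series(["CD8 T cell"]), {"PD-1": 3.0})
        assert out.iloc[0] == "PD-1+ CD8 T cell"

    def test_absent_marker_threshold_rejected(self):
        X = np.ones((1, len(DEFAULT_PANEL.markers)))
        cells = intensity_table(X)
        with pytest.raises(ValueError, match="absent marker"):
            call_checkpoints(cells, pd.Series(["B cell"]), {"TIM3": 1.0})

    def test_planted_checkpoint_fraction_recovered(self, phenotyped_cohort):
        labeled, truth = phenotyped_cohort
        t = truth.cells.set_index("cell_id")
        cd4 = labeled[labeled["main_type"] == "CD4 T cell"]
        true_cd4 = t.loc[cd4["cell_id"], "phenotype"]
        planted = (true_cd4 == "PD-1+ CD4 T cell").mean()
        called = (cd4["phenotype"] == "PD-1+ CD4 T cell").mean()
        assert called == pytest.approx(planted, abs=0.03)


class TestEndToEnd:
    def test_accuracy_at_least_95_percent(self, phenotyped_cohort):
        labeled, truth = phenotyped_cohort
        t = truth.cells.set_index("cell_id")["phenotype"]
        acc = (labeled["phenotype"].to_numpy() == t.loc[labeled["cell_id"]].to_numpy()).mean()
        assert acc >= 0.95

    def test_every_cell_gets_exactly_one_label(self, phenotyped_cohort):
        labeled, _ = phenotyped_cohort
        from spatialtme.synthetic_cohort import PHENOTYPES

        assert labeled["phenotype"].notna().all()
        assert set(labeled["phenotype"]) <= set(PHENOTYPES)


class TestProportions:
    def test_half_half(self):
        cells = make_cells(
            [(0, 0), (1, 0), (2, 0), (3, 0)],
            ["B cell", "B cell", "CD8 T cell", "CD8 T cell"],
        )
        prop = phenotype_proportions(cells)
        assert prop.loc["s0", "B cell"] == 0.5
        assert prop.loc["s0", "CD8 T cell"] == 0.5

    def test_rows_sum_to_one(self, phenotyped_cohort):
        labeled, _ = phenotyped_cohort
        prop = phenotype_proportions(labeled)
        np.testing.assert_allclose(prop.sum(axis=1), 1.0)

    def test_cohort_mean_matches_generator_mixture(self, phenotyped_cohort):
        from spatialtme.synthetic_cohort import default_phenotype_mixture

        labeled, truth = phenotyped_cohort
        prop = phenotype_proportions(
            labeled.assign(
                phenotype=truth.cells.set_index("cell_id")["phenotype"]
                .reindex(labeled["cell_id"])
                .to_numpy()
            )
        )
        target = default_phenotype_mixture()
        got = prop.mean(axis=0)
        for lab, p in target.items():
            assert abs(got.get(lab, 0.0) - p) < 0.02
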