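"""Clone calling, event discretization, tree ordering, composition, DE."""

import numpy as np
import pandas as pd
import pytest

from gliomosaic.clones import (CloneEventSet, cluster_subclones,
                               clone_differential_expression, consensus_events,
                               merge_subgroups_by_events, order_clones,
                               sector_composition)
from gliomosaic.cnv import ArmCNVMatrix
from gliomosaic.errors import ConfigurationError
from .conftest import lognorm_matrix


def arm_matrix(values, arms=None):
    values = np.asarray(values, dtype=float)
    arms = arms or [f"a{i}" for i in range(values.shape[1])]
    return ArmCNVMatrix(pd.DataFrame(
        values, index=[f"c{i}" for i in range(len(values))], columns=arms))


def ev(*pairs):
    return frozenset(pairs)


class TestSubcloneClustering:
    def test_single_clone_k1(self):
        arm = arm_matrix(np.random.default_rng(0).normal(0.3, 0.02, (10, 3)))
        malignant = pd.Series(True, index=arm.arm_score.index)
        labels = cluster_subclones(arm, malignant, k=1)
        assert set(labels) == {"CN-1"}

    def test_labels_ordered_by_event_count(self):
        rng = np.random.default_rng(1)
        none = rng.normal(0, 0.01, (30, 4))
        one = rng.normal([0.3, 0, 0, 0], 0.01, (30, 4))
        two = rng.normal([0.3, -0.4, 0, 0], 0.01, (30, 4))
        arm = arm_matrix(np.vstack([two, none, one]))
        malignant = pd.Series(True, index=arm.arm_score.index)
        labels = cluster_subclones(arm, malignant, k=3)
        events = consensus_events(arm, labels)
        counts = [len(events[f"CN-{i}"].events) for i in (1, 2, 3)]
        assert counts == sorted(counts)

    def test_non_malignant_labelled_cn0(self):
        rng = np.random.default_rng(2)
        arm = arm_matrix(rng.normal(0, 0.01, (6, 3)))
        malignant = pd.Series([True] * 3 + [False] * 3,
                              index=arm.arm_score.index)
        labels = cluster_subclones(arm, malignant, k=1)
        assert (labels.iloc[3:] == "CN-0").all()

    def test_k_exceeding_malignant_cells(self):
        arm = arm_matrix(np.zeros((4, 2)))
        malignant = pd.Series([True, True, False, False],
                              index=arm.arm_score.index)
        with pytest.raises(ConfigurationError, match="exceeds"):
            cluster_subclones(arm, malignant, k=5)


class TestConsensusEvents:
    def test_diploid_clone_empty_set(self):
        arm = arm_matrix(np.zeros((4, 3)))
        labels = pd.Series("CN-1", index=arm.arm_score.index)
        assert consensus_events(arm, labels)["CN-1"].events == frozenset()

    def test_boundary_threshold_inclusive(self):
        arm = arm_matrix(np.full((3, 1), 0.1), arms=["chr7p"])
        labels = pd.Series("CN-1", index=arm.arm_score.index)
        events = consensus_events(arm, labels, amp_threshold=0.1)
        assert events["CN-1"].events == ev(("chr7p", "amp"))

    def test_seeded_clone_recovered_exactly(self, dose_cohort):
        cohort, arm = dose_cohort
        truth = cohort.truth.cells
        events = consensus_events(arm, truth["true_clone"])
        assert events["CN-A"].events == ev(
            ("chr7p", "amp"), ("chr7q", "amp"),
            ("chr10p", "del"), ("chr10q", "del"))
        assert events["CN-B"].events == events["CN-A"].events | ev(
            ("chr2p", "amp"), ("chr2q", "amp"))
        assert events["CN-C"].events == events["CN-B"].events | ev(
            ("chr5p", "del"), ("chr5q", "del"))


class TestOrderClones:
    def test_linear_chain(self):
        sets = {
            "CN-3": CloneEventSet("CN-3", ev(("7p", "amp"))),
            "CN-4": CloneEventSet("CN-4", ev(("7p", "amp"), ("2p", "amp"))),
            "CN-5": CloneEventSet("CN-5", ev(("7p", "amp"), ("2p", "amp"),
                                             ("5q", "del"))),
        }
        tree = order_clones(sets)
        assert tree.root == "CN-3"
        assert [(p, c) for p, c, _ in tree.edges] == [("CN-3", "CN-4"),
                                                      ("CN-4", "CN-5")]
        gained = {c: g for _, c, g in tree.edges}
        assert gained["CN-4"] == ev(("2p", "amp"))
        assert gained["CN-5"] == ev(("5q", "del"))

    def test_single_clone(self):
        tree = order_clones({"CN-1": CloneEventSet("CN-1", ev(("7p", "amp")))})
        assert tree.root == "CN-1" and not tree.edges

    def test_branching_from_shared_root(self):
        sets = {
            "X": CloneEventSet("X", ev(("7p", "amp"))),
            "XY": CloneEventSet("XY", ev(("7p", "amp"), ("2p", "amp"))),
            "XZ": CloneEventSet("XZ", ev(("7p", "amp"), ("5q", "del"))),
        }
        tree = order_clones(sets)
        assert tree.root == "X"
        assert set(tree.children("X")) == {"XY", "XZ"}

    def test_identical_sets_merged_with_warning(self, caplog):
        sets = {
            "A": CloneEventSet("A", ev(("7p", "amp"))),
            "B": CloneEventSet("B", ev(("7p", "amp"))),
        }
        with caplog.at_level("WARNING"):
            tree = order_clones(sets)
        assert len(tree.nodes) == 1
        assert "merged" in caplog.text

    def test_synthetic_ancestor_for_incomparable_clones(self):
        sets = {
            "AB": CloneEventSet("AB", ev(("1p", "amp"), ("2p", "amp"))),
            "AC": CloneEventSet("AC", ev(("1p", "amp"), ("5q", "del"))),
        }
        tree = order_clones(sets)
        assert tree.root == "CN-anc"
        assert tree.nodes["CN-anc"] == ev(("1p", "amp"))
        assert set(tree.children("CN-anc")) == {"AB", "AC"}

    def test_transitive_reduction_matches_networkx(self):
        import networkx as nx
        rng = np.random.default_rng(9)
        universe = [("1p", "amp"), ("2q", "del"), ("7p", "amp"),
                    ("10q", "del"), ("19q", "del")]
        for trial in range(20):
            n = rng.integers(2, 7)
            sets, seen = {}, set()
            for i in range(n):
                s = frozenset(u for u in universe if rng.random() < 0.5)
                if s in seen:
                    continue
                seen.add(s)
                sets[f"c{i}"] = CloneEventSet(f"c{i}", s)
            if not sets:
                continue
            tree = order_clones(sets)
            tree.validate()
            # oracle: containment DAG over observed clones, reduced by networkx
            g = nx.DiGraph()
            g.add_nodes_from(sets)
            for a in sets:
                for b in sets:
                    if a != b and sets[a].events < sets[b].events:
                        g.add_edge(a, b)
            reduced = nx.transitive_reduction(g)
            observed_edges = {(p, c) for p, c, _ in tree.edges
                              if p in sets and c in sets}
            # every kept edge is a reduced containment edge, and each child
            # hangs under its maximal reduced parent (tree-ification of
            # diamonds keeps the parent sharing the most events)
            assert observed_edges <= set(reduced.edges())
            for c in sets:
                parents = [p for p, cc in reduced.edges() if cc == c]
                if parents:
                    best = max(parents, key=lambda p: (len(sets[p].events), p))
                    assert (best, c) in observed_edges

    def test_newick_and_edge_table(self):
        sets = {
            "R": CloneEventSet("R", ev(("7p", "amp"))),
            "C": CloneEventSet("C", ev(("7p", "amp"), ("2p", "amp"))),
        }
        tree = order_clones(sets)
        assert tree.to_newick() == "(C[&&events=2p:amp])R;"
        table = tree.to_edge_table()
        assert list(table.iloc[0]) == ["R", "C", "2p:amp"]


class TestEndToEndTreeRecovery:
    def test_gs1_like_chain_recovered(self, dose_cohort):
        # deliberate oversegmentation (k=5); clusters with identical consensus
        # event sets merge during tree ordering
        cohort, arm = dose_cohort
        truth = cohort.truth.cells
        malignant = truth["true_clone"] != "CN-0"
        labels = cluster_subclones(arm, malignant, k=5)
        tree = order_clones(consensus_events(arm, labels))
        chain = [tree.root]
        while tree.children(chain[-1]):
            kids = tree.children(chain[-1])
            assert len(kids) == 1
            chain.append(kids[0])
        assert len(chain) == 3
        # gained events along the chain mirror the seeded accumulation order
        gained = [g for _, _, g in tree.edges]
        assert gained[0] == ev(("chr2p", "amp"), ("chr2q", "amp"))
        assert gained[1] == ev(("chr5p", "del"), ("chr5q", "del"))

    def test_subgroup_merge_by_events(self, dose_cohort):
        from sklearn.metrics import adjusted_rand_score
        from gliomosaic.cnv import CNVParams, cluster_cnv_subgroups
        cohort, arm = dose_cohort
        labels = cluster_cnv_subgroups(arm, CNVParams(n_subgroups=5))
        merged = merge_subgroups_by_events(arm, labels)
        truth = cohort.truth.cells["true_clone"]
        assert adjusted_rand_score(truth.values, merged.values) >= 0.9


class TestComposition:
    def test_fractions_sum_to_one_and_counts_conserve(self, small_cohort):
        table = small_cohort.annotation.rename(
            columns={"true_type": "cell_type", "true_clone": "clone"})
        comp = sector_composition(table, "sector")
        sums = comp[comp["variable"] == "cell_type"].groupby("sector")["fraction"].sum()
        np.testing.assert_allclose(sums.values, 1.0, atol=1e-9)
        total = comp[comp["variable"] == "cell_type"]["count"].sum()
        assert total == len(table)

    def test_single_type_single_sector(self):
        table = pd.DataFrame({"sector": ["s"] * 4, "cell_type": ["glia"] * 4})
        comp = sector_composition(table, columns=("cell_type",))
        assert comp["fraction"].iloc[0] == 1.0

    def test_macrophage_core_microglia_margin_switch(self, small_cohort):
        table = small_cohort.annotation.rename(columns={"true_type": "cell_type"})
        comp = sector_composition(table, "sector", ("cell_type",))
        frac = comp.pivot_table(index="sector", columns="value",
                                values="fraction", fill_value=0.0)
        core = frac[frac.index.str.contains("core")]
        margin = frac[frac.index.str.contains("margin")]
        assert (core["macrophage"] > core["microglia"]).all()
        assert (margin["microglia"] > margin["macrophage"]).all()

    def test_composition_matches_seeded_mixture(self, small_cohort):
        # apportionment is deterministic, so recovered fractions equal the
        # config simplex up to 1/cells_per_sector
        comp = sector_composition(
            small_cohort.annotation.rename(columns={"true_type": "cell_type"}),
            "sector", ("cell_type",))
        mixtures = small_cohort.truth.sector_mixtures
        for (patient, name), mix in mixtures.items():
            sector = f"{patient}_{name}"
            block = comp[(comp["sector"] == sector)
                         & (comp["variable"] == "cell_type")]
            obs = dict(zip(block["value"], block["fraction"]))
            expected_malignant = sum(f for k, f in mix.items()
                                     if k.startswith("CN-"))
            for key, f in mix.items():
                if key.startswith("CN-"):
                    continue
                assert obs.get(key, 0.0) == pytest.approx(f, abs=0.02)
            assert obs.get("malignant", 0.0) == pytest.approx(
                expected_malignant, abs=0.02)


class TestDifferentialExpression:
    def _matrix(self, rng, n_genes=300, n_a=50, n_b=50, boost=None):
        vals = rng.normal(0, 1, (n_genes, n_a + n_b))
        if boost is not None:
            genes, lfc = boost
            vals[np.ix_(genes, range(n_a))] += lfc
        m = lognorm_matrix(vals)
        labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=m.cell_ids)
        return m, labels

    def test_group_overlap_rejected(self):
        rng = np.random.default_rng(0)
        m, labels = self._matrix(rng)
        with pytest.raises(ConfigurationError, match="overlap"):
            clone_differential_expression(m, labels, ["A"], ["A", "B"])

    def test_minimum_group_size(self):
        rng = np.random.default_rng(0)
        m, labels = self._matrix(rng, n_a=2, n_b=50)
        with pytest.raises(ConfigurationError, match=">= 3"):
            clone_differential_expression(m, labels, ["A"], ["B"])

    def test_seeded_genes_recovered(self):
        rng = np.random.default_rng(1)
        seeded = list(range(20))
        m, labels = self._matrix(rng, boost=(seeded, 2.0))
        table = clone_differential_expression(m, labels, ["A"], ["B"])
        top = set(table.head(20)["gene"])
        assert len(top & {f"g{i}" for i in seeded}) >= 18
        assert (table.set_index("gene").loc[[f"g{i}" for i in seeded],
                                            "lfc"] > 0).all()

    def test_null_split_controls_type_one(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            m, labels = self._matrix(rng)
            table = clone_differential_expression(m, labels, ["A"], ["B"])
            hits += table["significant"].sum() == 0
        assert hits >= 4

    def test_cnv_dose_flag_contract(self):
        rng = np.random.default_rng(2)
        m, labels = self._matrix(rng, n_genes=4)
        annotation = pd.DataFrame({
            "chrom": ["chr2", "chr2", "chr3", "chr3"],
            "start": [0, 2000, 0, 2000], "end": [1000, 3000, 1000, 3000],
            "arm": ["p", "p", "q", "q"]}, index=[f"g{i}" for i in range(4)])
        events = {
            "A": CloneEventSet("A", ev(("chr2p", "amp"))),
            "B": CloneEventSet("B", frozenset()),
        }
        table = clone_differential_expression(
            m, labels, ["A"], ["B"], annotation=annotation, clone_events=events)
        flags = table.set_index("gene")["cnv_dose"]
        assert flags["g0"] and flags["g1"]
        assert not flags["g2"] and not flags["g3"]
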