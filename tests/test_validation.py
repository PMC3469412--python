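import itertools

import numpy as np
import pytest

from modflux.discovery import ClusterAssignment
from modflux.dynamics import InfluenceModel
from modflux.validation import (
    InteractionSet,
    pair_interaction_counts,
    read_interaction_set,
    rewire_pvalues,
    validation_accuracy,
)

FOUR_GENES = ClusterAssignment({"a": 1, "b": 1, "c": 2, "d": 2})


class TestInteractionSet:
    def test_duplicates_collapse(self):
        iset = InteractionSet("x", [("a", "b"), ("a", "b"), ("b", "a")], directed=True)
        assert iset.n_edges == 2
        undirected = InteractionSet("x", [("a", "b"), ("b", "a")], directed=False)
        assert undirected.n_edges == 1

    def test_read_with_directive(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("#directed=false\ngene_a\tgene_b\na\tc\n")
        iset = read_interaction_set(p, name="ppi")
        assert not iset.directed
        assert iset.edges == [("a", "c")]


class TestPairCounts:
    def test_empty_set_gives_zeros(self):
        counts = pair_interaction_counts(FOUR_GENES, InteractionSet("e", []))
        assert counts.tolist() == [[0, 0], [0, 0]]

    def test_directed_enumeration(self):
        iset = InteractionSet("d", [("a", "c"), ("b", "d")], directed=True)
        counts = pair_interaction_counts(FOUR_GENES, iset)
        assert counts[0, 1] == 2
        assert counts[1, 0] == 0

    def test_undirected_counts_both_directions(self):
        iset = InteractionSet("u", [("a", "c"), ("b", "d")], directed=False)
        counts = pair_interaction_counts(FOUR_GENES, iset)
        assert counts[0, 1] == 2 and counts[1, 0] == 2

    def test_total_equals_usable_edges(self):
        rng = np.random.default_rng(0)
        genes = list("abcd")
        edges = [
            (genes[i], genes[j])
            for i, j in rng.integers(0, 4, size=(30, 2))
        ]
        directed = InteractionSet("d", edges, directed=True)
        counts = pair_interaction_counts(FOUR_GENES, directed)
        assert counts.sum() == directed.n_edges
        undirected = InteractionSet("u", edges, directed=False)
        counts_u = pair_interaction_counts(FOUR_GENES, undirected)
        assert counts_u.sum() == 2 * undirected.n_edges

    def test_unclustered_endpoints_dropped(self):
        iset = InteractionSet("d", [("a", "zz"), ("a", "c")], directed=True)
        counts = pair_interaction_counts(FOUR_GENES, iset)
        assert counts.sum() == 1


class TestRewirePvalues:
    def test_zero_count_pair_has_p_one(self):
        iset = InteractionSet("d", [("a", "c")], directed=True)
        p = rewire_pvalues(FOUR_GENES, iset, n_reps=50, rng=np.random.default_rng(1))
        assert p[1, 0] == 1.0  # no 2->1 edge observed

    def test_single_cluster_is_permutation_invariant(self):
        assign = ClusterAssignment({"a": 1, "b": 1, "c": 1})
        iset = InteractionSet("d", [("a", "b"), ("b", "c")], directed=True)
        p = rewire_pvalues(assign, iset, n_reps=30, rng=np.random.default_rng(2))
        assert p[0, 0] == 1.0

    def test_matches_exhaustive_permutation_enumeration(self):
        """Large-n permutation p-value converges to the exact average over
        all 4! gene relabelings."""
        iset = InteractionSet("d", [("a", "c"), ("b", "d"), ("a", "d")], directed=True)
        labels = {g: c for g, c in FOUR_GENES.mapping.items()}
        genes = sorted(labels)
        observed = pair_interaction_counts(FOUR_GENES, iset)
        exact_ge = np.zeros_like(observed, dtype=float)
        n_perm = 0
        for perm in itertools.permutations(genes):
            relabel = dict(zip(genes, perm))
            null_counts = np.zeros_like(observed)
            for x, y in iset.edges:
                null_counts[labels[relabel[x]] - 1, labels[relabel[y]] - 1] += 1
            exact_ge += null_counts >= observed
            n_perm += 1
        exact_p = exact_ge / n_perm
        p = rewire_pvalues(
            FOUR_GENES, iset, n_reps=40000, rng=np.random.default_rng(3)
        )
        # smoothed empirical p converges to the exact permutation fraction
        assert np.allclose(p, exact_p, atol=0.02)

    def test_too_few_genes_rejected(self):
        assign = ClusterAssignment({"a": 1})
        with pytest.raises(ValueError):
            rewire_pvalues(assign, InteractionSet("d", []), n_reps=10)


class TestValidationAccuracy:
    def _model(self, support):
        # support given source -> target; stored matrix rows are targets
        a = np.zeros((3, 3))
        for s, t in support:
            a[t, s] = 0.5
        np.fill_diagonal(a, -0.1)
        return InfluenceModel(a, np.ones(3, dtype=int))

    def test_quoted_accuracy_formula(self):
        # 6 ordered pairs: 3 TP + 2 TN + 1 FN -> accuracy 5/6
        model = self._model([(0, 1), (0, 2), (1, 2), (2, 1)])
        p = np.ones((3, 3))
        for s, t in [(0, 1), (0, 2), (1, 2)]:
            p[s, t] = 0.01
        table = validation_accuracy(model, {"x": p}, alpha=0.05)
        counts = table.table["label"].value_counts().to_dict()
        assert counts == {"TP": 3, "TN": 2, "FN": 1}
        assert table.per_dataset_accuracy["x"] == pytest.approx(5 / 6)

    def test_all_significant_all_edges_is_perfect(self):
        model = self._model(
            [(s, t) for s in range(3) for t in range(3) if s != t]
        )
        p = np.full((3, 3), 0.001)
        table = validation_accuracy(model, {"x": p})
        assert table.per_dataset_accuracy["x"] == 1.0

    def test_any_dataset_combination(self):
        # pair (0,1): FN in dataset 1, TP in dataset 2 -> counted correct
        model = self._model([(0, 1)])
        p1 = np.ones((3, 3))
        p2 = np.ones((3, 3))
        p2[0, 1] = 0.01
        table = validation_accuracy(model, {"one": p1, "two": p2})
        assert table.per_dataset_accuracy["one"] == pytest.approx(5 / 6)
        assert table.per_dataset_accuracy["two"] == 1.0
        assert table.combined_accuracy == 1.0

    def test_within_cluster_reported_separately(self):
        model = self._model([])
        p = np.ones((3, 3))
        p[1, 1] = 0.002
        table = validation_accuracy(model, {"x": p})
        within = table.within_cluster
        assert len(within) == 3
        assert within.loc[within.cluster == 2, "p_value"].item() == 0.002
        assert "FP" not in table.table.label.values  # diagonal not labelled

    def test_cluster_count_mismatch(self):
        model = self._model([])
        with pytest.raises(ValueError):
            validation_accuracy(model, {"x": np.ones((4, 4))})

    def test_orientation_matches_counts(self):
        """A directed interaction a->c (cluster 1 -> 2) validates the model
        edge 'cluster 1 regulates cluster 2' and not its reverse."""
        a = np.zeros((2, 2))
        a[1, 0] = 0.7  # target cluster 2 regulated by cluster 1
        np.fill_diagonal(a, -0.1)
        model = InfluenceModel(a, np.ones(2, dtype=int))
        p = np.ones((2, 2))
        p[0, 1] = 0.01  # source cluster 1 -> target cluster 2 significant
        table = validation_accuracy(model, {"x": p})
        row = table.table[(table.table.source == 1) & (table.table.target == 2)]
        assert row.label.item() == "TP"
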