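import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from oracles import hypergeom_upper_enum
from drem2.enrichment import (
    GoResult,
    build_split_table,
    count_significant_terms,
    export_split_genesets,
    flag_tf_direction,
    go_enrich,
    hypergeom_upper,
    significant_terms,
)
from drem2.io_formats import GoAnnotation
from drem2.learning import PathAssignment
from drem2.model_core import DremModel, SplitClassifier, StateNode


class TestHypergeomUpper:
    def test_zero_successes_always_certain(self):
        assert hypergeom_upper(0, 5, 3, 10) == 1.0

    def test_all_draws_hit_small_case(self):
        # C(5,5)*C(5,0)/C(10,5) = 1/252
        assert hypergeom_upper(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_exhaustive_enumeration_small_populations(self):
        for N in (1, 4, 8, 11):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = float(hypergeom_upper_enum(k, K, n, N))
                        assert hypergeom_upper(k, K, n, N) == pytest.approx(
                            expected, abs=1e-12
                        )

    @given(
        st.integers(min_value=20, max_value=200),
        st.data(),
    )
    def test_agrees_with_scipy_survival_function(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_upper(k, K, n, N) == pytest.approx(
            float(scipy_hypergeom.sf(k - 1, N, K, n)), rel=1e-9, abs=1e-300
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(4, 3, 3, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(0, 11, 3, 10)


def two_split_model(n_tfs=2):
    """t=0 root -> split into two 2-state chains (split time 1)."""
    a = StateNode(1, 1.0, 1.0, [StateNode(2, 1.0, 1.0)])
    b = StateNode(1, -1.0, 1.0, [StateNode(2, -1.0, 1.0)])
    root = StateNode(0, 0.0, 1.0, [a, b])
    root.classifier = SplitClassifier(np.zeros((2, n_tfs)), np.zeros(2))
    return DremModel(
        root=root, tf_ids=[f"TF{i}" for i in range(n_tfs)], n_times=3
    )


class TestBuildSplitTable:
    def assignment(self, n_genes, first_path):
        leaves = np.array([0] * first_path + [1] * (n_genes - first_path))
        genes = [f"g{i}" for i in range(n_genes)]
        return PathAssignment(leaves, 2, genes)

    def test_tf_with_no_targets_scores_one_everywhere(self):
        model = two_split_model()
        assign = self.assignment(30, 10)
        feats = {1: np.zeros((2, 30)), 2: np.zeros((2, 30))}
        tables = build_split_table(model, assign, feats)
        assert all(r.p_conditional == 1.0 for r in tables[0].rows)

    def test_concentrated_targets_match_direct_formula(self):
        # 100 genes enter; top path has 20; TF A's 10 targets all on top path
        model = two_split_model()
        assign = self.assignment(100, 20)
        feats = np.zeros((2, 100))
        feats[0, :10] = 1.0  # TF0 targets the first 10 genes (all on path 0)
        tables = build_split_table(model, assign, {1: feats, 2: feats})
        row = next(
            r for r in tables[0].rows if r.tf_id == "TF0" and r.path_index == 0
        )
        assert row.k_path == 10 and row.n_path == 20
        assert row.k_split == 10 and row.n_split == 100
        assert row.p_conditional == pytest.approx(
            hypergeom_upper(10, 10, 20, 100), rel=1e-12
        )

    def test_display_threshold_controls_annotation(self):
        model = two_split_model()
        assign = self.assignment(100, 20)
        feats = np.zeros((2, 100))
        feats[0, :10] = 1.0
        tables = build_split_table(
            model, assign, {1: feats, 2: feats}, display_threshold=5e-5
        )
        # p = hypergeom_upper(10,10,20,100) ~ 1.8e-8 <= 5e-5
        assert tables[0].annotated_tfs == ["TF0"]
        strict = build_split_table(
            model, assign, {1: feats, 2: feats}, display_threshold=1e-12
        )
        assert strict[0].annotated_tfs == []

    def test_path_counts_partition_the_split(self):
        model = two_split_model()
        assign = self.assignment(60, 25)
        feats = {t: np.zeros((2, 60)) for t in (1, 2)}
        tab = build_split_table(model, assign, feats)[0]
        for tf in ("TF0", "TF1"):
            n_paths = [r.n_path for r in tab.rows if r.tf_id == tf]
            assert sum(n_paths) == tab.n_split

    def test_p_conditional_invariant_under_path_relabeling(self, rng):
        model = two_split_model()
        n = 50
        leaves = rng.integers(0, 2, n)
        feats = {t: (rng.random((2, n)) < 0.3).astype(float) for t in (1, 2)}
        a1 = PathAssignment(leaves, 2, [f"g{i}" for i in range(n)])
        a2 = PathAssignment(1 - leaves, 2, [f"g{i}" for i in range(n)])
        t1 = build_split_table(model, a1, feats)[0]
        t2 = build_split_table(model, a2, feats)[0]
        p1 = {(r.tf_id, r.path_index): r.p_conditional for r in t1.rows}
        p2 = {(r.tf_id, 1 - r.path_index): r.p_conditional for r in t2.rows}
        assert p1 == pytest.approx(p2)


def toy_annotation():
    """3 terms, 10 genes; term X covers exactly genes g0..g4."""
    genes = [f"g{i}" for i in range(10)]
    gene_terms = {}
    for i, g in enumerate(genes):
        terms = set()
        if i < 5:
            terms.add("GO:X")
        if i % 2 == 0:
            terms.add("GO:Y")
        terms.add("GO:ROOT")
        gene_terms[g] = frozenset(terms)
    return GoAnnotation(
        ["GO:ROOT", "GO:X", "GO:Y"],
        {"GO:ROOT": "root", "GO:X": "x", "GO:Y": "y"},
        {"GO:X": {"GO:ROOT"}, "GO:Y": {"GO:ROOT"}, "GO:ROOT": set()},
        gene_terms,
    )


class TestGoEnrich:
    def test_path_equal_to_background_cannot_be_enriched(self):
        ann = toy_annotation()
        genes = [f"g{i}" for i in range(10)]
        results = go_enrich(genes, genes, ann)
        assert all(r.p_raw == 1.0 for r in results)

    def test_fully_covering_term_hand_computation(self):
        ann = toy_annotation()
        path = [f"g{i}" for i in range(5)]
        background = [f"g{i}" for i in range(10)]
        results = {r.term_id: r for r in go_enrich(path, background, ann)}
        assert results["GO:X"].p_raw == pytest.approx(1 / 252, rel=1e-12)
        # three terms tested (ROOT, X, Y all annotate >= 1 path gene)
        assert results["GO:X"].p_corrected == pytest.approx(3 / 252, rel=1e-12)

    def test_term_without_path_genes_not_tested(self):
        ann = toy_annotation()
        path = ["g1", "g3"]  # odd genes: no GO:Y
        results = go_enrich(path, [f"g{i}" for i in range(10)], ann)
        assert "GO:Y" not in {r.term_id for r in results}

    def test_bonferroni_never_decreases_p(self):
        ann = toy_annotation()
        results = go_enrich(["g0", "g1"], [f"g{i}" for i in range(10)], ann)
        assert all(r.p_corrected >= r.p_raw for r in results)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            go_enrich([], ["g0"], toy_annotation())

    def test_significant_sets_monotone_in_threshold(self):
        results = [
            GoResult(0, f"T{i}", "", 1, 5, 1, 10, p, p) for i, p in
            enumerate([0.001, 0.01, 0.04, 0.2])
        ]
        s1 = significant_terms(results, alpha=0.05)
        s2 = significant_terms(results, alpha=0.02)
        assert s2 <= s1


class TestCountSignificantTerms:
    def make(self, terms):
        return [GoResult(0, t, "", 1, 2, 1, 4, 0.001, 0.001) for t in terms]

    def test_identical_models_show_no_differences(self):
        rep = count_significant_terms(
            {"a": self.make(["T1", "T2"]), "b": self.make(["T1", "T2"])}
        )
        assert rep["counts"] == {"a": 2, "b": 2}
        pair = rep["pairwise"]["a vs b"]
        assert pair["shared"] == 2 and pair["only a"] == [] and pair["only b"] == []

    def test_one_term_difference_detected(self):
        rep = count_significant_terms(
            {"a": self.make(["T1"]), "b": self.make(["T1", "T2"])}
        )
        assert rep["pairwise"]["a vs b"]["only b"] == ["T2"]


class TestFlagTfDirection:
    def split(self):
        return two_split_model().splits()[0]

    def test_upregulated(self):
        f = flag_tf_direction(
            "TF0", self.split(), {"TF0": np.array([0.0, 1.2, 0.0])}, "t1.s0"
        )
        assert f.direction == "up"

    def test_downregulated(self):
        f = flag_tf_direction(
            "TF0", self.split(), {"TF0": np.array([0.0, -0.7, 0.0])}, "t1.s0"
        )
        assert f.direction == "down"

    def test_absent_tf_is_none(self):
        f = flag_tf_direction("TFq", self.split(), {}, "t1.s0")
        assert f.direction == "none"


class TestExportGenesets:
    def test_binary_split_writes_two_disjoint_contrasts(self, tmp_path):
        model = two_split_model()
        n = 20
        assign = PathAssignment(
            np.array([0] * 8 + [1] * 12), 2, [f"g{i}" for i in range(n)]
        )
        pairs = export_split_genesets(model, assign, "t0.s0", tmp_path)
        assert len(pairs) == 2
        fg = set((tmp_path / "t0.s0.path0.foreground.txt").read_text().split())
        bg = set((tmp_path / "t0.s0.path0.background.txt").read_text().split())
        assert fg.isdisjoint(bg)
        assert fg | bg == {f"g{i}" for i in range(n)}
        assert len(fg) == 8

    def test_ternary_split_writes_three_contrasts(self, tmp_path):
        chains = [
            StateNode(1, m, 1.0, [StateNode(2, m, 1.0)]) for m in (-1.0, 0.0, 1.0)
        ]
        root = StateNode(0, 0.0, 1.0, chains)
        root.classifier = SplitClassifier(np.zeros((3, 1)), np.zeros(3))
        model = DremModel(root=root, tf_ids=["TF0"], n_times=3)
        assign = PathAssignment(
            np.array([0, 1, 2] * 5), 3, [f"g{i}" for i in range(15)]
        )
        pairs = export_split_genesets(model, assign, "t0.s0", tmp_path)
        assert len(pairs) == 3

    def test_unknown_split_id_rejected(self, tmp_path):
        model = two_split_model()
        assign = PathAssignment(np.zeros(4, dtype=int), 2, list("abcd"))
        with pytest.raises(KeyError):
            export_split_genesets(model, assign, "t9.s9", tmp_path)
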