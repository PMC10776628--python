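"""Feature computations against hand-rolled and brute-force oracles."""

import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semnav.features import (
    FEATURE_COLUMNS,
    ConceptFeatures,
    aggregate_participant,
    build_feature_matrix,
    granularity_score,
    norm_feature_means,
    property_distance_flow,
    relevance_distinctiveness,
    semantic_variability,
)
from semnav.ingest import ContentToken, PropertyRecord
from semnav.lexicon import Taxonomy, VectorLexicon


def _rec(concept, idx, lemmas, pid="p1", pos="noun"):
    tokens = tuple(ContentToken(surface=l, lemma=l, pos=pos) for l in lemmas)
    return PropertyRecord(pid, "PD", concept, idx, " ".join(lemmas), "valid",
                          tokens=tokens, pretagged=True)


class TestNormMeans:
    def test_arithmetic_mean_over_pooled_lemmas(self, tiny_norms):
        recs = [_rec("sol", 1, ["ala"]), _rec("sol", 2, ["sol"])]
        out = norm_feature_means(recs, tiny_norms)
        assert out["concreteness"] == pytest.approx((4.0 + 6.1) / 2)

    def test_single_lemma_verbatim(self, tiny_norms):
        out = norm_feature_means([_rec("sol", 1, ["sol"])], tiny_norms)
        assert out["imageability"] == pytest.approx(6.5)
        assert out["length"] == pytest.approx(3)

    def test_all_oov_undefined(self, tiny_norms):
        out = norm_feature_means([_rec("sol", 1, ["zzz"])], tiny_norms)
        assert all(math.isnan(v) for v in out.values())


class TestSemanticVariability:
    def test_identical_vectors_zero_variance(self, tiny_vectors):
        assert semantic_variability([["ex", "exb", "ex"]], tiny_vectors) == pytest.approx(0.0)

    def test_two_tokens_undefined(self, tiny_vectors):
        assert math.isnan(semantic_variability([["ex", "ey"]], tiny_vectors))

    def test_hand_computed_cosine_oracle(self, tiny_vectors):
        # distances (0, 1) -> sample variance 0.5
        assert semantic_variability([["ex", "exb", "ey"]], tiny_vectors) == pytest.approx(0.5)

    def test_oov_tokens_dropped_before_pairing(self, tiny_vectors):
        with_oov = semantic_variability([["ex", "zzz", "exb", "ey"]], tiny_vectors)
        assert with_oov == pytest.approx(0.5)

    def test_adjacency_per_property_resets_at_boundaries(self, tiny_vectors):
        # concat sees the cross-boundary (ex->ey) distance; per_property does not
        props = [["ex", "exb"], ["ey", "ey"]]
        concat = semantic_variability(props, tiny_vectors, adjacency="concat")
        per_prop = semantic_variability(props, tiny_vectors, adjacency="per_property")
        assert concat == pytest.approx(np.var([0.0, 1.0, 0.0], ddof=1))
        assert per_prop == pytest.approx(0.0)


class TestPropertyDistanceFlow:
    def test_all_properties_at_concept_zero_variance(self, tiny_vectors):
        assert property_distance_flow("ex", [["exb"], ["ex"]], tiny_vectors) == pytest.approx(0.0)

    def test_single_usable_property_undefined(self, tiny_vectors):
        assert math.isnan(property_distance_flow("ex", [["ey"], ["zzz"]], tiny_vectors))

    def test_hand_computed_cosine_oracle(self, tiny_vectors):
        # property vectors (1,0) and (0,1) vs concept (1,0): distances (0,1)
        out = property_distance_flow("ex", [["exb"], ["ey"]], tiny_vectors)
        assert out == pytest.approx(0.5)

    def test_oov_concept_undefined(self, tiny_vectors):
        assert math.isnan(property_distance_flow("zzz", [["ex"], ["ey"]], tiny_vectors))


class TestRelevanceDistinctiveness:
    def test_shared_by_all_concepts_gives_zero(self):
        counts = pd.DataFrame({"p": [5] * 10}, index=[f"c{i}" for i in range(10)])
        table = relevance_distinctiveness(counts)
        assert table.k["p"].tolist() == [0.0] * 10
        assert table.distinctiveness["p"] == pytest.approx(0.0)

    def test_zero_frequency_gives_zero(self):
        counts = pd.DataFrame({"p": [3, 0]}, index=["a", "b"])
        table = relevance_distinctiveness(counts)
        assert table.k.at["b", "p"] == 0.0

    def test_high_precision_oracle(self):
        counts = pd.DataFrame(
            {"p": [3, 2] + [0] * 8}, index=[f"c{i}" for i in range(10)]
        )
        table = relevance_distinctiveness(counts)
        assert table.k.at["c0", "p"] == pytest.approx(3 * math.log(5), abs=1e-12)
        assert table.concept_count["p"] == 2

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            relevance_distinctiveness(pd.DataFrame({"p": [-1, 2]}, index=["a", "b"]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_on_random_tables(self, data):
        n_c = data.draw(st.integers(2, 6))
        n_p = data.draw(st.integers(1, 5))
        cells = data.draw(
            st.lists(st.lists(st.integers(0, 4), min_size=n_p, max_size=n_p),
                     min_size=n_c, max_size=n_c)
        )
        counts = pd.DataFrame(cells, index=[f"c{i}" for i in range(n_c)],
                              columns=[f"p{j}" for j in range(n_p)])
        if (counts.sum(axis=0) == 0).all():
            return
        table = relevance_distinctiveness(counts)
        for j in table.x.columns:
            i_j = sum(1 for i in counts.index if counts.at[i, j] > 0)
            assert table.concept_count[j] == i_j
            for i in counts.index:
                expected = counts.at[i, j] * math.log(n_c / i_j) if counts.at[i, j] > 0 else 0.0
                assert table.k.at[i, j] == pytest.approx(expected, abs=1e-10)
                assert table.k.at[i, j] >= -1e-12
            assert 0 <= table.distinctiveness[j] <= math.log(n_c) + 1e-12


def _bfs_depth(edges, start, root="entity"):
    """Independent BFS shortest-path oracle over child->parent edges."""
    adj = {}
    for child, parent in edges:
        adj.setdefault(child, []).append(parent)
    seen = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if node == root:
            return seen[node]
        for nxt in adj.get(node, []):
            if nxt not in seen:
                seen[nxt] = seen[node] + 1
                queue.append(nxt)
    return None


class TestGranularity:
    def _chain_taxonomy(self):
        edges = [("animal", "entity"), ("dog", "animal"), ("bulldog", "dog")]
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return Taxonomy(graph=g, mapping={"bulldog": ("bulldog",), "animal": ("animal",),
                                          "entity": ("entity",)}), edges

    def test_root_depth_zero(self):
        tax, _ = self._chain_taxonomy()
        assert granularity_score(["entity"], tax) == pytest.approx(0.0)

    def test_chain_depth_three(self):
        tax, edges = self._chain_taxonomy()
        assert granularity_score(["bulldog"], tax) == pytest.approx(3.0)
        assert _bfs_depth(edges, "bulldog") == 3

    def test_min_depth_under_polysemy(self):
        g = nx.DiGraph()
        g.add_edges_from([("a", "entity"), ("b", "a"), ("c", "b"), ("d", "c"),
                          ("x", "entity"), ("y", "x")])
        tax = Taxonomy(graph=g, mapping={"word": ("d", "y")})
        assert granularity_score(["word"], tax, polysemy="min") == pytest.approx(2.0)

    def test_unmapped_nouns_undefined(self):
        tax, _ = self._chain_taxonomy()
        assert math.isnan(granularity_score(["zzz"], tax))

    def test_random_taxonomies_match_bfs_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 25))
            nodes = ["entity"] + [f"n{i}" for i in range(n)]
            edges = []
            for i, node in enumerate(nodes[1:], start=1):
                n_parents = 1 + int(rng.random() < 0.3)  # DAG, possibly multi-parent
                parents = rng.choice(i, size=min(n_parents, i), replace=False)
                for p in parents:
                    edges.append((node, nodes[p]))
            g = nx.DiGraph()
            g.add_edges_from(edges)
            mapping = {f"w{i}": (nodes[int(rng.integers(0, len(nodes)))],) for i in range(10)}
            tax = Taxonomy(graph=g, mapping=mapping)
            for word, (node,) in mapping.items():
                assert tax.word_depth(word) == _bfs_depth(edges, node)


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_cosine_features_invariant_to_orthogonal_transform_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        dim, n = 5, 6
        vecs = rng.standard_normal((n, dim))
        q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
        scales = rng.uniform(0.5, 3.0, size=n)
        words = [f"w{i}" for i in range(n)]
        base = VectorLexicon({w: v for w, v in zip(words, vecs)}, dim)
        moved = VectorLexicon(
            {w: s * (q @ v) for w, v, s in zip(words, vecs, scales)}, dim
        )
        sv_a = semantic_variability([words], base)
        sv_b = semantic_variability([words], moved)
        assert sv_a == pytest.approx(sv_b, abs=1e-8)
        pdf_a = property_distance_flow(words[0], [[w] for w in words[1:]], base)
        pdf_b = property_distance_flow(words[0], [[w] for w in words[1:]], moved)
        # per-vector rescaling moves property *mean* vectors; single-word
        # properties keep the exact invariance
        assert pdf_a == pytest.approx(pdf_b, abs=1e-8)


class TestAggregation:
    def _cf(self, **kw):
        base = {c: math.nan for c in FEATURE_COLUMNS}
        base.update(kw)
        return ConceptFeatures(participant_id="p", concept="c", **base)

    def test_single_concept_identity(self):
        cf = self._cf(concreteness=4.2, semantic_variability=0.1)
        row = aggregate_participant([cf])
        assert row["concreteness"] == pytest.approx(4.2)
        assert math.isnan(row["granularity"])

    def test_mean_and_skip_missing(self):
        row = aggregate_participant(
            [self._cf(concreteness=2.0, granularity=math.nan),
             self._cf(concreteness=4.0, granularity=5.0)]
        )
        assert row["concreteness"] == pytest.approx(3.0)
        assert row["granularity"] == pytest.approx(5.0)


def test_feature_extraction_is_pure(default_dataset):
    """Identical inputs give bitwise-identical matrices."""
    from semnav.ingest import filter_valid

    ds = default_dataset
    retained, _ = filter_valid(ds.records)
    m1, _, _ = build_feature_matrix(retained, ds.norms, ds.vectors, ds.taxonomy)
    m2, _, _ = build_feature_matrix(retained, ds.norms, ds.vectors, ds.taxonomy)
    pd.testing.assert_frame_equal(m1, m2)
    assert list(m1.columns[-10:]) == list(FEATURE_COLUMNS)
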