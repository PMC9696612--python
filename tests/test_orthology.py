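"""Local alignment, reciprocal best hits, Markov clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlrkit.orthology import (
    BLOSUM62,
    SimilarityEdge,
    all_vs_all,
    assign_reference,
    build_orthology_graph,
    count_paralogs,
    local_align,
    mcl_cluster,
    reciprocal_best_hits,
)
from nlrkit.scoring import AA_INDEX
from nlrkit.synthdata import random_protein


def naive_sw_score(a, b, gap_open=11, gap_extend=1):
    """Textbook quadratic-space affine Smith–Waterman (score only); a gap
    of length L costs open + L*extend."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            s = BLOSUM62[AA_INDEX[a[i - 1]], AA_INDEX[b[j - 1]]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_identical_sequences_score_diagonal_sum(self):
        seq = "MKWVFDECARHILN"
        expected = sum(BLOSUM62[AA_INDEX[c], AA_INDEX[c]] for c in seq)
        res = local_align(seq, seq)
        assert res.score == expected
        assert (res.a_start, res.a_end) == (1, len(seq))

    def test_all_negative_cross_scores_give_empty_alignment(self):
        # glycine runs vs tryptophan runs: BLOSUM62(G, W) = -2 < 0
        res = local_align("GGGGGG", "WWWWWW")
        assert res.score == 0
        assert res.a_end < res.a_start  # empty interval

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MKW")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_matches_textbook_dp_reference(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(5, 40)))
        b = random_protein(rng, int(rng.integers(5, 40)))
        res = local_align(a, b)
        assert res.score == naive_sw_score(a, b)

    def test_reported_interval_reproduces_the_score(self):
        rng = np.random.default_rng(11)
        core = random_protein(rng, 30)
        a = random_protein(rng, 20) + core + random_protein(rng, 15)
        b = random_protein(rng, 5) + core + random_protein(rng, 40)
        res = local_align(a, b)
        sub_a = a[res.a_start - 1 : res.a_end]
        sub_b = b[res.b_start - 1 : res.b_end]
        assert local_align(sub_a, sub_b).score == res.score


class TestAllVsAll:
    def test_identical_proteomes_connect_every_gene(self):
        rng = np.random.default_rng(2)
        prots = {f"g{i}": random_protein(rng, 120) for i in range(4)}
        cohort = {
            "spA": {f"A_{k}": v for k, v in prots.items()},
            "spB": {f"B_{k}": v for k, v in prots.items()},
        }
        edges = all_vs_all(cohort, evalue_max=1e-5)
        pairs = {(e.query_id, e.subject_id) for e in edges}
        for k in prots:
            assert (f"A_{k}", f"B_{k}") in pairs or (f"B_{k}", f"A_{k}") in pairs

    def test_zero_threshold_gives_no_edges(self):
        rng = np.random.default_rng(3)
        cohort = {"spA": {"a": random_protein(rng, 100)},
                  "spB": {"b": random_protein(rng, 100)}}
        assert all_vs_all(cohort, evalue_max=0.0) == []


def _edge(q, s, score, ev=None):
    return SimilarityEdge(q, s, score, 10.0 ** (-score / 10) if ev is None else ev)


class TestRBH:
    def test_single_qualifying_pair_is_rbh(self):
        species = {"a1": "A", "b1": "B"}
        rbh = reciprocal_best_hits([_edge("a1", "b1", 100)], species)
        assert rbh == [("a1", "b1")]

    def test_one_sided_best_hit_is_not_rbh(self):
        species = {"a1": "A", "a2": "A", "b1": "B"}
        edges = [_edge("a1", "b1", 50), _edge("a2", "b1", 90)]
        rbh = reciprocal_best_hits(edges, species)
        assert rbh == [("a2", "b1")]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        species = {f"a{i}": "A" for i in range(na)} | {f"b{j}": "B" for j in range(nb)}
        scores = rng.integers(10, 1000, size=(na, nb))
        edges = [
            _edge(f"a{i}", f"b{j}", int(scores[i, j]))
            for i in range(na) for j in range(nb)
        ]
        expected = set()
        for i in range(na):
            j = int(np.argmax(scores[i]))  # ties: first index = lex smallest id
            if int(np.argmax(scores[:, j])) == i:
                expected.add((f"a{i}", f"b{j}"))
        assert set(reciprocal_best_hits(edges, species)) == expected

    def test_symmetric_under_input_permutation(self):
        rng = np.random.default_rng(9)
        species = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        edges = [
            _edge(f"a{i}", f"b{j}", int(rng.integers(10, 500)))
            for i in range(4) for j in range(4)
        ]
        shuffled = list(edges)
        rng.shuffle(shuffled)
        flipped = [SimilarityEdge(e.subject_id, e.query_id, e.score, e.evalue)
                   for e in shuffled]
        assert reciprocal_best_hits(edges, species) == reciprocal_best_hits(flipped, species)


def reference_mcl(nodes, edges, inflation=1.5, eps=1e-5, iters=200):
    """Independent dense MCL iteration (no per-component decomposition)."""
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, w in edges:
        W[idx[u], idx[v]] = W[idx[v], idx[u]] = w
    loops = W.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(W, loops)
    M = W / W.sum(0, keepdims=True)
    for _ in range(iters):
        M = np.linalg.matrix_power(M, 2) ** inflation
        M[M < eps] = 0
        s = M.sum(0, keepdims=True)
        s[s == 0] = 1
        M = M / s
    # connected components of the limit's nonzero pattern
    adj = (M + M.T) > eps
    seen, parts = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(np.nonzero(adj[k])[0].tolist())
        seen |= comp
        parts.append(frozenset(nodes[j] for j in comp))
    return set(parts)


def partition_of(groups):
    return {frozenset(og.member_ids) for og in groups}


class TestMCL:
    def test_disconnected_triangles_stay_separate(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        species = {g: "S" for g in "abcxyz"}
        groups = mcl_cluster(edges, species)
        assert partition_of(groups) == {frozenset("abc"), frozenset("xyz")}

    def test_single_edge_graph_is_one_group(self):
        groups = mcl_cluster([("a", "b", 5.0)], {"a": "S", "b": "T"})
        assert partition_of(groups) == {frozenset("ab")}

    def test_barbell_splits_at_weak_bridge(self):
        """Two 4-cliques joined by one weak edge (0.1 vs 1.0) separate at
        inflation 1.5; checked against an independent dense MCL iteration."""
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        edges = []
        for side in (left, right):
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append((side[i], side[j], 1.0))
        edges.append(("l0", "r0", 0.1))
        species = {g: "S" for g in left + right}
        groups = mcl_cluster(edges, species, inflation=1.5)
        assert partition_of(groups) == {frozenset(left), frozenset(right)}
        assert partition_of(groups) == reference_mcl(sorted(species), edges)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_output_is_always_a_partition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        nodes = [f"n{i}" for i in range(n)]
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    edges.append((nodes[i], nodes[j], float(rng.uniform(0.1, 10))))
        species = {g: "S" for g in nodes}
        groups = mcl_cluster(edges, species, nodes=nodes)
        seen = [g for og in groups for g in og.member_ids]
        assert sorted(seen) == sorted(nodes)  # every node exactly once

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster([("a", "b", 1.0)], {"a": "S", "b": "S"}, inflation=1.0)


class TestReferenceAssignment:
    def test_reference_identical_to_member_lands_in_its_group(self):
        rng = np.random.default_rng(21)
        seqs = {"a1": random_protein(rng, 150), "a2": random_protein(rng, 150)}
        species = {"a1": "A", "a2": "A"}
        groups = mcl_cluster([], species, nodes=["a1", "a2"])
        groups, unassigned = assign_reference({"RefX": seqs["a2"]}, groups, seqs)
        labeled = {og.group_id: og.reference_labels for og in groups}
        target = next(og for og in groups if "a2" in og.member_ids)
        assert target.reference_labels == ["RefX"]
        assert unassigned == []

    def test_reference_without_qualifying_hit_reported_unassigned(self):
        rng = np.random.default_rng(22)
        seqs = {"a1": random_protein(rng, 150)}
        groups = mcl_cluster([], {"a1": "A"}, nodes=["a1"])
        _, unassigned = assign_reference({"RefY": random_protein(rng, 60)}, groups, seqs)
        assert unassigned == ["RefY"]


class TestParalogs:
    def test_group_with_three_same_species_genes_counts_three(self):
        groups = mcl_cluster(
            [("a1", "a2", 9.0), ("a2", "a3", 9.0)],
            {"a1": "A", "a2": "A", "a3": "A"},
        )
        assert count_paralogs(groups) == {"A": 3}

    def test_all_singletons_count_zero(self):
        groups = mcl_cluster([], {"a1": "A", "b1": "B"}, nodes=["a1", "b1"])
        assert count_paralogs(groups) == {}


class TestGraphConstruction:
    def test_recent_paralog_rule_drops_weak_within_species_edges(self):
        species = {"a1": "A", "a2": "A", "b1": "B"}
        edges = [
            _edge("a1", "b1", 200, ev=1e-40),
            _edge("a2", "b1", 200, ev=1e-40),
            _edge("a1", "a2", 100, ev=1e-20),  # weaker than both cross hits
        ]
        graph = build_orthology_graph(edges, species, inparalog_mode="recent")
        assert all({u, v} != {"a1", "a2"} for u, v, _ in graph)
        graph2 = build_orthology_graph(edges, species, inparalog_mode="threshold")
        assert any({u, v} == {"a1", "a2"} for u, v, _ in graph2)


class TestOutputs:
    def test_tsv_and_summary_round_trip(self, tmp_path):
        groups = mcl_cluster(
            [("a1", "a2", 9.0), ("a1", "b1", 9.0)],
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        groups[0].reference_labels.append("RefZ")
        orthology = __import__("nlrkit.orthology", fromlist=["x"])
        orthology.write_orthogroups_tsv(tmp_path / "og.tsv", groups)
        orthology.write_edges_tsv(
            tmp_path / "edges.tsv", [_edge("a1", "b1", 42)]
        )
        orthology.write_summary_json(tmp_path / "summary.json", groups)
        lines = (tmp_path / "og.tsv").read_text().splitlines()
        assert lines[0] == "group_id\tgene_id\tspecies\treference_labels"
        assert len(lines) == 4  # header + 3 genes
        import json

        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["n_genes"] == 3
        assert summary["paralogs_per_species"] == {"A": 2}
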