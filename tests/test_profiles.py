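"""Correlations, hierarchical grouping and family summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from nlrkit.profiles import family_stats, hier_cluster, pearson, render_report


class TestPearson:
    def test_proportional_vectors_give_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x) == pytest.approx(1.0, abs=1e-15)

    def test_anti_proportional_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, -x) == pytest.approx(-1.0, abs=1e-15)

    def test_hand_computed_value(self):
        # x=(1,2,3,4), y=(1,3,2,5): sum dx*dy = 5.5, sum dx^2 = 5,
        # sum dy^2 = 8.75 (hand arithmetic)
        x, y = [1, 2, 3, 4], [1, 3, 2, 5]
        expected = 5.5 / np.sqrt(5 * 8.75)
        assert pearson(x, y) == pytest.approx(expected, abs=1e-15)

    def test_matches_scipy_to_1e12(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            assert pearson(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


def brute_force_linkage(matrix: pd.DataFrame, metric="jaccard", method="average"):
    """Exhaustive agglomerative merge sequence on a tiny binary matrix."""

    def jaccard(u, v):
        both = np.logical_and(u, v).sum()
        either = np.logical_or(u, v).sum()
        return 0.0 if either == 0 else 1 - both / either

    clusters = {i: [i] for i in range(matrix.shape[0])}
    data = matrix.to_numpy(dtype=bool)
    d = {
        (i, j): jaccard(data[i], data[j])
        for i, j in itertools.combinations(range(len(data)), 2)
    }
    merges = []
    next_label = len(data)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            pair_d = [d[tuple(sorted((i, j)))] for i in clusters[a] for j in clusters[b]]
            dist = np.mean(pair_d) if method == "average" else max(pair_d)
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        merges.append((dist, frozenset(clusters[a] + clusters[b])))
        clusters[next_label] = clusters.pop(a) + clusters.pop(b)
        next_label += 1
    return merges


class TestHierCluster:
    def test_identical_rows_merge_at_height_zero(self):
        mat = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]],
                           index=["a", "b", "c"], columns=["M1", "M2", "M3"])
        dend, _ = hier_cluster(mat)
        assert dend.linkage_matrix[0, 2] == 0.0

    def test_disjoint_motif_sets_are_jaccard_distance_one(self):
        mat = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        dend, _ = hier_cluster(mat)
        assert dend.linkage_matrix[-1, 2] == pytest.approx(1.0)

    def test_toy_matrix_matches_bruteforce_linkage(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.integers(0, 2, size=(6, 5)),
                           index=list("abcdef"))
        dend, _ = hier_cluster(mat, distance="jaccard", linkage_method="average")
        expected = brute_force_linkage(mat)
        got_heights = dend.linkage_matrix[:, 2]
        assert np.allclose(got_heights, [m[0] for m in expected])

    def test_cut_produces_requested_group_count(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.integers(0, 2, size=(10, 6)),
                           index=[f"g{i}" for i in range(10)])
        dend, groups = hier_cluster(mat, k=3)
        assert len(set(groups.values())) == 3
        assert set(groups) == set(mat.index)

    def test_k_larger_than_rows_rejected(self):
        mat = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        with pytest.raises(ValueError):
            hier_cluster(mat, k=5)

    def test_newick_covers_all_leaves(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.integers(0, 2, size=(5, 4)),
                           index=[f"g{i}" for i in range(5)])
        dend, _ = hier_cluster(mat)
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for label in mat.index:
            assert label in nwk

    def test_zero_noise_cohort_groups_by_class(self, clean_cohort):
        """With noise-free planted architectures, presence-pattern clustering
        reproduces the class partition exactly (ARI = 1)."""
        from sklearn.metrics import adjusted_rand_score

        from nlrkit import pipeline

        res = pipeline.run_pipeline(clean_cohort)
        mat = res["presence_matrix"]
        truth = clean_cohort.truth
        n_classes = len({truth.true_class[g] for g in mat.index})
        dend, groups = hier_cluster(mat, k=n_classes)
        ari = adjusted_rand_score(
            [truth.true_class[g] for g in mat.index],
            [groups[g] for g in mat.index],
        )
        assert ari == pytest.approx(1.0)


class TestFamilyStats:
    def test_mean_and_range_formatting(self):
        counts = pd.DataFrame(
            {"orthogroups": [20, 25, 27]}, index=["s1", "s2", "s3"]
        )
        out = family_stats(counts, {"s1": "Fam", "s2": "Fam", "s3": "Fam"})
        assert out.loc["Fam", "orthogroups"] == "24 (20–27)"

    def test_single_genome_collapses_range(self):
        counts = pd.DataFrame({"clusters": [7]}, index=["s1"])
        out = family_stats(counts, {"s1": "Solo"})
        assert out.loc["Solo", "clusters_mean"] == 7
        assert out.loc["Solo", "clusters_min"] == out.loc["Solo", "clusters_max"] == 7

    def test_unassigned_species_rejected(self):
        counts = pd.DataFrame({"clusters": [7, 8]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            family_stats(counts, {"s1": "Fam"})

    def test_cohort_totals_match_truth_tallies(self, clean_cohort):
        truth = clean_cohort.truth
        rows = {}
        for sp in clean_cohort.species:
            ids = [g for g in truth.true_class if truth.species_of[g] == sp]
            rows[sp] = {"nblrr": len(ids)}
        counts = pd.DataFrame.from_dict(rows, orient="index")
        grouping = {sp: "cladeA" for sp in clean_cohort.species}
        out = family_stats(counts, grouping)
        assert out.loc["cladeA", "nblrr_mean"] * len(rows) == pytest.approx(
            len(truth.true_class)
        )


class TestReport:
    def test_report_lists_missing_sections(self, tmp_path):
        path = render_report(tmp_path, {"cohort": {"n_species": 2}})
        import json

        report = json.loads(path.read_text())
        assert "motifs" in report["missing_sections"]
        assert "cohort" not in report["missing_sections"]

    def test_rerun_is_byte_identical(self, tmp_path):
        table = pd.DataFrame({"x": [1, 2]}, index=["a", "b"])
        p1 = render_report(tmp_path / "r1", {"cohort": {}}, tables={"t": table},
                          newick="(a:1,b:1);")
        p2 = render_report(tmp_path / "r2", {"cohort": {}}, tables={"t": table},
                          newick="(a:1,b:1);")
        assert p1.read_bytes() == p2.read_bytes()


class TestClusterParalogCorrelation:
    def test_cluster_counts_track_paralog_counts(self):
        """Tandem duplication both creates paralogs and seeds clusters, so
        per-species cluster counts correlate strongly with paralog counts
        across a cohort (the qualitative pattern behind the reported
        r = 0.76 on real genomes)."""
        from nlrkit import synthdata

        cfg = synthdata.CohortConfig(n_species=10, genes_per_species=400,
                                     nblrr_fraction=0.08, seed=17)
        cohort = synthdata.generate_cohort(cfg)
        truth = cohort.truth
        clusters, paralogs = [], []
        for sp in cohort.species:
            clusters.append(len(truth.true_clusters[sp]))
            by_group = {}
            for g in truth.true_class:
                if truth.species_of[g] == sp:
                    by_group.setdefault(truth.true_orthogroup[g], []).append(g)
            paralogs.append(sum(len(v) for v in by_group.values() if len(v) >= 2))
        assert pearson(clusters, paralogs) >= 0.7
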