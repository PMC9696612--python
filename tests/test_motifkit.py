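"""EM motif discovery, rescanning, lettering and presence matrices."""

import numpy as np
import pytest

from nlrkit.motifkit import (
    ArchitectureString,
    MotifModel,
    MotifOccurrence,
    conserved_and_specific,
    discover_motifs,
    name_occurrences,
    presence_matrix,
    scan_motifs,
)
from nlrkit.motifkit import _WindowIndex, _em_fit, _estimate_background
from nlrkit.scoring import AA_INDEX, encode
from nlrkit.synthdata import random_protein


def indicator_motif(consensus, motif_id="M1", p=0.9):
    pwm = np.full((len(consensus), 20), (1 - p) / 19)
    for j, aa in enumerate(consensus):
        pwm[j, AA_INDEX[aa]] = p
    return MotifModel(motif_id=motif_id, pwm=pwm)


class TestDiscovery:
    def test_planted_motif_recovered_exactly_at_zero_noise(self, motif_bench):
        seqs, consensi, _ = motif_bench(n_seqs=20, n_motifs=1, noise=0.0, seed=1)
        motifs = discover_motifs(seqs, n_motifs=1, width_range=(15, 15), seed=0)
        assert motifs[0].consensus == consensi["M1"]

    def test_second_motif_falls_below_significance_floor(self, motif_bench):
        seqs, _, _ = motif_bench(n_seqs=20, n_motifs=1, noise=0.0, seed=2)
        motifs = discover_motifs(seqs, n_motifs=2, width_range=(15, 15), seed=0)
        assert len(motifs) == 1

    def test_erasure_prevents_rediscovery(self, motif_bench):
        """After a motif is accepted its occurrences are erased, so a
        multi-motif run never returns the same consensus twice."""
        seqs, consensi, _ = motif_bench(n_seqs=20, n_motifs=4, noise=0.0, seed=3)
        motifs = discover_motifs(seqs, n_motifs=4, width_range=(15, 15), seed=0)
        found = [m.consensus for m in motifs]
        assert len(set(found)) == len(found)
        assert set(found) == set(consensi.values())

    def test_degenerate_single_sequence_full_width(self):
        seq = "MKWVFDECARHILNQS"
        motifs = discover_motifs([seq], n_motifs=1, width_range=(16, 16), seed=0)
        assert len(motifs) == 1
        # EM fixed point: columns are (pseudocount-smoothed) indicators
        assert motifs[0].consensus == seq

    def test_fixed_seed_is_deterministic(self, motif_bench):
        seqs, _, _ = motif_bench(n_seqs=15, n_motifs=3, noise=0.05, seed=4)
        a = discover_motifs(seqs, n_motifs=3, width_range=(15, 15), seed=5)
        b = discover_motifs(seqs, n_motifs=3, width_range=(15, 15), seed=5)
        assert len(a) == len(b)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.pwm, mb.pwm)

    def test_em_objective_is_nondecreasing(self, motif_bench):
        """The marginal likelihood EM optimizes must not decrease across
        iterations, for every start."""
        seqs, _, _ = motif_bench(n_seqs=12, n_motifs=2, noise=0.1, seed=6)
        encoded = [encode(s) for s in seqs.values()]
        win = _WindowIndex(encoded, 15)
        bg = _estimate_background(encoded)
        f = np.ones(win.n)
        rng = np.random.default_rng(0)
        for s in rng.choice(win.n, size=5, replace=False):
            for model in ("anr", "zoops"):
                *_, trace = _em_fit(win, f, win.X[int(s)], bg, len(seqs),
                                    model, 1e-6, 100)
                diffs = np.diff(np.array(trace))
                assert (diffs >= -1e-9).all()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs(["MKWVFDECAR"], model="oops")


class TestScan:
    def test_verbatim_consensus_found_at_minimal_p(self):
        rng = np.random.default_rng(8)
        cons = random_protein(rng, 12)
        motif = indicator_motif(cons)
        seq = random_protein(rng, 40) + cons + random_protein(rng, 40)
        occs = scan_motifs(seq, [motif], p_max=1e-4)
        assert any(o.start == 41 and o.end == 52 for o in occs)
        best = min(occs, key=lambda o: o.match_p)
        assert best.start == 41

    def test_tightening_p_max_shrinks_occurrences(self):
        rng = np.random.default_rng(9)
        cons = random_protein(rng, 10)
        motif = indicator_motif(cons)
        seq = random_protein(rng, 200) + cons
        loose = {(o.motif_id, o.start) for o in scan_motifs(seq, [motif], p_max=1e-2)}
        tight = {(o.motif_id, o.start) for o in scan_motifs(seq, [motif], p_max=1e-6)}
        assert tight <= loose

    def test_overlaps_resolved_best_p_first(self):
        rng = np.random.default_rng(10)
        cons = random_protein(rng, 10)
        m1 = indicator_motif(cons, "M1", p=0.95)
        m2 = indicator_motif(cons[1:] + "A", "M2", p=0.6)  # weaker, overlapping
        seq = "A" * 20 + cons + "A" * 20
        occs = scan_motifs(seq, [m1, m2], p_max=1e-2)
        starts = [(o.motif_id, o.start, o.end) for o in occs]
        for a, b in zip(occs, occs[1:]):
            assert a.end < b.start  # non-overlapping after resolution

    def test_repeated_motif_gets_letter_suffixes_in_order(self):
        rng = np.random.default_rng(12)
        cons = random_protein(rng, 10)
        motif = indicator_motif(cons, "M6")
        seq = "A" * 10 + cons + "A" * 30 + cons + "A" * 10
        occs = scan_motifs(seq, [motif], p_max=1e-4)
        assert [o.label for o in occs] == ["M6a", "M6b"]


def _occ(mid, start, width=10, gene="g1"):
    return MotifOccurrence(gene, mid, "", start, start + width - 1, 1e-9)


class TestNaming:
    def test_single_occurrence_keeps_bare_id(self):
        arch = name_occurrences([_occ("M12", 30)])
        assert arch.labels == ["M12"]

    def test_duplicates_lettered_by_coordinate(self):
        arch = name_occurrences([_occ("M6", 50), _occ("M6", 10)])
        assert arch.labels == ["M6a", "M6b"]

    def test_interleaved_repeat_lettering(self):
        arch = name_occurrences([_occ("M3", 5), _occ("M6", 20), _occ("M3", 90)])
        assert arch.labels == ["M3a", "M6", "M3b"]

    def test_remaining_overlap_is_internal_error(self):
        with pytest.raises(RuntimeError, match="overlap"):
            name_occurrences([_occ("M1", 5), _occ("M2", 8)])


class TestPresenceMatrix:
    def test_lettered_variants_are_distinct_columns(self):
        mat = presence_matrix([
            ArchitectureString("g1", ["M6a", "M6b"]),
            ArchitectureString("g2", ["M6a"]),
        ])
        assert mat.loc["g1", "M6a"] == 1 and mat.loc["g1", "M6b"] == 1
        assert mat.loc["g2", "M6b"] == 0

    def test_empty_architecture_gives_zero_row(self):
        mat = presence_matrix([
            ArchitectureString("g1", ["M1"]),
            ArchitectureString("g2", []),
        ])
        assert mat.loc["g2"].sum() == 0

    def test_row_sums_equal_architecture_lengths(self):
        archs = [
            ArchitectureString("g1", ["M1", "M2", "M5"]),
            ArchitectureString("g2", ["M1"]),
        ]
        mat = presence_matrix(archs)
        for a in archs:
            assert mat.loc[a.gene_id].sum() == len(a.labels)


class TestConservedAndSpecific:
    def test_all_ones_column_is_core(self):
        mat = presence_matrix([
            ArchitectureString("g1", ["M1", "M2"]),
            ArchitectureString("g2", ["M1"]),
        ])
        core, _ = conserved_and_specific(mat, {"g1": "TNL", "g2": "CNL"})
        assert core == ["M1"]

    def test_class_indicator_column_is_specific(self):
        mat = presence_matrix([
            ArchitectureString("t1", ["M1", "M9"]),
            ArchitectureString("t2", ["M1", "M9"]),
            ArchitectureString("c1", ["M1"]),
        ])
        classes = {"t1": "TNL", "t2": "TNL", "c1": "CNL"}
        core, spec = conserved_and_specific(mat, classes)
        assert spec["TNL"] == ["M9"]
        assert spec["CNL"] == []

    def test_relaxed_prevalence_thresholds(self):
        mat = presence_matrix([
            ArchitectureString("t1", ["M9"]),
            ArchitectureString("t2", ["M9"]),
            ArchitectureString("t3", []),
            ArchitectureString("c1", []),
        ])
        classes = {"t1": "TNL", "t2": "TNL", "t3": "TNL", "c1": "CNL"}
        _, strict = conserved_and_specific(mat, classes)
        assert strict["TNL"] == []
        _, relaxed = conserved_and_specific(mat, classes, min_prevalence=0.6)
        assert relaxed["TNL"] == ["M9"]


class TestOutputs:
    def test_meme_minimal_and_architecture_tsv(self, tmp_path):
        rng = np.random.default_rng(1)
        motif = indicator_motif(random_protein(rng, 8), "M1")
        from nlrkit.motifkit import write_architectures_tsv, write_meme_minimal

        write_meme_minimal(tmp_path / "m.meme", [motif])
        text = (tmp_path / "m.meme").read_text()
        assert text.startswith("MEME version 4")
        assert "MOTIF M1" in text and "w= 8" in text
        write_architectures_tsv(
            tmp_path / "a.tsv",
            [ArchitectureString("g1", ["M1a", "M2", "M1b"])],
        )
        assert "g1\tM1a,M2,M1b" in (tmp_path / "a.tsv").read_text()
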