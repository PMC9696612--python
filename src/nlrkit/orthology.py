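"""Cross-species orthology of NB-LRR genes.

The pipeline mirrors the classic BLAST → reciprocal-best-hit → Markov
clustering (OrthoMCL-style) workflow, with the alignment stage implemented
natively: Smith–Waterman local alignment with affine gaps (BLOSUM62,
open 11 / extend 1 by default) and Karlin–Altschul e-values
``E = K·m·n·exp(−λ·S)`` using the documented gapped BLOSUM62 constants
K = 0.041, λ = 0.267.  These e-values are approximate and serve only for
thresholding and ranking, which is all the graph construction needs.

Graph construction keeps reciprocal best hits between species plus
within-species "recent paralog" edges — pairs at least as similar to each
other as either member is to anything in another species — and Markov
clustering (expansion/inflation on the column-stochastic adjacency,
inflation 1.5 as in OrthoMCL's default MCL setting) partitions the graph
into orthogroups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .scoring import ALPHABET, ALPHABET_SIZE, encode

__all__ = [
    "SimilarityEdge",
    "Orthogroup",
    "AlignmentResult",
    "local_align",
    "all_vs_all",
    "reciprocal_best_hits",
    "build_orthology_graph",
    "mcl_cluster",
    "assign_reference",
    "count_paralogs",
    "infer_orthogroups",
    "write_orthogroups_tsv",
]

#: Karlin–Altschul parameters for gapped BLOSUM62 (open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

#: Edge weights are −log10(e-value) capped at this value (OrthoMCL convention).
WEIGHT_CAP = 200.0


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a (21, 21) int matrix over ALPHABET + wildcard.

    Unknown residues score through the matrix's ``X`` row.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((ALPHABET_SIZE + 1, ALPHABET_SIZE + 1), dtype=np.int64)
    letters = ALPHABET + "X"
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            m[i, j] = int(blosum[a][b])
    return m


BLOSUM62 = _blosum62_matrix()


@njit(cache=True)
def _sw_end(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jit
    """Affine-gap Smith–Waterman, score only, plus the best cell (end coords).

    A gap of length L costs ``gap_open + L * gap_extend`` (BLAST convention:
    the first gap residue costs open + extend).
    """
    n, m = a.shape[0], b.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, -10**9, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        diag = 0  # H[i-1][0]
        F = -10**9
        prev_h = 0  # H[i][0]
        for j in range(1, m + 1):
            E[j] = max(E[j] - gap_extend, H[j] - gap_open - gap_extend)
            F = max(F - gap_extend, prev_h - gap_open - gap_extend)
            h = diag + sub[a[i - 1], b[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            prev_h = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    evalue: float
    a_start: int  # 1-based inclusive interval on each sequence
    a_end: int
    b_start: int
    b_end: int


def _evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def local_align(
    a: str,
    b: str,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    matrix: np.ndarray | None = None,
) -> AlignmentResult:
    """Smith–Waterman local alignment score and aligned interval.

    The interval start is found by rerunning the DP on the reversed
    prefixes ending at the best cell (standard two-pass trick; exact, no
    traceback matrix).  A score of 0 reports an empty interval.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sub = BLOSUM62 if matrix is None else matrix
    ea, eb = encode(a), encode(b)
    score, ai, bj = _sw_end(ea, eb, sub, gap_open, gap_extend)
    if score <= 0:
        return AlignmentResult(0, _evalue(0, len(a), len(b)), 0, -1, 0, -1)
    ra, rb = ea[:ai][::-1].copy(), eb[:bj][::-1].copy()
    score2, ri, rj = _sw_end(ra, rb, sub, gap_open, gap_extend)
    assert score2 >= score
    return AlignmentResult(
        score=int(score),
        evalue=_evalue(score, len(a), len(b)),
        a_start=ai - ri + 1,
        a_end=ai,
        b_start=bj - rj + 1,
        b_end=bj,
    )


@dataclass(frozen=True)
class SimilarityEdge:
    """One unordered sequence pair with its (symmetric) local-alignment
    score; SW scores do not depend on query/subject order, so a single
    score serves both directions."""

    query_id: str
    subject_id: str
    score: int
    evalue: float


def all_vs_all(
    proteins_by_species: dict[str, dict[str, str]],
    evalue_max: float = 1e-5,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> list[SimilarityEdge]:
    """All-vs-all local alignment (within and across species), keeping
    pairs with evalue <= ``evalue_max``.  Self-pairs are excluded."""
    ids: list[str] = []
    seqs: list[np.ndarray] = []
    lens: list[int] = []
    for sp in sorted(proteins_by_species):
        for gid in sorted(proteins_by_species[sp]):
            ids.append(gid)
            s = proteins_by_species[sp][gid]
            seqs.append(encode(s))
            lens.append(len(s))
    edges: list[SimilarityEdge] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            score, _, _ = _sw_end(seqs[i], seqs[j], BLOSUM62, gap_open, gap_extend)
            ev = _evalue(score, lens[i], lens[j])
            if ev <= evalue_max:
                edges.append(SimilarityEdge(ids[i], ids[j], int(score), ev))
    return edges


def reciprocal_best_hits(
    edges: Iterable[SimilarityEdge],
    species_of: dict[str, str],
) -> list[tuple[str, str]]:
    """Reciprocal best hits across species.

    For each (gene, target species) the best subject is the highest score,
    ties broken by lower e-value then lexicographic subject id; (a, b) is
    an RBH iff each is the other's best in the partner species.
    """
    best: dict[tuple[str, str], tuple[str, float, float]] = {}
    for e in edges:
        for q, s in ((e.query_id, e.subject_id), (e.subject_id, e.query_id)):
            sp = species_of[s]
            if species_of[q] == sp:
                continue
            key = (q, sp)
            cur = best.get(key)
            cand = (s, float(e.score), e.evalue)
            if cur is None or (-cand[1], cand[2], cand[0]) < (-cur[1], cur[2], cur[0]):
                best[key] = cand
    rbh: set[tuple[str, str]] = set()
    for (q, _sp), (s, _score, _ev) in best.items():
        back = best.get((s, species_of[q]))
        if back is not None and back[0] == q:
            rbh.add((min(q, s), max(q, s)))
    return sorted(rbh)


def build_orthology_graph(
    edges: Iterable[SimilarityEdge],
    species_of: dict[str, str],
    evalue_max: float = 1e-5,
    inparalog_mode: str = "recent",
) -> list[tuple[str, str, float]]:
    """RBH edges plus within-species paralog edges, weighted by
    −log10(e-value) capped at 200.

    ``inparalog_mode="recent"`` keeps a within-species edge only when it is
    at least as strong (by e-value) as both members' best cross-species
    hits — OrthoMCL's recent-paralog criterion in simplified form;
    ``"threshold"`` keeps every within-species edge passing ``evalue_max``.
    """
    if inparalog_mode not in ("recent", "threshold"):
        raise ValueError(f"unknown inparalog_mode {inparalog_mode!r}")
    edges = [e for e in edges if e.evalue <= evalue_max]
    rbh = set(reciprocal_best_hits(edges, species_of))
    best_cross: dict[str, float] = {}
    for e in edges:
        if species_of[e.query_id] != species_of[e.subject_id]:
            for g in (e.query_id, e.subject_id):
                best_cross[g] = min(best_cross.get(g, float("inf")), e.evalue)

    def weight(ev: float) -> float:
        if ev <= 0:
            return WEIGHT_CAP
        return min(-math.log10(ev), WEIGHT_CAP)

    out: list[tuple[str, str, float]] = []
    for e in edges:
        u, v = min(e.query_id, e.subject_id), max(e.query_id, e.subject_id)
        same_sp = species_of[u] == species_of[v]
        if same_sp:
            if inparalog_mode == "recent":
                bar = max(
                    best_cross.get(u, float("inf")),
                    best_cross.get(v, float("inf")),
                )
                if math.isfinite(bar) and e.evalue > bar:
                    continue
            out.append((u, v, weight(e.evalue)))
        elif (u, v) in rbh:
            out.append((u, v, weight(e.evalue)))
    return out


@dataclass
class Orthogroup:
    group_id: str
    members_by_species: dict[str, list[str]] = field(default_factory=dict)
    reference_labels: list[str] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return sorted(g for ms in self.members_by_species.values() for g in ms)

    @property
    def size(self) -> int:
        return sum(len(ms) for ms in self.members_by_species.values())


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _mcl_component(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    inflation: float,
    pruning_epsilon: float,
    max_iter: int,
) -> tuple[list[list[str]], bool]:
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, w in edges:
        W[idx[u], idx[v]] = W[idx[v], idx[u]] = w
    # self-loops at each node's max incident weight regularize the flow
    loops = W.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(W, loops)
    M = W / W.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        M2 = M @ M
        M2 = M2 ** inflation
        M2[M2 < pruning_epsilon] = 0.0
        colsum = M2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.abs(M2 - M).max() < 1e-6:
            M = M2
            converged = True
            break
        M = M2
    # converged MCL iterants are near-idempotent; clusters are the connected
    # components of the remaining nonzero structure
    dsu = _DSU(range(n))
    nz = np.argwhere(M > pruning_epsilon)
    for i, j in nz:
        dsu.union(int(i), int(j))
    groups: dict[int, list[str]] = {}
    for i, g in enumerate(nodes):
        groups.setdefault(dsu.find(i), []).append(g)
    return [sorted(v) for v in groups.values()], converged


def mcl_cluster(
    graph: list[tuple[str, str, float]],
    species_of: dict[str, str],
    nodes: Iterable[str] | None = None,
    inflation: float = 1.5,
    pruning_epsilon: float = 1e-5,
    max_iter: int = 100,
) -> list[Orthogroup]:
    """Markov clustering of the orthology graph into orthogroups.

    Expansion (matrix squaring) alternates with inflation (elementwise
    power and column renormalization) until the iterant changes by less
    than 1e-6 or ``max_iter`` is reached (in which case the current hard
    clustering is returned with a warning).  The result is a partition:
    every node lands in exactly one group; nodes absent from the graph
    become singletons.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    node_set = {g for u, v, _ in graph for g in (u, v)}
    if nodes is not None:
        node_set |= set(nodes)
    all_nodes = sorted(node_set)
    dsu = _DSU(all_nodes)
    for u, v, _ in graph:
        dsu.union(u, v)
    comps: dict[str, list[str]] = {}
    for g in all_nodes:
        comps.setdefault(dsu.find(g), []).append(g)
    edges_of: dict[str, list[tuple[str, str, float]]] = {}
    for u, v, w in graph:
        edges_of.setdefault(dsu.find(u), []).append((u, v, w))

    partitions: list[list[str]] = []
    for root, members in comps.items():
        if len(members) == 1:
            partitions.append(members)
            continue
        clusters, converged = _mcl_component(
            sorted(members), edges_of.get(root, []), inflation,
            pruning_epsilon, max_iter,
        )
        if not converged:
            import logging

            logging.getLogger(__name__).warning(
                "MCL did not converge within %d iterations on a %d-node "
                "component; returning current hard clustering",
                max_iter, len(members),
            )
        partitions.extend(clusters)

    partitions.sort(key=lambda ms: (-len(ms), ms[0]))
    out = []
    for k, members in enumerate(partitions, 1):
        by_sp: dict[str, list[str]] = {}
        for g in sorted(members):
            by_sp.setdefault(species_of.get(g, ""), []).append(g)
        out.append(Orthogroup(group_id=f"OG{k:04d}", members_by_species=by_sp))
    return out


def assign_reference(
    references: dict[str, str],
    orthogroups: list[Orthogroup],
    member_seqs: dict[str, str],
    evalue_max: float = 1e-5,
) -> tuple[list[Orthogroup], list[str]]:
    """Attach characterized reference proteins to orthogroups by best hit.

    Each reference goes to the group containing its single best-scoring
    hit with evalue <= ``evalue_max`` (ties: lower e-value, then
    lexicographic gene id); references with no qualifying hit are returned
    as unassigned.
    """
    group_of: dict[str, Orthogroup] = {}
    for og in orthogroups:
        for g in og.member_ids:
            group_of[g] = og
    unassigned: list[str] = []
    for rid in sorted(references):
        rseq = references[rid]
        best: tuple[float, float, str] | None = None  # (-score, evalue, gid)
        for gid in sorted(member_seqs):
            res = local_align(rseq, member_seqs[gid])
            if res.evalue > evalue_max:
                continue
            key = (-float(res.score), res.evalue, gid)
            if best is None or key < best:
                best = key
        if best is None:
            unassigned.append(rid)
        else:
            group_of[best[2]].reference_labels.append(rid)
    return orthogroups, unassigned


def count_paralogs(orthogroups: Iterable[Orthogroup]) -> dict[str, int]:
    """A gene is a paralog iff its orthogroup holds >= 2 genes of its own
    species; returns per-species paralog counts."""
    counts: dict[str, int] = {}
    for og in orthogroups:
        for sp, members in og.members_by_species.items():
            if len(members) >= 2:
                counts[sp] = counts.get(sp, 0) + len(members)
    return counts


def infer_orthogroups(
    proteins_by_species: dict[str, dict[str, str]],
    evalue_max: float = 1e-5,
    inflation: float = 1.5,
    inparalog_mode: str = "recent",
) -> tuple[list[Orthogroup], list[SimilarityEdge]]:
    """End-to-end orthology: all-vs-all → RBH + paralog graph → MCL."""
    species_of = {
        gid: sp for sp, genes in proteins_by_species.items() for gid in genes
    }
    edges = all_vs_all(proteins_by_species, evalue_max=evalue_max)
    graph = build_orthology_graph(
        edges, species_of, evalue_max=evalue_max, inparalog_mode=inparalog_mode
    )
    groups = mcl_cluster(graph, species_of, nodes=species_of.keys(),
                         inflation=inflation)
    return groups, edges


def write_edges_tsv(path: str | Path, edges: Iterable[SimilarityEdge]) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tscore\tevalue\n")
        for e in sorted(edges, key=lambda e: (e.query_id, e.subject_id)):
            fh.write(f"{e.query_id}\t{e.subject_id}\t{e.score}\t{e.evalue:.3g}\n")


def write_summary_json(path: str | Path, orthogroups: list[Orthogroup]) -> None:
    """Summary JSON: group count, per-species gene and paralog tallies."""
    import json

    per_species: dict[str, int] = {}
    for og in orthogroups:
        for sp, members in og.members_by_species.items():
            per_species[sp] = per_species.get(sp, 0) + len(members)
    summary = {
        "n_groups": len(orthogroups),
        "n_genes": sum(og.size for og in orthogroups),
        "genes_per_species": dict(sorted(per_species.items())),
        "paralogs_per_species": dict(sorted(count_paralogs(orthogroups).items())),
        "group_sizes": {og.group_id: og.size for og in orthogroups},
    }
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def write_orthogroups_tsv(path: str | Path, orthogroups: Iterable[Orthogroup]) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgene_id\tspecies\treference_labels\n")
        for og in orthogroups:
            labels = ",".join(sorted(og.reference_labels)) or "-"
            for sp in sorted(og.members_by_species):
                for gid in og.members_by_species[sp]:
                    fh.write(f"{og.group_id}\t{gid}\t{sp}\t{labels}\n")
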