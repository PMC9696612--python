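"""Physical R-gene cluster detection.

Tandem duplication concentrates NB-LRR genes in chromosomal clusters.  Two
NB-LRR genes belong to the same cluster when they lie on the same seqid and
no more than ``max_intervening`` (default 8) other annotated genes fall
strictly between their start coordinates; cluster membership is the
transitive closure of this pairwise relation.  Strand is ignored, and
"other genes" counts every annotated gene, NB-LRR or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .domainscan import GeneModel

__all__ = ["ClusterParams", "GeneClusterSet", "detect_clusters", "cluster_stats",
           "read_id_list", "write_clusters_tsv"]


def read_id_list(source: str | Path) -> set[str]:
    """Candidate NB-LRR ids, one per line; blank lines and # comments skipped."""
    ids = set()
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


@dataclass(frozen=True)
class ClusterParams:
    max_intervening: int = 8

    def __post_init__(self) -> None:
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")


@dataclass
class GeneClusterSet:
    species: str
    clusters: list[list[str]] = field(default_factory=list)  # ordered by start
    singletons: list[str] = field(default_factory=list)

    @property
    def clustered_ids(self) -> set[str]:
        return {g for c in self.clusters for g in c}


def detect_clusters(
    genes: Iterable[GeneModel],
    nblrr_ids: set[str],
    params: ClusterParams = ClusterParams(),
) -> GeneClusterSet:
    """Cluster NB-LRR genes by the intervening-gene rule.

    For genes sorted by start coordinate within a seqid, the number of
    other genes strictly between two NB-LRR genes is their index distance
    minus one, so consecutive NB-LRR genes are linked when that count is
    <= ``max_intervening``; connected components follow by chaining runs
    (linking any non-consecutive pair implies all its consecutive pairs
    are linked, because intermediate gaps are strictly smaller).
    """
    genes = list(genes)
    known = {g.gene_id for g in genes}
    missing = sorted(nblrr_ids - known)
    if missing:
        raise ValueError(f"NB-LRR ids absent from gene models: {missing}")
    species = next((g.species for g in genes if g.species), "")

    by_seqid: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seqid.setdefault(g.seqid, []).append(g)

    clusters: list[list[str]] = []
    singles: list[str] = []
    for seqid in sorted(by_seqid):
        ordered = sorted(by_seqid[seqid], key=lambda g: (g.start, g.gene_id))
        marks = [(i, g.gene_id) for i, g in enumerate(ordered) if g.gene_id in nblrr_ids]
        run: list[str] = []
        prev_idx: int | None = None
        for idx, gid in marks:
            if prev_idx is not None and idx - prev_idx - 1 <= params.max_intervening:
                run.append(gid)
            else:
                if len(run) >= 2:
                    clusters.append(run)
                elif run:
                    singles.append(run[0])
                run = [gid]
            prev_idx = idx
        if len(run) >= 2:
            clusters.append(run)
        elif run:
            singles.append(run[0])
    return GeneClusterSet(species=species, clusters=clusters, singletons=singles)


def cluster_stats(
    cluster_set: GeneClusterSet,
    class_of: dict[str, str] | None = None,
) -> dict:
    """Per-species cluster summary; totals conserve gene counts."""
    n_clustered = sum(len(c) for c in cluster_set.clusters)
    summary = {
        "species": cluster_set.species,
        "n_clusters": len(cluster_set.clusters),
        "n_clustered_genes": n_clustered,
        "n_singletons": len(cluster_set.singletons),
        "n_genes": n_clustered + len(cluster_set.singletons),
    }
    if class_of is not None:
        per_class: dict[str, dict[str, int]] = {}
        for gid in cluster_set.clustered_ids:
            c = class_of.get(gid, "other")
            per_class.setdefault(c, {"clustered": 0, "singleton": 0})["clustered"] += 1
        for gid in cluster_set.singletons:
            c = class_of.get(gid, "other")
            per_class.setdefault(c, {"clustered": 0, "singleton": 0})["singleton"] += 1
        summary["per_class"] = {k: per_class[k] for k in sorted(per_class)}
    return summary


def write_clusters_tsv(
    path: str | Path,
    cluster_sets: Iterable[GeneClusterSet],
    genes_by_id: dict[str, GeneModel],
) -> None:
    """Cluster table (BED-convertible: seqid + 1-based inclusive span)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tspecies\tseqid\tmember_ids\tspan_start\tspan_end\n")
        for cs in cluster_sets:
            for i, members in enumerate(cs.clusters, 1):
                models = [genes_by_id[g] for g in members]
                seqid = models[0].seqid
                fh.write(
                    f"{cs.species}_C{i:03d}\t{cs.species}\t{seqid}\t"
                    f"{','.join(members)}\t{min(m.start for m in models)}\t"
                    f"{max(m.end for m in models)}\n"
                )
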