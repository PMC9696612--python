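"""Glue: run the full survey on a synthetic cohort.

Ties the stages together in the order a real analysis would run them —
scan & classify, detect physical clusters, infer orthogroups, decompose NB
domains into motifs, and summarize.  Returns a plain dict of stage outputs
so callers (examples, validation, reporting) can pick what they need.
"""

from __future__ import annotations

from . import domainscan, genecluster, motifkit, orthology
from .scoring import build_pssm
from .synthdata import Cohort, DOMAIN_WIDTHS


def domain_profiles_from_registry(registry: dict[str, str]):
    """Build scan profiles for the planted N-terminal/NB/LRR segments.

    Each profile is a PSSM from the (duplicated) consensus block; with the
    default pseudocount this reproduces the consensus scores needed for
    detection while tolerating per-copy substitution noise.
    """
    profiles_ = []
    for kind in DOMAIN_WIDTHS:
        consensus = registry[kind]
        profiles_.append(
            build_pssm([consensus, consensus], pseudocount=1.0,
                       profile_id=kind, kind=kind)
        )
    return profiles_


def run_pipeline(
    cohort: Cohort,
    scan_evalue_max: float = 1e-6,
    cluster_max_intervening: int = 8,
    ortho_evalue_max: float = 1e-5,
    inflation: float = 1.5,
    motif_p_max: float = 1e-9,
    discover: bool = False,
    n_motifs: int | None = None,
    motif_widths: tuple[int, int] | None = None,
    seed: int = 0,
) -> dict:
    """Run scan → classify → cluster → orthology → motifs on a cohort.

    By default the motif stage rescans with PSSMs built from the planted
    registry consensi (the configured-truth route); ``discover=True`` runs
    de-novo EM discovery on the NB regions instead.  The occurrence
    threshold is stricter than the generic scan default because registry
    PSSMs are sharp: true occurrences sit around p = 20^-width, while
    p <= 1e-4 already admits chance ~6-of-15 residue matches.
    """
    truth = cohort.truth
    genes = cohort.all_genes()

    # --- domain scan & classification
    profs = domain_profiles_from_registry(truth.planted_motifs)
    hits = domainscan.scan_proteome(genes, profs, evalue_max=scan_evalue_max)
    classified = domainscan.classify_genes(genes, hits)
    nblrr_ids = {
        gid for gid, cg in classified.items() if cg.class_label != "other"
    }

    # --- physical clusters per species
    params = genecluster.ClusterParams(max_intervening=cluster_max_intervening)
    cluster_sets = {
        sp: genecluster.detect_clusters(
            cohort.genes[sp], nblrr_ids & {g.gene_id for g in cohort.genes[sp]},
            params,
        )
        for sp in cohort.species
    }

    # --- orthology over identified NB-LRR genes
    proteins_by_species = {
        sp: {g.gene_id: g.protein for g in cohort.genes[sp] if g.gene_id in nblrr_ids}
        for sp in cohort.species
    }
    groups, edges = orthology.infer_orthogroups(
        proteins_by_species, evalue_max=ortho_evalue_max, inflation=inflation
    )
    if cohort.references:
        member_seqs = {
            gid: seq for d in proteins_by_species.values() for gid, seq in d.items()
        }
        groups, unassigned = orthology.assign_reference(
            cohort.references, groups, member_seqs, evalue_max=ortho_evalue_max
        )
    else:
        unassigned = []
    paralogs = orthology.count_paralogs(groups)

    # --- NB-domain motif content
    nb_seqs = cohort.nb_sequences()
    if discover:
        widths = motif_widths or cohort.config._width_range
        motifs = motifkit.discover_motifs(
            nb_seqs,
            n_motifs=n_motifs or len(
                [m for m in truth.planted_motifs if m.startswith("M")]
            ),
            width_range=widths,
            seed=seed,
        )
    else:
        import numpy as np

        motifs = []
        for mid in sorted(
            (m for m in truth.planted_motifs if m.startswith("M")),
            key=lambda s: int(s[1:]),
        ):
            cons = truth.planted_motifs[mid]
            pwm = np.full((len(cons), 20), 0.5 / 19)
            from .scoring import AA_INDEX

            for j, aa in enumerate(cons):
                pwm[j, AA_INDEX[aa]] = 0.5
            motifs.append(motifkit.MotifModel(motif_id=mid, pwm=pwm))
    occurrences = motifkit.scan_collection(nb_seqs, motifs, p_max=motif_p_max)
    architectures = [
        motifkit.name_occurrences(occ) if occ else motifkit.ArchitectureString(gid)
        for gid, occ in sorted(occurrences.items())
    ]
    matrix = motifkit.presence_matrix(architectures) if architectures else None

    # --- per-species count table
    import pandas as pd

    count_rows = {}
    for sp in cohort.species:
        n_groups_sp = sum(
            1 for og in groups if og.members_by_species.get(sp)
        )
        count_rows[sp] = {
            "nblrr_genes": len(proteins_by_species[sp]),
            "orthogroups": n_groups_sp,
            "paralogs": paralogs.get(sp, 0),
            "clusters": len(cluster_sets[sp].clusters),
        }
    counts = pd.DataFrame.from_dict(count_rows, orient="index").sort_index()

    return {
        "hits": hits,
        "classified": classified,
        "nblrr_ids": nblrr_ids,
        "cluster_sets": cluster_sets,
        "orthogroups": groups,
        "edges": edges,
        "unassigned_references": unassigned,
        "paralogs": paralogs,
        "motifs": motifs,
        "occurrences": occurrences,
        "presence_matrix": matrix,
        "counts": counts,
    }
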