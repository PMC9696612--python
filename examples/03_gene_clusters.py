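"""Detect physical R-gene clusters with the intervening-gene rule.

Two NB-LRR genes share a cluster when at most eight other annotated genes
lie between them on the same chromosome, closed transitively.  Detected
clusters are compared with the planted layout.
"""

from nlrkit import genecluster, synthdata

cohort = synthdata.generate_cohort(synthdata.CohortConfig(seed=1))
truth = cohort.truth
params = genecluster.ClusterParams(max_intervening=8)

for sp in cohort.species:
    ids = {g for g in truth.true_class if truth.species_of[g] == sp}
    cs = genecluster.detect_clusters(cohort.genes[sp], ids, params)
    stats = genecluster.cluster_stats(cs, class_of=truth.true_class)
    planted = {frozenset(c) for c in truth.true_clusters[sp]}
    detected = {frozenset(c) for c in cs.clusters}
    print(
        f"{sp}: {stats['n_clusters']} clusters covering "
        f"{stats['n_clustered_genes']} genes, {stats['n_singletons']} singletons "
        f"(matches planted layout: {detected == planted})"
    )
# Cluster membership is the transitive closure of the pairwise rule, so a
# chain A-(8 genes)-B-(8 genes)-C is one cluster even though A and C are
# separated by more than eight genes.
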