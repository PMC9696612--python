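"""Decompose NB domains into ungapped motifs by EM and rescan them.

Thirty 15-residue motifs are planted (in order, with random spacers) in 70
synthetic NB domain sequences; discovery fits one PWM at a time with
probabilistic erasure between rounds.  Rescanning assigns exact p-values
and per-gene letter suffixes (M6a, M6b, ...) to repeated motifs.
"""

import numpy as np

from nlrkit import motifkit
from nlrkit.synthdata import draw_distinct_motifs, plant_motifs, random_protein

rng = np.random.default_rng(1)
consensi = draw_distinct_motifs(rng, 30, 15)
sequences = {}
for s in range(70):
    scaffold = random_protein(rng, 30 * 15 + int(rng.integers(60, 120)))
    seq, _ = plant_motifs(scaffold, list(consensi.values()), 0.0, rng)
    sequences[f"g{s}"] = seq

motifs = motifkit.discover_motifs(
    sequences, n_motifs=30, width_range=(15, 15), seed=0, n_starts=3
)
exact = sum(m.consensus in consensi.values() for m in motifs)
print(f"motifs discovered: {len(motifs)}; exact consensus recovery: {exact}/30")

occurrences = motifkit.scan_collection(sequences, motifs, p_max=1e-4)
arch = motifkit.name_occurrences(occurrences["g0"])
print(f"architecture of g0: {arch}")

matrix = motifkit.presence_matrix(
    [motifkit.name_occurrences(o) for o in occurrences.values()]
)
print(f"presence matrix: {matrix.shape[0]} genes x {matrix.shape[1]} motif labels; "
      f"all-present columns: {int((matrix.mean() == 1.0).sum())}")
# At zero noise every planted motif is recovered verbatim and every
# occurrence sits at its planted coordinate with the minimal p-value.
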