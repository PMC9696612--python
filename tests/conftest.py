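import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from nlrkit import synthdata
from nlrkit.synthdata import plant_motifs, random_protein

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free cohort: planted structure is exactly recoverable."""
    cfg = synthdata.CohortConfig(
        n_species=3,
        genes_per_species=250,
        nblrr_fraction=0.08,
        substitution_rate=0.0,
        motif_dropout_rate=0.0,
        seed=42,
    )
    return synthdata.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort at the default 5% substitution / 5% dropout conditions."""
    cfg = synthdata.CohortConfig(
        n_species=3, genes_per_species=250, nblrr_fraction=0.08, seed=43
    )
    return synthdata.generate_cohort(cfg)


def make_motif_bench(n_seqs=20, n_motifs=5, width=15, noise=0.0, seed=7,
                     spacer_budget=(40, 80)):
    """Planted-motif benchmark: sequences hosting every motif once, in
    order, with per-sequence random spacers.  Returns (sequences, consensi,
    occurrences) with 1-based truth coordinates."""
    rng = np.random.default_rng(seed)
    consensi = synthdata.draw_distinct_motifs(rng, n_motifs, width)
    seqs, occurrences = {}, {}
    for s in range(n_seqs):
        scaffold = random_protein(
            rng, n_motifs * width + int(rng.integers(*spacer_budget))
        )
        seq, coords = plant_motifs(scaffold, list(consensi.values()), noise, rng)
        seqs[f"g{s}"] = seq
        occurrences[f"g{s}"] = list(zip(consensi.keys(), coords))
    return seqs, consensi, occurrences


@pytest.fixture
def motif_bench():
    return make_motif_bench
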