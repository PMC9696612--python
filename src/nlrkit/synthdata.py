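"""Synthetic multi-species NB-LRR cohorts with known ground truth.

The generator emulates the data structure a plant R-gene survey consumes:
per-species proteomes (FASTA) and gene models (GFF3) in which a configurable
fraction of genes are NB-LRR receptors.  Each NB-LRR protein is assembled
from planted building blocks —

* an N-terminal domain segment (TIR, CC or RPW8 by class; absent in
  ``partial`` genes),
* an NB-ARC region carrying an anchor segment plus an ordered set of
  ungapped motifs (a shared core set in every class, plus class-specific
  sets), separated by per-founder random spacers,
* a run of identical LRR repeat units and a short C-terminal tail.

Orthogroups arise by star-phylogeny copying: a founder archetype is copied
into each species (subject to a per-species loss probability) with
independent per-residue substitution noise; tandem duplications add
recent, slightly diverged paralog copies.  Physical gene clusters are laid
out on synthetic chromosomes with a bounded number of intervening
background genes between members and a larger separation (> 8 background
genes) between clusters, so the planted cluster structure is exactly
recoverable by the intervening-gene rule.

Everything is driven by named RNG streams derived from the config seed, so
a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .domainscan import GeneModel
from .scoring import ALPHABET, ROBINSON_BACKGROUND

__all__ = [
    "CohortConfig",
    "TruthTables",
    "Cohort",
    "ConfigError",
    "CapacityError",
    "generate_cohort",
    "plant_motifs",
    "random_protein",
    "draw_distinct_motifs",
    "ARCH_LABEL_OF_TRUE_CLASS",
]

NBLRR_CLASSES = ("TNL", "CNL", "RNL", "partial")

#: What classify_architecture is expected to call each planted class
#: (partial genes carry an NB domain only, hence the ``N`` label).
ARCH_LABEL_OF_TRUE_CLASS = {"TNL": "TNL", "CNL": "CNL", "RNL": "RNL", "partial": "N"}

#: Widths of the planted domain segments (residues).
DOMAIN_WIDTHS = {"TIR": 40, "CC": 30, "RPW8": 32, "NB": 40, "LRR": 24}


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


class CapacityError(ValueError):
    """Scaffold too short to host the requested motifs."""


def _default_class_mix() -> dict[str, float]:
    return {"TNL": 0.40, "CNL": 0.35, "RNL": 0.10, "partial": 0.15}


def _default_class_specific() -> dict[str, int]:
    return {"TNL": 8, "CNL": 10, "RNL": 4, "partial": 0}


def _default_cluster_sizes() -> dict[int, float]:
    # heavily skewed to singletons: most multi-gene clusters should arise
    # from tandem paralog arrays, not from chance adjacency of unrelated
    # genes, mirroring the duplication-driven origin of real R-gene clusters
    return {1: 0.82, 2: 0.10, 3: 0.05, 4: 0.03}


def _default_intervening() -> dict[int, float]:
    return {0: 0.35, 1: 0.20, 2: 0.14, 3: 0.10, 4: 0.08,
            5: 0.05, 6: 0.04, 7: 0.02, 8: 0.02}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a five-species cohort of ~200 NB-LRR genes (~40 per
    species before loss/duplication), a 13-motif conserved NB core with 8
    TNL-, 10 CNL- and 4 RNL-specific motifs of width 15, 5% per-copy
    substitution noise and 5% per-motif dropout — the regime the validation
    suite exercises.
    """

    n_species: int = 5
    genes_per_species: int = 500
    nblrr_fraction: float = 0.08
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    n_core_motifs: int = 13
    class_specific_motifs: dict[str, int] = field(default_factory=_default_class_specific)
    motif_width: int | tuple[int, int] = 15
    substitution_rate: float = 0.05
    motif_dropout_rate: float = 0.05
    cluster_size_distribution: dict[int, float] = field(default_factory=_default_cluster_sizes)
    intervening_gene_distribution: dict[int, float] = field(default_factory=_default_intervening)
    duplication_rate: float = 0.15
    loss_rate: float = 0.10
    n_references: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "genes_per_species", "n_core_motifs"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("nblrr_fraction", "substitution_rate", "motif_dropout_rate",
                     "duplication_rate", "loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix proportions must sum to 1")
        for cls in self.class_mix:
            if cls not in NBLRR_CLASSES:
                raise ConfigError(f"class_mix: unknown class {cls!r}")
        for cls, n in self.class_specific_motifs.items():
            if cls not in NBLRR_CLASSES or n < 0:
                raise ConfigError(f"class_specific_motifs: bad entry {cls!r}: {n}")
        for name in ("cluster_size_distribution", "intervening_gene_distribution"):
            dist = getattr(self, name)
            if not dist or abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"{name} probabilities must be >= 0")
        if min(self.cluster_size_distribution) < 1:
            raise ConfigError("cluster_size_distribution sizes must be >= 1")
        if min(self.intervening_gene_distribution) < 0:
            raise ConfigError("intervening_gene_distribution counts must be >= 0")
        w = self.motif_width
        lo, hi = (w, w) if isinstance(w, int) else (int(w[0]), int(w[1]))
        if lo < 4 or hi < lo:
            raise ConfigError("motif_width must be >= 4 (or a valid (min, max) range)")
        self._width_range = (lo, hi)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "CohortConfig":
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if "motif_width" in data and isinstance(data["motif_width"], list):
            data["motif_width"] = tuple(data["motif_width"])
        for key in ("cluster_size_distribution", "intervening_gene_distribution"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if not k.startswith("_")
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TruthTables:
    """Planted ground truth for one cohort."""

    true_class: dict[str, str] = field(default_factory=dict)
    true_orthogroup: dict[str, str] = field(default_factory=dict)
    true_clusters: dict[str, list[set[str]]] = field(default_factory=dict)
    planted_motifs: dict[str, str] = field(default_factory=dict)
    planted_architecture: dict[str, list[str]] = field(default_factory=dict)
    # extras beyond the minimum contract, used by validation:
    planted_occurrences: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    nb_region: dict[str, tuple[int, int]] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)
    reference_group: dict[str, str] = field(default_factory=dict)
    class_motif_order: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Cohort:
    config: CohortConfig
    species: list[str]
    genes: dict[str, list[GeneModel]]  # species -> genes in chromosome order
    truth: TruthTables
    references: dict[str, str] = field(default_factory=dict)  # ref id -> protein

    @property
    def nblrr_ids(self) -> set[str]:
        return set(self.truth.true_class)

    def all_genes(self) -> list[GeneModel]:
        return [g for sp in self.species for g in self.genes[sp]]

    def nb_sequences(self) -> dict[str, str]:
        """Planted NB-region subsequences (motif-discovery input)."""
        seqs = {}
        proteins = {g.gene_id: g.protein for g in self.all_genes()}
        for gid, (s, e) in self.truth.nb_region.items():
            seqs[gid] = proteins[gid][s - 1 : e]
        return seqs

    # ------------------------------------------------------------------ io
    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA + GFF3 per species, truth TSV, motif registry JSON and
        the config as YAML.  Deterministic: same cohort, same bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sp in self.species:
            fa = outdir / f"{sp}.faa"
            with open(fa, "w") as fh:
                for g in self.genes[sp]:
                    fh.write(f">{g.gene_id}\n")
                    for i in range(0, len(g.protein), 60):
                        fh.write(g.protein[i : i + 60] + "\n")
            gff = outdir / f"{sp}.gff3"
            with open(gff, "w") as fh:
                fh.write("##gff-version 3\n")
                for g in self.genes[sp]:
                    fh.write(
                        f"{g.seqid}\tnlrkit_synth\tgene\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}\n"
                    )
            paths[f"{sp}.faa"] = fa
            paths[f"{sp}.gff3"] = gff
        cluster_id_of: dict[str, str] = {}
        for sp in self.species:
            for i, members in enumerate(self.truth.true_clusters.get(sp, []), 1):
                for gid in members:
                    cluster_id_of[gid] = f"{sp}_C{i:03d}"
        truth_tsv = outdir / "truth.tsv"
        with open(truth_tsv, "w") as fh:
            fh.write("gene_id\tspecies\tclass\torthogroup\tcluster_id\n")
            for gid in sorted(self.truth.true_class):
                fh.write(
                    f"{gid}\t{self.truth.species_of[gid]}\t{self.truth.true_class[gid]}"
                    f"\t{self.truth.true_orthogroup[gid]}\t{cluster_id_of.get(gid, '-')}\n"
                )
        registry = {
            "motifs": self.truth.planted_motifs,
            "class_motif_order": self.truth.class_motif_order,
        }
        registry_json = outdir / "motifs.json"
        registry_json.write_text(json.dumps(registry, indent=2, sort_keys=True) + "\n")
        if self.references:
            ref_fa = outdir / "references.faa"
            with open(ref_fa, "w") as fh:
                for rid in sorted(self.references):
                    fh.write(f">{rid}\n")
                    seq = self.references[rid]
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")
            paths["references.faa"] = ref_fa
        self.config.to_yaml(outdir / "config.yaml")
        paths.update({"truth.tsv": truth_tsv, "motifs.json": registry_json,
                      "config.yaml": outdir / "config.yaml"})
        return paths

    def output_digest(self) -> str:
        """SHA-256 over all emitted artifacts (for determinism checks)."""
        h = hashlib.sha256()
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            paths = self.write(tmp)
            for name in sorted(paths):
                h.update(name.encode())
                h.update(paths[name].read_bytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# sequence-level primitives


def random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(ALPHABET), size=length, p=ROBINSON_BACKGROUND)
    return "".join(ALPHABET[i] for i in idx)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-residue substitution: with probability ``rate`` a position is
    redrawn uniformly from the 20-letter alphabet (so rate 1 leaves ~5%
    identity by chance)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        repl = rng.integers(0, len(ALPHABET), size=n)
        arr[mask] = np.frombuffer(
            "".join(ALPHABET[i] for i in repl).encode(), dtype=np.uint8
        )
    return arr.tobytes().decode()


def plant_motifs(
    scaffold: str,
    motifs: list[str],
    noise: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]]]:
    """Embed motif consensus strings, in order, at random non-overlapping
    positions of a scaffold.

    Returns the edited sequence and 1-based inclusive occurrence
    coordinates, strictly ascending.  At ``noise=0`` the substring at each
    coordinate equals the consensus exactly.  Raises CapacityError when the
    scaffold cannot host all motifs.
    """
    total = sum(len(m) for m in motifs)
    slack = len(scaffold) - total
    if slack < 0:
        raise CapacityError(
            f"scaffold of {len(scaffold)} residues cannot host "
            f"{len(motifs)} motifs totalling {total}"
        )
    gaps = rng.multinomial(slack, np.full(len(motifs) + 1, 1.0 / (len(motifs) + 1)))
    out = []
    coords = []
    pos = 0  # 0-based cursor in scaffold
    for gap, motif in zip(gaps[:-1], motifs):
        out.append(scaffold[pos : pos + gap])
        pos += gap
        start = sum(len(s) for s in out)
        out.append(_mutate(motif, noise, rng))
        pos += len(motif)
        coords.append((start + 1, start + len(motif)))
    out.append(scaffold[pos:])
    return "".join(out), coords


# ---------------------------------------------------------------------------
# cohort generation

_STREAM_REGISTRY = 1
_STREAM_SPECIES = 2


@dataclass
class _Founder:
    founder_id: str
    group_id: str
    nblrr_class: str
    archetype: str
    motif_ids: list[str]  # NB motifs in planted order
    motif_coords: list[tuple[int, int]]  # 1-based in archetype
    domain_coords: dict[str, tuple[int, int]]
    nb_region: tuple[int, int]


def _max_cross_identity(a: str, b: str) -> int:
    """Maximum positional identity between two strings over all offsets."""
    best = 0
    for off in range(-(len(a) - 1), len(b)):
        matches = sum(
            1 for i in range(len(a))
            if 0 <= i + off < len(b) and a[i] == b[i + off]
        )
        best = max(best, matches)
    return best


def _draw_distinct(
    rng: np.random.Generator, width: int, existing: list[str]
) -> str:
    """Draw a random consensus rejected until it is dissimilar from every
    existing planted block.  Without this, a chance near-match between two
    planted blocks makes the planted truth ambiguous (the same pattern
    occurs in two places by construction)."""
    threshold = max(4, -(-2 * width // 5))  # ceil(0.4 * width)
    for _ in range(200):
        cand = random_protein(rng, width)
        if all(_max_cross_identity(cand, other) < threshold for other in existing):
            return cand
    raise ConfigError("motif_width: cannot draw mutually distinct motifs")


def draw_distinct_motifs(
    rng: np.random.Generator, n: int, width: int, ids_from: int = 1
) -> dict[str, str]:
    """A registry of n mutually dissimilar motif consensi (M{k}, ...)."""
    out: dict[str, str] = {}
    for i in range(n):
        out[f"M{ids_from + i}"] = _draw_distinct(rng, width, list(out.values()))
    return out


def _build_registry(cfg: CohortConfig, rng: np.random.Generator):
    """Draw the motif consensus registry and per-class motif orders."""
    lo, hi = cfg._width_range
    registry: dict[str, str] = {}
    # domain segments first, then motifs, each rejected against all earlier
    # blocks so no planted pattern occurs twice by accident
    for kind, w in DOMAIN_WIDTHS.items():
        registry[kind] = _draw_distinct(rng, w, list(registry.values()))
    n_specific = {c: cfg.class_specific_motifs.get(c, 0) for c in NBLRR_CLASSES}
    total = cfg.n_core_motifs + sum(n_specific.values())
    widths = rng.integers(lo, hi + 1, size=total)
    for i in range(total):
        registry[f"M{i + 1}"] = _draw_distinct(
            rng, int(widths[i]), list(registry.values())
        )
    core_ids = [f"M{i + 1}" for i in range(cfg.n_core_motifs)]
    specific_ids: dict[str, list[str]] = {}
    nxt = cfg.n_core_motifs
    for cls in NBLRR_CLASSES:
        specific_ids[cls] = [f"M{j + 1}" for j in range(nxt, nxt + n_specific[cls])]
        nxt += n_specific[cls]
    # per-class NB motif order: core order fixed, specific motifs spliced in
    # at evenly spread positions (deterministic given the registry stream)
    class_order: dict[str, list[str]] = {}
    for cls in NBLRR_CLASSES:
        order = list(core_ids)
        spec = specific_ids[cls]
        if spec:
            slots = np.linspace(1, len(order), num=len(spec), dtype=int)
            for off, (slot, mid) in enumerate(zip(slots, spec)):
                order.insert(int(slot) + off, mid)
        class_order[cls] = order
    return registry, class_order


def _build_founder(
    cfg: CohortConfig,
    rng: np.random.Generator,
    registry: dict[str, str],
    class_order: dict[str, list[str]],
    idx: int,
    nblrr_class: str,
) -> _Founder:
    """Assemble a founder archetype from planted blocks; spacers, linkers
    and LRR copy number are founder-specific so unrelated founders share
    only the planted blocks themselves."""
    parts: list[str] = []
    domain_coords: dict[str, tuple[int, int]] = {}

    def append(block: str) -> tuple[int, int]:
        start = sum(len(p) for p in parts) + 1
        parts.append(block)
        return start, start + len(block) - 1

    if nblrr_class != "partial":
        nterm_kind = {"TNL": "TIR", "CNL": "CC", "RNL": "RPW8"}[nblrr_class]
        domain_coords[nterm_kind] = append(registry[nterm_kind])
        append(random_protein(rng, int(rng.integers(8, 16))))
    nb_start = sum(len(p) for p in parts) + 1
    domain_coords["NB"] = append(registry["NB"])
    motif_ids = class_order[nblrr_class]
    motif_block = [registry[m] for m in motif_ids]
    scaffold = random_protein(
        rng, sum(len(m) for m in motif_block) + int(rng.integers(2, 7)) * (len(motif_block) + 1)
    )
    nb_body, rel_coords = plant_motifs(scaffold, motif_block, 0.0, rng)
    body_start = append(nb_body)[0]
    motif_coords = [(body_start + s - 1, body_start + e - 1) for s, e in rel_coords]
    nb_end = body_start + len(nb_body) - 1
    if nblrr_class != "partial":
        n_units = int(rng.integers(3, 6))
        lrr_start = sum(len(p) for p in parts) + 1
        for _ in range(n_units):
            append(registry["LRR"])
        domain_coords["LRR"] = (lrr_start, sum(len(p) for p in parts))
    append(random_protein(rng, int(rng.integers(5, 21))))
    return _Founder(
        founder_id=f"F{idx:04d}",
        group_id=f"OG{idx:04d}",
        nblrr_class=nblrr_class,
        archetype="".join(parts),
        motif_ids=list(motif_ids),
        motif_coords=motif_coords,
        domain_coords=domain_coords,
        nb_region=(nb_start, nb_end),
    )


def _make_copy(
    founder: _Founder,
    cfg: CohortConfig,
    rng: np.random.Generator,
    extra_rate: float = 0.0,
) -> tuple[str, list[str], list[tuple[str, int, int]]]:
    """Instantiate one gene copy of a founder: per-motif dropout (dropped
    blocks are replaced by random residues of equal length, keeping
    coordinates stable) followed by per-residue substitution noise."""
    seq = founder.archetype
    kept_ids: list[str] = []
    occurrences: list[tuple[str, int, int]] = []
    chars = list(seq)
    counter: dict[str, int] = {}
    for mid, (s, e) in zip(founder.motif_ids, founder.motif_coords):
        counter[mid] = counter.get(mid, 0) + 1
        if rng.random() < cfg.motif_dropout_rate:
            chars[s - 1 : e] = list(random_protein(rng, e - s + 1))
        else:
            kept_ids.append(mid)
            occurrences.append((mid, s, e))
    seq = _mutate("".join(chars), cfg.substitution_rate + extra_rate, rng)
    return seq, kept_ids, occurrences


def _draw_from(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return int(keys[rng.choice(len(keys), p=probs)])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a multi-species cohort with planted ground truth.

    Orthogroups follow a star phylogeny: each founder is copied into each
    species with probability ``1 - loss_rate`` at ``substitution_rate``
    divergence; a duplication event (probability ``duplication_rate``)
    adds tandem paralog copies carrying a small amount of extra, recent
    divergence.  Tandem arrays seed physical clusters; additional clusters
    group unrelated NB-LRR genes per the configured size distribution.
    """
    cfg = config
    rng_reg = np.random.default_rng([cfg.seed, _STREAM_REGISTRY])
    registry, class_order = _build_registry(cfg, rng_reg)

    n_per_species = int(round(cfg.genes_per_species * cfg.nblrr_fraction))
    # expected copies per founder per species (loss, then tandem expansion)
    mean_extra = cfg.duplication_rate * (1.0 / 0.6)
    exp_copies = (1.0 - cfg.loss_rate) * (1.0 + mean_extra)
    n_founders = int(round(n_per_species / exp_copies)) if n_per_species else 0

    founders: list[_Founder] = []
    classes = sorted(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    for i in range(n_founders):
        cls = classes[int(rng_reg.choice(len(classes), p=probs))]
        founders.append(_build_founder(cfg, rng_reg, registry, class_order, i + 1, cls))

    truth = TruthTables(
        planted_motifs=dict(registry),
        class_motif_order={c: list(class_order[c]) for c in NBLRR_CLASSES},
    )
    species = [f"sp{i + 1:02d}" for i in range(cfg.n_species)]
    genes: dict[str, list[GeneModel]] = {}

    for si, sp in enumerate(species):
        rng = np.random.default_rng([cfg.seed, _STREAM_SPECIES, si])
        # species differ in their propensity for tandem expansion, creating
        # the family-size spread real repertoires show; this also couples
        # per-species paralog and cluster counts
        dup_rate = min(cfg.duplication_rate * float(rng.uniform(0.05, 2.5)), 0.95)
        # -- which founders are present, and with how many tandem copies
        units: list[list[tuple[_Founder, str, list[str], list[tuple[str, int, int]]]]] = []
        for founder in founders:
            if rng.random() < cfg.loss_rate:
                continue
            n_copies = 1
            if rng.random() < dup_rate:
                n_copies += int(rng.geometric(0.6))
            # the species base copy diverges from the founder at the cohort
            # substitution rate; tandem duplicates are *recent* copies of
            # the base gene, carrying only a fifth of that divergence
            seq, kept, occ = _make_copy(founder, cfg, rng)
            unit = [(founder, seq, kept, occ)]
            for _ in range(n_copies - 1):
                dup = _mutate(seq, cfg.substitution_rate / 5.0, rng)
                unit.append((founder, dup, kept, occ))
            units.append(unit)
        perm = rng.permutation(len(units))
        units = [units[int(i)] for i in perm]

        # -- group units into physical clusters: tandem arrays are clusters
        # by construction; single-copy founders co-cluster only per the
        # configured size distribution
        clusters: list[list] = []
        current: list = []
        target = _draw_from(cfg.cluster_size_distribution, rng)
        for unit in units:
            if len(unit) >= 2:
                clusters.append(list(unit))
                continue
            current.extend(unit)
            if len(current) >= target:
                clusters.append(current)
                current = []
                target = _draw_from(cfg.cluster_size_distribution, rng)
        if current:
            clusters.append(current)
        perm = rng.permutation(len(clusters))
        clusters = [clusters[int(i)] for i in perm]

        n_nblrr = sum(len(c) for c in clusters)
        n_background = max(cfg.genes_per_species - n_nblrr, 0)
        # -- intra-cluster intervening gene counts
        intra = [
            [_draw_from(cfg.intervening_gene_distribution, rng) for _ in range(len(c) - 1)]
            for c in clusters
        ]
        intra_used = sum(sum(x) for x in intra)
        # clusters are assigned whole to chromosomes so a cluster never
        # spans a seqid; the minimum separation of 9 background genes keeps
        # distinct clusters unlinkable at the default intervening rule
        n_chrom = 2 if len(clusters) >= 4 else 1
        chrom_of_cluster = [k * n_chrom // max(len(clusters), 1) for k in range(len(clusters))]
        min_sep = 9
        n_gaps = len(clusters) + n_chrom
        leftover = n_background - intra_used - min_sep * n_gaps
        if leftover < 0:
            # genes_per_species is a target, not a hard cap: the separation
            # guarantee between planted clusters takes precedence, so top up
            # with extra background genes when a species draws many copies
            n_background += -leftover
            leftover = 0
        seps = min_sep + rng.multinomial(leftover, np.full(n_gaps, 1.0 / n_gaps))

        # -- serialize the gene order per chromosome
        order: list[tuple[str, object, int]] = []  # (kind, entry, chrom)
        sep_iter = iter(int(s) for s in seps)
        for chrom in range(1, n_chrom + 1):
            ks = [k for k in range(len(clusters)) if chrom_of_cluster[k] == chrom - 1]
            for k in ks:
                for _ in range(next(sep_iter)):
                    order.append(("bg", None, chrom))
                for j, entry in enumerate(clusters[k]):
                    if j > 0:
                        for _ in range(intra[k][j - 1]):
                            order.append(("bg", None, chrom))
                    order.append(("nblrr", (entry, k), chrom))
            for _ in range(next(sep_iter)):
                order.append(("bg", None, chrom))

        sp_genes: list[GeneModel] = []
        serial = 0
        cluster_members: dict[int, set[str]] = {}
        pos = 1000
        cur_chrom = 1
        for kind, payload, chrom in order:
            if chrom != cur_chrom:
                cur_chrom, pos = chrom, 1000
            serial += 1
            gid = f"{sp}_g{serial:04d}"
            if kind == "bg":
                protein = random_protein(rng, int(rng.integers(150, 601)))
            else:
                entry, k = payload
                founder, protein, kept, occ = entry
                truth.true_class[gid] = founder.nblrr_class
                truth.true_orthogroup[gid] = founder.group_id
                truth.planted_architecture[gid] = kept
                truth.planted_occurrences[gid] = occ
                truth.nb_region[gid] = founder.nb_region
                truth.species_of[gid] = sp
                cluster_members.setdefault(k, set()).add(gid)
            start = pos
            end = start + 3 * len(protein) + int(rng.integers(100, 500))
            pos = end + int(rng.integers(500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            sp_genes.append(
                GeneModel(gene_id=gid, species=sp, seqid=f"{sp}_chr{cur_chrom}",
                          start=start, end=end, strand=strand, protein=protein)
            )
        truth.true_clusters[sp] = [
            cluster_members[k]
            for k in sorted(cluster_members)
            if len(cluster_members[k]) >= 2
        ]
        genes[sp] = sp_genes

    # -- characterized reference proteins: founder archetypes by name
    references: dict[str, str] = {}
    n_ref = min(cfg.n_references, len(founders))
    if n_ref:
        pick = rng_reg.choice(len(founders), size=n_ref, replace=False)
        for j, fi in enumerate(sorted(int(x) for x in pick), 1):
            f = founders[fi]
            rid = f"RefR{j}"
            references[rid] = f.archetype
            truth.reference_group[rid] = f.group_id
    return Cohort(config=cfg, species=species, genes=genes, truth=truth,
                  references=references)
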