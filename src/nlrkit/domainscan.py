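"""NB-LRR candidate identification and protein-class assignment.

Plant R proteins are recognized by their domain architecture: an N-terminal
signalling domain (TIR, coiled-coil or RPW8), a central nucleotide-binding
(NB-ARC) domain, and C-terminal leucine-rich repeats.  This module reads
proteomes (FASTA) and gene models (GFF3), scans proteins with ungapped
log-odds profiles for those domains (or ingests precomputed domain-hit
tables in InterProScan tabular format), and classifies each gene as
TNL / CNL / RNL / NL / N / other from the coordinate-ordered architecture
of its hits.

Coordinates are 1-based inclusive throughout, matching GFF3 and
InterProScan conventions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

from .scoring import ProfileModel, encode, scan_sequence
from .scoring import build_pssm  # re-exported; construction lives in scoring

__all__ = [
    "GeneModel",
    "DomainHit",
    "ClassifiedGene",
    "FormatError",
    "read_fasta",
    "read_gff3",
    "join_models",
    "read_domain_hits",
    "build_pssm",
    "scan_proteome",
    "classify_architecture",
    "classify_genes",
    "write_classification_tsv",
    "write_hits_tsv",
]

logger = logging.getLogger(__name__)

#: Default mapping from external signature accessions to internal domain kinds.
#: PF00931 is the Pfam NB-ARC domain; the remaining entries cover the common
#: TIR / LRR / RPW8 / coiled-coil signatures seen in InterProScan output.
DEFAULT_SIGNATURE_KINDS = {
    "PF00931": "NB",
    "PF01582": "TIR",
    "PF05659": "RPW8",
    "PF18052": "CC",
    "PF00560": "LRR",
    "PF13306": "LRR",
    "PTHR11017:SF191": "LRR",
    "G3DSA:1.10.8.430": "NB",
    "SSF52540": "NB",
}

N_TERMINAL_KINDS = ("RPW8", "TIR", "CC")


class FormatError(ValueError):
    """Raised for malformed FASTA/GFF3/TSV input."""


@dataclass
class GeneModel:
    """A gene: genomic coordinates plus its protein product."""

    gene_id: str
    species: str = ""
    seqid: str = ""
    start: int = 0
    end: int = 0
    strand: str = "."
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start and self.end and self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class DomainHit:
    """A scored interval of a protein matched by a domain or motif profile."""

    gene_id: str
    profile_id: str
    kind: str
    start: int  # 1-based inclusive protein coordinate
    end: int
    score: float  # bits
    evalue: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"hit {self.profile_id}@{self.gene_id}: start > end")
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ClassifiedGene:
    gene_id: str
    class_label: str  # TNL, CNL, RNL, NL, N, other
    supporting_hits: list[DomainHit] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# input parsing


def read_fasta(source: str | Path | TextIO) -> dict[str, str]:
    """Read a protein FASTA into {record id: sequence}.

    Duplicate ids are a format error; an empty file returns an empty dict
    with a warning.
    """
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        payloads: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in payloads:
                raise FormatError(f"duplicate FASTA id {rec.id!r}")
            payloads[rec.id] = str(rec.seq).upper()
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if not payloads:
        logger.warning("empty FASTA input")
    return payloads


def read_gff3(source: str | Path | TextIO) -> dict[str, GeneModel]:
    """Read gene features from a GFF3 stream into {gene id: GeneModel}.

    Only ``gene`` features are considered; coordinates are validated
    (1-based, start <= end) and violations are rejected with the offending
    line number.
    """
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        models: dict[str, GeneModel] = {}
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"GFF3 line {lineno}: expected 9 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"GFF3 line {lineno}: non-integer coordinates")
            if start < 1 or end < start:
                raise FormatError(
                    f"GFF3 line {lineno}: invalid interval {start}..{end}"
                )
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attributes.get("ID")
            if gene_id is None:
                raise FormatError(f"GFF3 line {lineno}: gene feature without ID=")
            if gene_id in models:
                raise FormatError(f"GFF3 line {lineno}: duplicate gene ID {gene_id!r}")
            models[gene_id] = GeneModel(
                gene_id=gene_id, seqid=seqid, start=start, end=end,
                strand=strand if strand in "+-." else ".",
            )
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return models


def join_models(
    fasta_payloads: dict[str, str],
    gff3_payloads: dict[str, GeneModel],
    species: str = "",
) -> tuple[list[GeneModel], list[str]]:
    """Join protein payloads onto gene coordinates by shared id.

    Returns the joined GeneModels (in GFF3 order) plus the list of
    unmatched ids from either side.
    """
    joined = []
    for gene_id, model in gff3_payloads.items():
        if gene_id in fasta_payloads:
            joined.append(
                GeneModel(
                    gene_id=gene_id,
                    species=species or model.species,
                    seqid=model.seqid,
                    start=model.start,
                    end=model.end,
                    strand=model.strand,
                    protein=fasta_payloads[gene_id],
                )
            )
    matched = {g.gene_id for g in joined}
    unmatched = sorted(
        (set(fasta_payloads) | set(gff3_payloads)) - matched
    )
    if unmatched:
        logger.warning("join_models: %d unmatched ids", len(unmatched))
    return joined, unmatched


_IPS_COLUMNS = [
    "accession", "md5", "length", "analysis", "signature", "description",
    "start", "stop", "score", "status", "date", "interpro_id", "interpro_desc",
]


def read_domain_hits(
    source: str | Path | TextIO,
    dialect: str = "interproscan-tsv",
    signature_kinds: dict[str, str] | None = None,
) -> list[DomainHit]:
    """Ingest a precomputed domain-hit table.

    ``interproscan-tsv`` expects the 13-column InterProScan layout
    (accession, md5, length, analysis, signature, description, start, stop,
    score, status, date, interpro id, interpro description); ``generic``
    expects columns gene_id, profile_id, kind, start, end, score, evalue.
    Signatures absent from the signature→kind table map to kind ``other``
    with a warning.
    """
    if dialect not in ("interproscan-tsv", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    kinds = dict(DEFAULT_SIGNATURE_KINDS)
    if signature_kinds:
        kinds.update(signature_kinds)
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        hits: list[DomainHit] = []
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if dialect == "generic":
                gene_id, profile_id, kind, start, end, score, evalue = row[:7]
                hits.append(
                    DomainHit(gene_id, profile_id, kind, int(start), int(end),
                              float(score), float(evalue))
                )
                continue
            if len(row) < 9:
                raise FormatError(
                    f"interproscan-tsv row with {len(row)} columns (need >= 9)"
                )
            rec = dict(zip(_IPS_COLUMNS, row))
            signature = rec["signature"]
            kind = kinds.get(signature)
            if kind is None:
                logger.warning("unmapped signature %s -> kind 'other'", signature)
                kind = "other"
            try:
                score = float(rec["score"])
            except ValueError:
                score = float("nan")
            hits.append(
                DomainHit(
                    gene_id=rec["accession"],
                    profile_id=signature,
                    kind=kind,
                    start=int(rec["start"]),
                    end=int(rec["stop"]),
                    score=0.0,
                    # InterProScan's score column is an e-value for most analyses
                    evalue=max(score, 0.0) if score == score else 0.0,
                )
            )
        return hits
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


# ---------------------------------------------------------------------------
# scanning


def _merge_overlapping(hits: list[DomainHit]) -> list[DomainHit]:
    """Reduce same-profile hits overlapping >= 50% of the shorter hit to the
    best-scoring one."""
    out: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.start)):
        merged = False
        for kept in out:
            ov = min(hit.end, kept.end) - max(hit.start, kept.start) + 1
            if ov > 0 and ov >= 0.5 * min(hit.length, kept.length):
                merged = True  # kept has >= score by sort order
                break
        if not merged:
            out.append(hit)
    return sorted(out, key=lambda h: h.start)


def scan_proteome(
    genes: Iterable[GeneModel],
    profiles: Iterable[ProfileModel],
    evalue_max: float = 1e-2,
) -> list[DomainHit]:
    """Slide every profile over every protein and return thresholded hits.

    Hit p-values come from the exact background score-distribution DP; the
    e-value is p times the number of windows scanned in that protein.
    Overlapping hits of the same profile are reduced to the best-scoring
    one.  Proteins shorter than a profile are skipped for that profile.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    profiles = list(profiles)
    all_hits: list[DomainHit] = []
    for gene in genes:
        if not gene.protein:
            continue
        enc = encode(gene.protein)
        for profile in profiles:
            if enc.size < profile.width:
                logger.debug(
                    "%s shorter than profile %s; skipped",
                    gene.gene_id, profile.profile_id,
                )
                continue
            windows = scan_sequence(enc, profile, evalue_max=evalue_max)
            hits = [
                DomainHit(
                    gene_id=gene.gene_id,
                    profile_id=profile.profile_id,
                    kind=profile.kind,
                    start=w.start + 1,
                    end=w.start + profile.width,
                    score=w.score_bits,
                    evalue=w.evalue,
                )
                for w in windows
            ]
            all_hits.extend(_merge_overlapping(hits))
    return all_hits


# ---------------------------------------------------------------------------
# classification


def classify_architecture(hits: Iterable[DomainHit]) -> ClassifiedGene:
    """Assign a protein class from the coordinate-ordered domain architecture.

    Rules: an NB hit is required for any NB-LRR label.  With NB + LRR the
    N-terminal kind decides TNL (TIR), CNL (CC) or RNL (RPW8); NB + LRR
    without a recognized N-terminus is NL; NB alone (including TIR+NB
    truncations) is the N-containing partial label ``N``; anything else is
    ``other``.  The N-terminal hit must start before the NB hit, and the
    LRR hit must start after it.  When several N-terminal kinds hit one
    gene the best-scoring one wins, ties broken RPW8 > TIR > CC (the rarest,
    most specific signature first); equal-kind ambiguity is flagged.
    """
    hits = list(hits)
    gene_ids = {h.gene_id for h in hits}
    if len(gene_ids) > 1:
        raise ValueError(f"hits from multiple genes: {sorted(gene_ids)}")
    gene_id = gene_ids.pop() if gene_ids else ""
    flags: list[str] = []

    def best(kind: str) -> DomainHit | None:
        cands = [h for h in hits if h.kind == kind]
        return max(cands, key=lambda h: h.score) if cands else None

    nb = best("NB")
    if nb is None:
        return ClassifiedGene(gene_id, "other", hits, flags)

    lrr = best("LRR")
    if lrr is not None and lrr.start <= nb.start:
        lrr = None  # LRR is C-terminal of NB by architecture

    nterm_candidates = [
        h for h in hits if h.kind in N_TERMINAL_KINDS and h.start < nb.start
    ]
    nterm = None
    if nterm_candidates:
        prec = {k: i for i, k in enumerate(N_TERMINAL_KINDS)}
        nterm_candidates.sort(key=lambda h: (-h.score, prec[h.kind]))
        nterm = nterm_candidates[0]
        tied = [
            h for h in nterm_candidates[1:]
            if h.score == nterm.score and h.kind != nterm.kind
        ]
        if tied:
            flags.append("ambiguous-n-terminus")
        if len({h.kind for h in nterm_candidates}) > 1:
            flags.append("multiple-n-terminal-kinds")

    if lrr is None:
        label = "N"
    elif nterm is None:
        label = "NL"
    else:
        label = {"TIR": "TNL", "CC": "CNL", "RPW8": "RNL"}[nterm.kind]
    supporting = [h for h in (nterm, nb, lrr) if h is not None]
    return ClassifiedGene(gene_id, label, supporting or hits, flags)


def classify_genes(
    genes: Iterable[GeneModel], hits: Iterable[DomainHit]
) -> dict[str, ClassifiedGene]:
    """Classify every gene from its own hits (genes without hits → other)."""
    by_gene: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_gene.setdefault(hit.gene_id, []).append(hit)
    out = {}
    for gene in genes:
        out[gene.gene_id] = classify_architecture(by_gene.get(gene.gene_id, []))
        out[gene.gene_id].gene_id = gene.gene_id
    return out


# ---------------------------------------------------------------------------
# output


def write_classification_tsv(
    path: str | Path,
    classified: dict[str, ClassifiedGene],
    species_of: dict[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies\tclass\tn_hits\n")
        for gene_id in sorted(classified):
            cg = classified[gene_id]
            sp = (species_of or {}).get(gene_id, "")
            fh.write(f"{gene_id}\t{sp}\t{cg.class_label}\t{len(cg.supporting_hits)}\n")


def write_hits_tsv(path: str | Path, hits: Iterable[DomainHit]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tprofile_id\tkind\tstart\tend\tscore_bits\tevalue\n")
        for h in sorted(hits, key=lambda h: (h.gene_id, h.start, h.profile_id)):
            fh.write(
                f"{h.gene_id}\t{h.profile_id}\t{h.kind}\t{h.start}\t{h.end}\t"
                f"{h.score:.2f}\t{h.evalue:.3g}\n"
            )
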