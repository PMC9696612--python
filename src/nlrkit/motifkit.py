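"""Ungapped motif decomposition of NB domains.

NB-ARC domains carry an ordered vocabulary of short conserved motifs
(P-loop/Walker A, RNBS-A–D, Walker B, GLPL, MHD, ...).  This module
rediscovers such a vocabulary de novo: expectation-maximization fits one
position weight matrix at a time to a set of protein sequences, discovered
occurrences are probabilistically erased, and the procedure repeats until
the requested number of motifs is found or new candidates drop below a
significance floor calibrated on shuffled sequences.  Motifs are named
M1, M2, ... in discovery order; when a motif occurs more than once in a
sequence its occurrences get letter suffixes in coordinate order (M6a,
M6b, ...), and lettered labels are distinct columns of the binary
presence/absence matrix.

The site model is "any number of occurrences per sequence" by default
(repeated motifs are real in this family); a zero-or-one-per-sequence
model is available.  Rescanning uses the exact-p-value machinery from
:mod:`nlrkit.scoring`, so occurrence p-values are exact under the
background model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    ALPHABET,
    ALPHABET_SIZE,
    ProfileModel,
    encode,
    pssm_from_pwm,
    scan_sequence,
    uniform_background,
)

__all__ = [
    "MotifModel",
    "MotifOccurrence",
    "ArchitectureString",
    "NB_MOTIF_LEXICON",
    "discover_motifs",
    "scan_motifs",
    "scan_collection",
    "name_occurrences",
    "presence_matrix",
    "conserved_and_specific",
    "write_meme_minimal",
    "write_architectures_tsv",
    "write_occurrences_tsv",
]

logger = logging.getLogger(__name__)

#: Canonical NB-ARC motif names in their N→C order; an optional mapping of
#: discovered motif ids onto these names is user input.
NB_MOTIF_LEXICON = (
    "hhGRExE",
    "P-loop (Walker A)",
    "RNBS-A",
    "kinase 2 (Walker B)",
    "kinase 3a",
    "RNBS-B",
    "RNBS-C",
    "GLPL",
    "RNBS-D",
    "MHD",
)


@dataclass
class MotifModel:
    """One discovered ungapped motif (probability PWM)."""

    motif_id: str
    pwm: np.ndarray  # (width, 20), columns sum to 1
    e_value_like_score: float = 0.0
    background: np.ndarray | None = None
    nsites: float = 0.0
    lexicon_name: str | None = None
    _profile: ProfileModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        sums = self.pwm.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in np.argmax(self.pwm, axis=1))

    def profile(self) -> ProfileModel:
        """Log-odds profile for rescanning (cached)."""
        if self._profile is None:
            bg = self.background if self.background is not None else uniform_background()
            self._profile = pssm_from_pwm(
                self.pwm, background=bg, profile_id=self.motif_id, kind="motif"
            )
        return self._profile


@dataclass(frozen=True)
class MotifOccurrence:
    gene_id: str
    motif_id: str
    letter_suffix: str  # "" or "a".."z"
    start: int  # 1-based inclusive
    end: int
    match_p: float

    @property
    def label(self) -> str:
        return self.motif_id + self.letter_suffix


@dataclass
class ArchitectureString:
    gene_id: str
    labels: list[str] = field(default_factory=list)  # ascending start order

    def __str__(self) -> str:
        return ", ".join(self.labels)


# ---------------------------------------------------------------------------
# discovery


class _WindowIndex:
    """All length-w windows of a sequence set, with sequence bookkeeping."""

    def __init__(self, encoded: list[np.ndarray], w: int):
        mats, seq_ids, starts, offsets = [], [], [], [0]
        for si, enc in enumerate(encoded):
            n = enc.size - w + 1
            if n > 0:
                from numpy.lib.stride_tricks import sliding_window_view

                mats.append(sliding_window_view(enc, w))
                seq_ids.append(np.full(n, si))
                starts.append(np.arange(n))
            offsets.append(offsets[-1] + max(n, 0))
        if not mats:
            raise ValueError(f"no sequence long enough for width {w}")
        self.X = np.ascontiguousarray(np.concatenate(mats)).astype(np.int64)
        self.seq_id = np.concatenate(seq_ids)
        self.start = np.concatenate(starts)
        self.offsets = np.array(offsets)
        self.w = w
        self.n = self.X.shape[0]

    def erase_factor(self, pos_weight: list[np.ndarray]) -> np.ndarray:
        """Per-window erasure discount: min remaining weight over covered
        positions."""
        f = np.empty(self.n)
        k = 0
        for si, pw in enumerate(pos_weight):
            n = pw.size - self.w + 1
            if n <= 0:
                continue
            from numpy.lib.stride_tricks import sliding_window_view

            f[k : k + n] = sliding_window_view(pw, self.w).min(axis=1)
            k += n
        return f


def _estimate_background(encoded: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(ALPHABET_SIZE)  # +1 smoothing
    for enc in encoded:
        counts += np.bincount(enc[enc < ALPHABET_SIZE], minlength=ALPHABET_SIZE)
    return counts / counts.sum()


def _em_fit(
    win: _WindowIndex,
    f: np.ndarray,
    seed_window: np.ndarray,
    background: np.ndarray,
    n_expected_sites: float,
    model: str,
    tol: float,
    max_iter: int,
):
    """Fit one PWM by EM from a seed window.

    The erasure factor ``f`` enters as a fixed per-window site-likelihood
    discount, so the marginal objective
    ``J = sum_i log((1-q) + q * f_i * L_i)`` (ANR) is non-decreasing under
    the updates.  Returns (pwm, q, Z, sig_bits, objective_trace).
    """
    w, n = win.w, win.n
    X = win.X
    # sharp seed init keeps EM in the seed motif's basin: a soft start lets
    # an unrelated motif that shares a handful of residues with the seed
    # bleed into the PWM and converge to a merged two-motif solution
    pwm = np.full((w, ALPHABET_SIZE), 0.15 / (ALPHABET_SIZE - 1))
    pwm[np.arange(w), seed_window] = 0.85
    q = min(n_expected_sites / n, 0.4)
    log_bg = np.log(background)
    prev_J = -np.inf
    trace: list[float] = []
    Z = np.zeros(n)
    for _ in range(max_iter):
        log_ratio = np.log(np.maximum(pwm, 1e-300)) - log_bg[None, :]
        llr = log_ratio[np.arange(w)[:, None], X.T].sum(axis=0)  # (n,)
        fL = f * np.exp(np.minimum(llr, 700.0))
        if model == "anr":
            site = q * fL
            Z = site / (site + (1.0 - q))
            J = float(np.sum(np.log(site + (1.0 - q))))
        else:  # zoops: one site at most per sequence, uniform over windows
            seq_idx = win.seq_id
            m_i = np.diff(win.offsets)[seq_idx]
            site_i = q * fL / np.maximum(m_i, 1)
            denom = (1.0 - q) + np.add.reduceat(site_i, win.offsets[:-1])[seq_idx]
            Z = site_i / denom
            J = float(
                np.sum(np.log((1.0 - q) + np.add.reduceat(site_i, win.offsets[:-1])))
            )
        trace.append(J)
        # M-step
        total = Z.sum()
        counts = np.empty((w, ALPHABET_SIZE))
        for j in range(w):
            counts[j] = np.bincount(X[:, j], weights=Z, minlength=ALPHABET_SIZE)[
                :ALPHABET_SIZE
            ]
        beta = 0.1
        pwm = (counts + beta * background[None, :]) / (total + beta)
        pwm /= pwm.sum(axis=1, keepdims=True)
        if model == "anr":
            q = min(max(total / n, 1e-9), 0.4)
        else:
            q = min(max(total / len(win.offsets[:-1]), 1e-9), 0.999)
        if J - prev_J < tol * (1.0 + abs(J)) and len(trace) > 2:
            prev_J = J
            break
        prev_J = J
    sig_bits = float(np.sum(Z * np.maximum(llr, 0.0)) / np.log(2.0))
    return pwm, q, Z, sig_bits, trace


def _pick_seeds(
    win: _WindowIndex,
    f: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int,
    n_starts: int,
) -> list[int]:
    """Sample candidate windows (weighted by erasure) and rank them by how
    strongly their exact residues recur across sequences."""
    probs = f / f.sum() if f.sum() > 0 else None
    k = min(n_candidates, win.n)
    cand = rng.choice(win.n, size=k, replace=False, p=probs)
    n_seqs = len(win.offsets) - 1
    scores = np.empty(k)
    for ci, c in enumerate(cand):
        matches = (win.X == win.X[c]).sum(axis=1).astype(float) * f
        per_seq = np.maximum.reduceat(matches, win.offsets[:-1])
        scores[ci] = per_seq.sum()
    order = np.argsort(-scores, kind="stable")
    return [int(cand[i]) for i in order[:n_starts]]


def discover_motifs(
    sequences: dict[str, str] | Sequence[str],
    n_motifs: int = 30,
    width_range: tuple[int, int] = (8, 20),
    model: str = "anr",
    n_starts: int = 5,
    seed: int = 0,
    width_step: int | None = None,
    n_candidates: int = 100,
    significance_factor: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    background: np.ndarray | None = None,
) -> list[MotifModel]:
    """Decompose a sequence set into ungapped motifs by iterative EM.

    For each motif: EM runs from ``n_starts`` seeded alignments (the most
    recurrent sampled k-mers) at each candidate width; the width whose
    fitted motif carries the most information relative to a shuffled-
    sequence null wins; discovered occurrences are probabilistically
    erased and the search repeats.  Discovery stops early when the best
    candidate's significance falls below ``significance_factor`` times the
    null significance for its width.

    Returns motifs ordered by discovery rank (M1 first).
    """
    if model not in ("anr", "zoops"):
        raise ValueError(f"unknown site model {model!r}")
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    if len(seqs) < 1:
        raise ValueError("need at least one sequence")
    encoded = [encode(s) for s in seqs]
    rng = np.random.default_rng(seed)
    if background is None:
        background = _estimate_background(encoded)
    lo, hi = width_range
    if hi > min(len(s) for s in seqs):
        hi = min(len(s) for s in seqs)
    if lo > hi:
        raise ValueError("width_range below minimum sequence length is empty")
    if width_step is None:
        width_step = max(1, (hi - lo) // 4)
    widths = list(range(lo, hi + 1, width_step)) or [lo]

    indexes = {w: _WindowIndex(encoded, w) for w in widths}
    n_seqs = len(seqs)

    # significance null: best single-motif fit on residue-shuffled sequences
    null_sig: dict[int, float] = {}
    shuffled = [enc[rng.permutation(enc.size)] for enc in encoded]
    for w in widths:
        if indexes[w].n < 5 * n_seqs:
            # too few windows per sequence: shuffling largely reproduces the
            # signal, so the null carries no information — no floor applied
            null_sig[w] = 0.0
            continue
        swin = _WindowIndex(shuffled, w)
        f0 = np.ones(swin.n)
        seeds = _pick_seeds(swin, f0, rng, min(n_candidates, 50), min(n_starts, 2))
        best = 0.0
        for s in seeds:
            _, _, _, sig, _ = _em_fit(
                swin, f0, swin.X[s], background, n_seqs, model, tol, max_iter
            )
            best = max(best, sig)
        null_sig[w] = best

    pos_weight = [np.ones(enc.size) for enc in encoded]
    motifs: list[MotifModel] = []
    for rank in range(1, n_motifs + 1):
        best_fit = None  # (margin, sig, pwm, Z, w)
        for w in widths:
            win = indexes[w]
            f = win.erase_factor(pos_weight)
            if f.max() < 1e-3:
                continue
            for s in _pick_seeds(win, f, rng, n_candidates, n_starts):
                pwm, q, Z, sig, _ = _em_fit(
                    win, f, win.X[s], background, n_seqs, model, tol, max_iter
                )
                margin = sig - significance_factor * null_sig[w]
                if best_fit is None or margin > best_fit[0]:
                    best_fit = (margin, sig, pwm, Z, w)
        if best_fit is None or best_fit[0] <= 0:
            logger.warning(
                "motif discovery stopped at %d of %d motifs (significance floor)",
                rank - 1, n_motifs,
            )
            break
        _, sig, pwm, Z, w = best_fit
        win = indexes[w]
        motifs.append(
            MotifModel(
                motif_id=f"M{rank}",
                pwm=pwm,
                e_value_like_score=sig,
                background=background,
                nsites=float(Z.sum()),
            )
        )
        # probabilistic erasure of discovered occurrences
        strong = np.nonzero(Z > 0.01)[0]
        for i in strong:
            si, st = int(win.seq_id[i]), int(win.start[i])
            pos_weight[si][st : st + w] *= 1.0 - float(Z[i])
    return motifs


# ---------------------------------------------------------------------------
# rescanning and architectures


def scan_motifs(
    sequence: str,
    motifs: Iterable[MotifModel],
    p_max: float = 1e-4,
    gene_id: str = "",
) -> list[MotifOccurrence]:
    """Find motif occurrences in one sequence at exact position p-values.

    Occurrences with p <= ``p_max`` are kept; overlaps (within and across
    motifs) are resolved greedily best-p-first, ties by start then motif
    id.  Letter suffixes are then assigned per gene by
    :func:`name_occurrences` ordering rules.
    """
    raw: list[MotifOccurrence] = []
    for motif in motifs:
        prof = motif.profile()
        for hit in scan_sequence(sequence, prof, p_max=p_max):
            raw.append(
                MotifOccurrence(
                    gene_id=gene_id,
                    motif_id=motif.motif_id,
                    letter_suffix="",
                    start=hit.start + 1,
                    end=hit.start + motif.width,
                    match_p=hit.pvalue,
                )
            )
    raw.sort(key=lambda o: (o.match_p, o.start, o.motif_id))
    kept: list[MotifOccurrence] = []
    for occ in raw:
        if all(occ.end < k.start or occ.start > k.end for k in kept):
            kept.append(occ)
    kept.sort(key=lambda o: o.start)
    return _letter(kept)


def _letter(occurrences: list[MotifOccurrence]) -> list[MotifOccurrence]:
    """Assign per-gene letter suffixes (a, b, ... in coordinate order) to
    motifs occurring more than once; single occurrences keep the bare id."""
    counts: dict[str, int] = {}
    for o in occurrences:
        counts[o.motif_id] = counts.get(o.motif_id, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for o in occurrences:
        if counts[o.motif_id] > 1:
            k = seen.get(o.motif_id, 0)
            if k >= 26:
                raise ValueError(f"more than 26 occurrences of {o.motif_id}")
            suffix = chr(ord("a") + k)
            seen[o.motif_id] = k + 1
        else:
            suffix = ""
        out.append(
            MotifOccurrence(o.gene_id, o.motif_id, suffix, o.start, o.end, o.match_p)
        )
    return out


def scan_collection(
    sequences: dict[str, str],
    motifs: Iterable[MotifModel],
    p_max: float = 1e-4,
) -> dict[str, list[MotifOccurrence]]:
    motifs = list(motifs)
    return {
        gid: scan_motifs(seq, motifs, p_max=p_max, gene_id=gid)
        for gid, seq in sequences.items()
    }


def name_occurrences(occurrences: Iterable[MotifOccurrence]) -> ArchitectureString:
    """Build the ordered architecture string of one gene's occurrences."""
    occs = sorted(occurrences, key=lambda o: o.start)
    gene_ids = {o.gene_id for o in occs}
    if len(gene_ids) > 1:
        raise ValueError(f"occurrences from multiple genes: {sorted(gene_ids)}")
    for prev, nxt in zip(occs, occs[1:]):
        if nxt.start <= prev.end:
            raise RuntimeError(
                f"unresolved overlap between {prev.label} and {nxt.label}"
            )
    relettered = _letter(
        [MotifOccurrence(o.gene_id, o.motif_id, "", o.start, o.end, o.match_p)
         for o in occs]
    )
    return ArchitectureString(
        gene_id=gene_ids.pop() if gene_ids else "",
        labels=[o.label for o in relettered],
    )


def _label_key(label: str) -> tuple[int, str]:
    num = "".join(c for c in label[1:] if c.isdigit())
    suffix = label[1 + len(num):]
    return (int(num), suffix)


def presence_matrix(architectures: Iterable[ArchitectureString]) -> pd.DataFrame:
    """Genes × motif-label binary matrix; lettered variants are distinct
    columns (M28a is not M28b)."""
    archs = list(architectures)
    gene_ids = [a.gene_id for a in archs]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids among architectures")
    labels = sorted({lab for a in archs for lab in a.labels}, key=_label_key)
    mat = pd.DataFrame(0, index=gene_ids, columns=labels, dtype=int)
    for a in archs:
        for lab in a.labels:
            mat.loc[a.gene_id, lab] = 1
    return mat


def conserved_and_specific(
    matrix: pd.DataFrame,
    class_of: dict[str, str],
    min_prevalence: float = 1.0,
    max_other_prevalence: float = 0.0,
) -> tuple[list[str], dict[str, list[str]]]:
    """Core and class-specific motif sets from a presence matrix.

    Core motifs are present in (at least ``min_prevalence`` of) all genes;
    a class-specific motif is present in >= ``min_prevalence`` of one
    class's genes and in <= ``max_other_prevalence`` of every other
    class's.  Defaults are the strict all/none calls.
    """
    classes = sorted(set(class_of.values()))
    prevalence = {}
    for cls in classes:
        rows = [g for g in matrix.index if class_of.get(g) == cls]
        prevalence[cls] = matrix.loc[rows].mean(axis=0) if rows else None
    core = [
        lab for lab in matrix.columns
        if float(matrix[lab].mean()) >= min_prevalence
    ]
    specific: dict[str, list[str]] = {}
    for cls in classes:
        if prevalence[cls] is None:
            specific[cls] = []
            continue
        cols = []
        for lab in matrix.columns:
            if prevalence[cls][lab] < min_prevalence:
                continue
            others_ok = all(
                prevalence[o] is None or prevalence[o][lab] <= max_other_prevalence
                for o in classes if o != cls
            )
            if others_ok:
                cols.append(lab)
        specific[cls] = cols
    return core, specific


# ---------------------------------------------------------------------------
# output


def write_meme_minimal(
    path: str | Path, motifs: Iterable[MotifModel], background: np.ndarray | None = None
) -> None:
    """Write motifs in MEME minimal text format."""
    motifs = list(motifs)
    if background is None and motifs and motifs[0].background is not None:
        background = motifs[0].background
    if background is None:
        background = uniform_background()
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + ALPHABET + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{a} {f:.5f}" for a, f in zip(ALPHABET, background)) + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= {ALPHABET_SIZE} "
                f"w= {m.width} nsites= {m.nsites:.1f} E= {2.0 ** -m.e_value_like_score:.2e}\n"
            )
            for row in m.pwm:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def write_architectures_tsv(
    path: str | Path, architectures: Iterable[ArchitectureString]
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tarchitecture\n")
        for a in sorted(architectures, key=lambda a: a.gene_id):
            fh.write(f"{a.gene_id}\t{','.join(a.labels)}\n")


def write_occurrences_tsv(
    path: str | Path, occurrences_by_gene: dict[str, list[MotifOccurrence]]
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\tmotif_id\tstart\tend\tmatch_p\n")
        for gid in sorted(occurrences_by_gene):
            for o in occurrences_by_gene[gid]:
                fh.write(
                    f"{gid}\t{o.label}\t{o.motif_id}\t{o.start}\t{o.end}\t{o.match_p:.3g}\n"
                )
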