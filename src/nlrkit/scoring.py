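"""Ungapped position-specific scoring: PSSM construction, sliding-window
scanning and exact p-values.

This module is the shared numerical core for domain scanning and motif
rescanning.  A profile is an ungapped log-odds matrix over the 20 standard
amino acids.  Scores are expressed in bits and discretized to fixed-width
bins (default 1/100 bit) so that the null score distribution of a profile —
the distribution of window scores under the background model — can be
computed *exactly* by dynamic programming over the per-column score
distributions.  Window p-values are then survival-function lookups, and
e-values follow as p times the number of windows scanned.

Because the same discretized scores are used both for scanning and for the
null DP, the reported p-values agree exactly with exhaustive enumeration
over all length-w words (see the test suite, which checks this on a reduced
alphabet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: The 20 standard amino acids, in alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SIZE = len(ALPHABET)
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Robinson & Robinson amino-acid background frequencies (renormalized),
#: the conventional null model for protein profile scanning.
ROBINSON_BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
ROBINSON_BACKGROUND = ROBINSON_BACKGROUND / ROBINSON_BACKGROUND.sum()

#: Default score bin width for exact p-value DP, in bits.
SCORE_BIN_BITS = 0.01


def uniform_background() -> np.ndarray:
    return np.full(ALPHABET_SIZE, 1.0 / ALPHABET_SIZE)


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as int8 indices into ALPHABET.

    Residues outside the 20-letter alphabet (X, B, Z, ...) map to index 20,
    a neutral wildcard that scores 0 in every profile column.
    """
    lut = np.full(128, ALPHABET_SIZE, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
        lut[ord(aa.lower())] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[arr]


@dataclass
class ProfileModel:
    """An ungapped log-odds profile (PSSM).

    Parameters
    ----------
    profile_id : str
        Identifier, e.g. ``"NB"`` or ``"M7"``.
    kind : str
        One of ``NB, LRR, TIR, CC, RPW8, motif``.
    matrix : ndarray of shape (width, 20)
        Log-odds scores in bits.
    background : ndarray of shape (20,)
        Background residue frequencies; must sum to 1.
    pseudocount : float
        Total pseudocount used at construction time (informational).
    """

    profile_id: str
    kind: str
    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0

    # derived, filled in __post_init__
    int_matrix: np.ndarray = field(init=False, repr=False)
    _sf: np.ndarray = field(init=False, repr=False)
    _sf_min: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != ALPHABET_SIZE:
            raise ValueError("profile matrix must have shape (width, 20)")
        if self.width < 3:
            raise ValueError("profile width must be >= 3")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        # Discretized scores; a 21st wildcard column scores 0.
        ints = np.rint(self.matrix / SCORE_BIN_BITS).astype(np.int64)
        self.int_matrix = np.concatenate(
            [ints, np.zeros((self.width, 1), dtype=np.int64)], axis=1
        )
        self._sf, self._sf_min = _null_survival(ints, self.background)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in np.argmax(self.matrix, axis=1))

    @property
    def max_score(self) -> float:
        """Sum of per-column maxima, in bits."""
        return float(self.matrix.max(axis=1).sum())

    def pvalue(self, score_bits: float) -> float:
        """Exact P(window score >= score) under the background model."""
        return self.pvalue_int(int(np.rint(score_bits / SCORE_BIN_BITS)))

    def pvalue_int(self, int_score: int) -> float:
        idx = int_score - self._sf_min
        if idx <= 0:
            return 1.0
        if idx >= self._sf.size:
            return 0.0
        return float(self._sf[idx])


def _null_survival(int_matrix: np.ndarray, background: np.ndarray):
    """Exact distribution of the discretized window score under background.

    Classic column-by-column convolution: the support is the integer range
    [sum of column minima, sum of column maxima]; each column contributes a
    20-point distribution.  Returns (sf, min_score) with
    sf[s - min_score] = P(S >= s).
    """
    lo = int(int_matrix.min(axis=1).sum())
    hi = int(int_matrix.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    # running support starts at 0 before any column
    offset = 0  # current distribution is over [offset, ...]
    cur = np.array([1.0])
    for j in range(int_matrix.shape[0]):
        col = int_matrix[j]
        clo, chi = int(col.min()), int(col.max())
        new = np.zeros(cur.size + (chi - clo))
        for a in range(ALPHABET_SIZE):
            s = int(col[a]) - clo
            new[s : s + cur.size] += background[a] * cur
        cur = new
        offset += clo
    assert offset == lo and cur.size == hi - lo + 1
    dist[:] = cur
    sf = np.cumsum(dist[::-1])[::-1]
    return sf, lo


def build_pssm(
    block: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    profile_id: str = "profile",
    kind: str = "motif",
) -> ProfileModel:
    """Build a log-odds PSSM from an ungapped alignment block.

    ``matrix[j][a] = log2( (count(a,j) + pc*bg[a]) / (n + pc) / bg[a] )``
    with ``pc`` the total pseudocount distributed by background frequency.
    """
    if len(block) < 2:
        raise ValueError("alignment block needs at least 2 rows")
    widths = {len(row) for row in block}
    if len(widths) != 1:
        raise ValueError(f"ragged alignment block: widths {sorted(widths)}")
    (w,) = widths
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    n = len(block)
    counts = np.zeros((w, ALPHABET_SIZE))
    for row in block:
        enc = encode(row)
        if (enc >= ALPHABET_SIZE).any():
            bad = row[int(np.argmax(enc >= ALPHABET_SIZE))]
            raise ValueError(f"non-standard residue {bad!r} in alignment block")
        counts[np.arange(w), enc] += 1.0
    freqs = (counts + pseudocount * background) / (n + pseudocount)
    matrix = np.log2(freqs / background)
    return ProfileModel(
        profile_id=profile_id,
        kind=kind,
        matrix=matrix,
        background=background,
        pseudocount=pseudocount,
    )


def pssm_from_pwm(
    pwm: np.ndarray,
    background: np.ndarray | None = None,
    profile_id: str = "profile",
    kind: str = "motif",
    floor: float = 1e-4,
) -> ProfileModel:
    """Turn a probability PWM (columns sum to 1) into a log-odds profile.

    ``floor`` guards log(0) for zero-probability cells.
    """
    pwm = np.asarray(pwm, dtype=float)
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    # letters with zero background probability never occur under the null;
    # they get a large finite penalty instead of -inf so discretization is
    # well defined
    safe_bg = np.where(background > 0, background, 1.0)
    matrix = np.log2(np.maximum(pwm, floor) / safe_bg)
    matrix[:, background <= 0] = -100.0
    return ProfileModel(
        profile_id=profile_id, kind=kind, matrix=matrix, background=background
    )


@dataclass(frozen=True)
class WindowHit:
    """One scoring window of a profile on a sequence (0-based start)."""

    start: int
    score_bits: float
    pvalue: float
    evalue: float


def scan_sequence(
    seq: str | np.ndarray,
    profile: ProfileModel,
    p_max: float | None = None,
    evalue_max: float | None = None,
) -> list[WindowHit]:
    """Slide a profile over a sequence and return thresholded window hits.

    Sequences shorter than the profile width yield no hits.  The e-value of
    a window is its exact p-value times the number of windows scanned in
    this sequence.
    """
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)
    w = profile.width
    n_windows = enc.size - w + 1
    if n_windows <= 0:
        return []
    windows = sliding_window_view(enc, w)
    scores = profile.int_matrix[np.arange(w), windows].sum(axis=1)
    # vectorized survival-function lookup; indices below support → p=1, above → p=0
    idx = scores - profile._sf_min
    pvals = np.ones(n_windows)
    in_range = (idx > 0) & (idx < profile._sf.size)
    pvals[in_range] = profile._sf[idx[in_range]]
    pvals[idx >= profile._sf.size] = 0.0
    evals = pvals * n_windows
    keep = np.ones(n_windows, dtype=bool)
    if p_max is not None:
        keep &= pvals <= p_max
    if evalue_max is not None:
        keep &= evals <= evalue_max
    return [
        WindowHit(int(i), float(scores[i]) * SCORE_BIN_BITS, float(pvals[i]), float(evals[i]))
        for i in np.nonzero(keep)[0]
    ]


def window_scores(seq_enc: np.ndarray, profile: ProfileModel) -> np.ndarray:
    """Discretized window scores (integer bins) for all windows; may be empty."""
    w = profile.width
    if seq_enc.size < w:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(seq_enc, w)
    return profile.int_matrix[np.arange(w), windows].sum(axis=1)
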