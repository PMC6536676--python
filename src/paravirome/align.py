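"""Deterministic Smith-Waterman local alignment with Karlin-Altschul statistics.

This is the computational substrate for the protein similarity networks
and the nucleotide ribbon comparison: exact affine-gap (Gotoh) dynamic
programming, no seeding heuristics.  Scores are turned into bit scores
via ``bit = (lambda * S - ln K) / ln 2`` and into E-values via the
database-search form ``E = m * n * 2**(-bit)``.

The DP is exact and deterministic: among equal-scoring optima the hit
with the earliest query start, then the earliest subject start, is
reported.  Runtime is O(m * n) per pair, which is intended for desk
scale (phage proteomes, kilobase-scale genome fragments), not for
database searching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = ["ScoringParams", "AlignmentHit", "local_align", "find_hsps", "evalue", "bit_score"]

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
NUCLEOTIDE_ALPHABET = "ACGT"


def _blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    out = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            out[i, j] = int(m[a, b])
    return out


def _nucleotide_matrix(match: int = 2, mismatch: int = -3) -> np.ndarray:
    n = len(NUCLEOTIDE_ALPHABET)
    out = np.full((n, n), mismatch, dtype=np.int32)
    np.fill_diagonal(out, match)
    return out


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, affine gap penalties, and Karlin-Altschul constants.

    A gap of length k costs ``gap_open + k * gap_extend`` (NCBI
    convention, so the BLASTp-like default 11/1 charges 12 for a
    length-1 gap).  ``karlin_lambda`` and ``karlin_k`` are the gapped
    defaults for the corresponding scoring system; they are tunable,
    not fitted -- threshold behaviour, not parity with any particular
    BLAST build, is the contract.
    """

    alphabet: str
    matrix: np.ndarray = field(repr=False)
    gap_open: int
    gap_extend: int
    karlin_lambda: float
    karlin_k: float

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be > 0")

    @classmethod
    def protein(cls, gap_open: int = 11, gap_extend: int = 1) -> "ScoringParams":
        """BLOSUM62 with BLASTp-like gapped defaults (lambda=0.267, K=0.041)."""
        return cls(PROTEIN_ALPHABET, _blosum62_matrix(), gap_open, gap_extend, 0.267, 0.041)

    @classmethod
    def nucleotide(
        cls,
        match: int = 2,
        mismatch: int = -3,
        gap_open: int = 5,
        gap_extend: int = 2,
    ) -> "ScoringParams":
        """+2/-3 with megablast-like gapped defaults (lambda=0.625, K=0.41)."""
        return cls(NUCLEOTIDE_ALPHABET, _nucleotide_matrix(match, mismatch), gap_open, gap_extend, 0.625, 0.41)

    def encode(self, seq: str, role: str = "sequence") -> np.ndarray:
        if not seq:
            raise ValueError(f"empty {role}")
        lut = {c: i for i, c in enumerate(self.alphabet)}
        out = np.empty(len(seq), dtype=np.int8)
        for i, c in enumerate(seq.upper()):
            code = lut.get(c)
            if code is None:
                raise ValueError(f"invalid residue {c!r} at position {i + 1} of {role}")
            out[i] = code
        return out


@dataclass
class AlignmentHit:
    """One local alignment (1-based inclusive coordinates)."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    alignment_length: int
    identities: int
    identity_percent: float
    query_coverage_percent: float
    raw_score: int
    bit_score: float
    evalue: float
    strand: str | None = None

    def to_tab(self) -> str:
        """BLAST outfmt-6-like row with a trailing query-coverage column."""
        mismatches = self.alignment_length - self.identities  # gaps counted with mismatches
        return "\t".join(
            str(x)
            for x in (
                self.query_id, self.subject_id,
                f"{self.identity_percent:.2f}", self.alignment_length, mismatches, "-",
                self.query_start, self.query_end, self.subject_start, self.subject_end,
                f"{self.evalue:.2e}", f"{self.bit_score:.1f}",
                f"{self.query_coverage_percent:.2f}",
            )
        )


def bit_score(raw_score: float, params: ScoringParams) -> float:
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2.0)


def evalue(bit: float, query_length: int, search_space_length: int) -> float:
    """Karlin-Altschul expect value ``E = m * n * 2**(-bit)``."""
    if query_length < 1 or search_space_length < 1:
        raise ValueError("sequence lengths must be >= 1")
    return float(query_length) * float(search_space_length) * math.exp2(-bit)


@njit(cache=True)
def _sw_fill(q, s, sub, open_cost, ext_cost, s_mask):  # pragma: no cover - numba
    n, m = q.size, s.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.zeros((n + 1, m + 1), dtype=np.int32)  # gap in query (move along subject)
    F = np.zeros((n + 1, m + 1), dtype=np.int32)  # gap in subject (move along query)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    neg = np.int32(-(1 << 29))
    first_gap = open_cost + ext_cost
    best = np.int32(0)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_new = H[i, j - 1] - first_gap
            e_ext = E[i, j - 1] - ext_cost
            if e_ext > e_new:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_new
            f_new = H[i - 1, j] - first_gap
            f_ext = F[i - 1, j] - ext_cost
            if f_ext > f_new:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_new
            if s_mask[j - 1]:
                diag = neg
            else:
                diag = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
    return best, H, ptr, ptrE, ptrF


@njit(cache=True)
def _sw_traceback(q, s, ptr, ptrE, ptrF, i, j):  # pragma: no cover - numba
    """Walk pointers from end cell (i, j); return (qs, qe, ss, se, alen, idents)."""
    qe, se = i, j
    alen = 0
    idents = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == s[j - 1]:
                    idents += 1
                alen += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            alen += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            alen += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    return i + 1, qe, j + 1, se, alen, idents


def _align_encoded(
    q: np.ndarray,
    s: np.ndarray,
    params: ScoringParams,
    s_mask: np.ndarray,
) -> tuple[int, tuple[int, int, int, int, int, int]] | None:
    best, H, ptr, ptrE, ptrF = _sw_fill(
        q, s, params.matrix, np.int32(params.gap_open), np.int32(params.gap_extend), s_mask
    )
    if best <= 0:
        return None
    ends = np.argwhere(H == best)
    chosen = None
    for i, j in ends:
        tb = _sw_traceback(q, s, ptr, ptrE, ptrF, int(i), int(j))
        key = (tb[0], tb[2])  # earliest query start, then earliest subject start
        if chosen is None or key < chosen[0]:
            chosen = (key, tb)
    return int(best), chosen[1]


def _make_hit(
    raw: int,
    tb: tuple[int, int, int, int, int, int],
    query: str,
    params: ScoringParams,
    query_id: str,
    subject_id: str,
    search_space: int,
) -> AlignmentHit:
    qs, qe, ss, se, alen, idents = tb
    bit = bit_score(raw, params)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
        alignment_length=alen,
        identities=idents,
        identity_percent=100.0 * idents / alen,
        query_coverage_percent=100.0 * (qe - qs + 1) / len(query),
        raw_score=raw,
        bit_score=bit,
        evalue=evalue(bit, len(query), search_space),
    )


def local_align(
    query: str,
    subject: str,
    params: ScoringParams,
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: int | None = None,
) -> AlignmentHit | None:
    """Optimal Smith-Waterman local alignment; ``None`` if no positive score.

    ``search_space`` is the n of the E-value formula; it defaults to the
    subject length (single-pair convention).  All-vs-all callers pass
    the total residue count of the subject set instead (database-style
    convention) so that thresholds are reproducible.
    """
    q = params.encode(query, "query")
    s = params.encode(subject, "subject")
    res = _align_encoded(q, s, params, np.zeros(s.size, dtype=np.bool_))
    if res is None:
        return None
    raw, tb = res
    return _make_hit(raw, tb, query, params, query_id, subject_id, search_space or len(subject))


def find_hsps(
    query: str,
    subject: str,
    params: ScoringParams,
    min_raw_score: int,
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: int | None = None,
    max_hsps: int = 64,
) -> list[AlignmentHit]:
    """Greedy non-overlapping HSPs on the subject.

    Report the optimal HSP, mask its subject interval, and repeat until
    the best remaining raw score drops below ``min_raw_score``.
    """
    q = params.encode(query, "query")
    s = params.encode(subject, "subject")
    mask = np.zeros(s.size, dtype=np.bool_)
    hits: list[AlignmentHit] = []
    for _ in range(max_hsps):
        res = _align_encoded(q, s, params, mask)
        if res is None or res[0] < min_raw_score:
            break
        raw, tb = res
        hits.append(_make_hit(raw, tb, query, params, query_id, subject_id, search_space or len(subject)))
        mask[tb[2] - 1 : tb[3]] = True
    return hits
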