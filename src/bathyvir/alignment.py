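"""Comparison primitives: local alignment (nt and aa), Karlin-Altschul
E-values, and maximal exact-match enumeration.

The aligner is a k-mer seeded, window-extended local aligner whose extension
step is an exact affine-gap Smith-Waterman (numba kernel). When the problem
is small enough (query x subject below ``EXACT_CELL_LIMIT`` dynamic-
programming cells) the full exact matrix is computed instead of seeding, so
for read-length queries the reported top score is the optimal local
alignment score.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(both negative), i.e. the first gapped column already pays open + extend.
Identity is matched columns / alignment columns including gap columns;
N (nucleotide) and X (protein) never count as matches.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Optional

import numpy as np
from numba import njit

from .records import revcomp

# ------------------------------------------------------------------ encoding

NT_ALPHABET = "ACGTN"
_NT_LOOKUP = np.full(128, 4, dtype=np.int8)
for _i, _c in enumerate(NT_ALPHABET):
    _NT_LOOKUP[ord(_c)] = _i

from Bio.Align import substitution_matrices as _submat

_BLOSUM45 = _submat.load("BLOSUM45")
AA_ALPHABET = str(_BLOSUM45.alphabet)  # "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_LOOKUP = np.full(128, AA_ALPHABET.index("X"), dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_LOOKUP[ord(_c)] = _i

_AA_MATRIX = np.array(_BLOSUM45, dtype=np.float64)
_AA_IDENT = np.zeros((len(AA_ALPHABET),) * 2, dtype=np.uint8)
for _i, _c in enumerate(AA_ALPHABET):
    if _c not in "BZX*":
        _AA_IDENT[_i, _i] = 1

#: default nucleotide scoring (match, mismatch, gap_open, gap_extend)
DEFAULT_NT_SCORING = (2, -3, -5, -2)
#: default protein gap penalties with BLOSUM45 (open, extend)
DEFAULT_AA_GAPS = (-15, -2)

#: above this many DP cells local_align_nt switches to seed-and-extend
EXACT_CELL_LIMIT = 2_000_000

#: Karlin-Altschul parameters per scoring scheme (K, lambda); these are
#: coarse published-style constants -- E-value exactness is not a contract,
#: only the threshold semantics of the downstream filters.
KA_PARAMS = {
    "nt": (0.41, 0.625),
    "aa": (0.0551, 0.2291),
}


def encode_nt(seq: str) -> np.ndarray:
    return _NT_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def nt_score_matrix(match: float, mismatch: float) -> np.ndarray:
    """5x5 matrix over ACGTN; N never matches anything (scores as mismatch)."""
    mat = np.full((5, 5), float(mismatch))
    for i in range(4):
        mat[i, i] = float(match)
    return mat


_NT_IDENT = np.zeros((5, 5), dtype=np.uint8)
for _i in range(4):
    _NT_IDENT[_i, _i] = 1


# ------------------------------------------------------------------ records

@dataclass
class LocalAlignmentHit:
    """One local alignment; coordinates are 0-based half-open on the
    original (forward) query and subject. ``strand`` '-' means the reverse
    complement of the query aligned to the subject."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    align_len: int
    identity: float
    score: float
    evalue: float

    @property
    def mismatches(self) -> int:
        # columns that are neither identities nor gap columns
        gapcols = 2 * self.align_len - (self.q_end - self.q_start) - (
            self.s_end - self.s_start
        )
        return self.align_len - gapcols - round(self.identity * self.align_len)


@dataclass
class ExactMatch:
    """A maximal exact (100% identity) match between two sequences.

    strand '-' means a[a_start:a_end] == revcomp(b[b_start:b_end]).
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length != self.a_end - self.a_start or self.length != (
            self.b_end - self.b_start
        ):
            raise ValueError("exact match length inconsistent with intervals")


# ------------------------------------------------------------------ kernel

_NEG = -1e18


@njit(cache=True)
def _sw_kernel(q, s, mat, idm, go, ge):  # pragma: no cover - numba
    """Exact affine-gap Smith-Waterman with traceback.

    Returns (score, q_start, q_end, s_start, s_end, align_len, n_ident);
    score 0 means no positive-scoring local alignment.
    """
    n = q.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1), np.float64)
    E = np.full((n + 1, m + 1), _NEG, np.float64)
    F = np.full((n + 1, m + 1), _NEG, np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] + go, E[i, j - 1]) + ge
            f = max(H[i - 1, j] + go, F[i - 1, j]) + ge
            h = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            if h < e:
                h = e
            if h < f:
                h = f
            if h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0
    # traceback from (bi, bj); state 0=H, 1=E (gap in query), 2=F (gap in subject)
    i = bi
    j = bj
    state = 0
    alen = 0
    ident = 0
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            d = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if h == d:
                alen += 1
                if idm[q[i - 1], s[j - 1]] == 1:
                    ident += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            alen += 1
            if E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            alen += 1
            if F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = 0
    return best, i, bi, j, bj, alen, ident


def smith_waterman(
    q: np.ndarray, s: np.ndarray, mat: np.ndarray, idm: np.ndarray,
    gap_open: float, gap_extend: float,
):
    """Exact local alignment of two encoded sequences. Thin typed wrapper
    over the numba kernel; returns None when the best score is 0."""
    score, qs, qe, ss, se, alen, ident = _sw_kernel(
        q, s, mat, idm, float(gap_open), float(gap_extend)
    )
    if score <= 0:
        return None
    return score, qs, qe, ss, se, alen, ident


# ------------------------------------------------------------------ E-value

def estimate_evalue(
    score: float,
    query_len: int,
    subject_total_len: int,
    K: float,
    lam: float,
) -> float:
    """Karlin-Altschul expected number of chance hits with >= score:
    E = K * m * n * exp(-lambda * score)."""
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if query_len < 1 or subject_total_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    if score < 0:
        raise ValueError("score must be non-negative")
    x = lam * score
    if x > 700:  # exp underflow guard
        return 0.0
    return K * query_len * subject_total_len * exp(-x)


# ------------------------------------------------------------------ seeding

class SeedIndex:
    """k-mer index of one nucleotide subject for seed-and-extend search.

    Build once per genome, then :meth:`search` each read. Candidate seed
    diagonals are clustered into windows and each window is resolved with
    the exact affine Smith-Waterman kernel, so hit scores on the window are
    exact; only seeding (an exact shared k-mer) is heuristic.
    """

    def __init__(self, subject: str, subject_id: str = "subject", k: int = 13):
        if not subject:
            raise ValueError("empty subject sequence")
        self.subject = subject
        self.subject_id = subject_id
        self.k = k
        self._enc = encode_nt(subject)
        index: dict[str, list[int]] = {}
        for j in range(len(subject) - k + 1):
            kmer = subject[j : j + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(j)
        self._index = index

    def search(
        self,
        query: str,
        query_id: str = "query",
        scoring=DEFAULT_NT_SCORING,
        band: int = 16,
        max_windows: int = 8,
        ka=KA_PARAMS["nt"],
    ) -> list[LocalAlignmentHit]:
        """Seed-and-extend both strands of ``query`` against the subject."""
        if not query:
            raise ValueError("empty query sequence")
        match, mismatch, go, ge = scoring
        mat = nt_score_matrix(match, mismatch)
        hits: list[LocalAlignmentHit] = []
        n_s = len(self.subject)
        for strand, q in (("+", query), ("-", revcomp(query))):
            k = self.k
            if len(q) < k:
                continue
            diags: dict[int, int] = {}
            for qp in range(len(q) - k + 1):
                for sp in self._index.get(q[qp : qp + k], ()):
                    d = sp - qp
                    diags[d] = diags.get(d, 0) + 1
            if not diags:
                continue
            # cluster nearby diagonals into windows
            sorted_d = sorted(diags)
            clusters: list[list[int]] = [[sorted_d[0]]]
            for d in sorted_d[1:]:
                if d - clusters[-1][-1] <= band:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            clusters.sort(key=lambda c: -sum(diags[d] for d in c))
            qe_arr = encode_nt(q)
            seen: set[tuple] = set()
            for cluster in clusters[:max_windows]:
                lo = max(0, cluster[0] - band)
                hi = min(n_s, cluster[-1] + len(q) + band)
                res = smith_waterman(
                    qe_arr, self._enc[lo:hi], mat, _NT_IDENT, go, ge
                )
                if res is None:
                    continue
                score, qs, qe, ss, se, alen, ident = res
                key = (strand, qs, qe, lo + ss, lo + se)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    self._make_hit(
                        query_id, query, strand, score, qs, qe, lo + ss,
                        lo + se, alen, ident, ka,
                    )
                )
        hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
        return hits

    def _make_hit(
        self, query_id, query, strand, score, qs, qe, ss, se, alen, ident, ka
    ) -> LocalAlignmentHit:
        if strand == "-":  # map reverse-complement query coords back
            qs, qe = len(query) - qe, len(query) - qs
        K, lam = ka
        return LocalAlignmentHit(
            query_id=query_id,
            subject_id=self.subject_id,
            q_start=qs,
            q_end=qe,
            s_start=ss,
            s_end=se,
            strand=strand,
            align_len=alen,
            identity=ident / alen if alen else 0.0,
            score=score,
            evalue=estimate_evalue(score, len(query), len(self.subject), K, lam),
        )


# ------------------------------------------------------------------ top level

def local_align_nt(
    query: str,
    subject: str,
    scoring=DEFAULT_NT_SCORING,
    query_id: str = "query",
    subject_id: str = "subject",
    k: int = 13,
) -> list[LocalAlignmentHit]:
    """Local nucleotide alignment on both strands.

    Uses the full exact DP when the problem is small (below
    ``EXACT_CELL_LIMIT`` cells) and k-mer seed-and-extend otherwise.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if len(query) * len(subject) <= EXACT_CELL_LIMIT:
        match, mismatch, go, ge = scoring
        mat = nt_score_matrix(match, mismatch)
        s_enc = encode_nt(subject)
        hits = []
        K, lam = KA_PARAMS["nt"]
        for strand, q in (("+", query), ("-", revcomp(query))):
            res = smith_waterman(encode_nt(q), s_enc, mat, _NT_IDENT, go, ge)
            if res is None:
                continue
            score, qs, qe, ss, se, alen, ident = res
            if strand == "-":
                qs, qe = len(query) - qe, len(query) - qs
            hits.append(
                LocalAlignmentHit(
                    query_id, subject_id, qs, qe, ss, se, strand, alen,
                    ident / alen if alen else 0.0, score,
                    estimate_evalue(score, len(query), len(subject), K, lam),
                )
            )
        hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
        return hits
    index = SeedIndex(subject, subject_id, k=k)
    return index.search(query, query_id=query_id, scoring=scoring)


def local_align_aa(
    query: str,
    subject: str,
    matrix: str = "BLOSUM45",
    gap_penalties=DEFAULT_AA_GAPS,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_total_len: Optional[int] = None,
) -> list[LocalAlignmentHit]:
    """Exact local protein alignment scored with a BLOSUM-type matrix.

    X is allowed but never counts as an identity. ``subject_total_len``
    overrides the database length used for the E-value (defaults to the
    subject length).
    """
    if not query or not subject:
        raise ValueError("empty protein sequence")
    if matrix == "BLOSUM45":
        mat = _AA_MATRIX
    else:
        m = _submat.load(matrix)
        if str(m.alphabet) != AA_ALPHABET:
            raise ValueError(f"unsupported matrix alphabet for {matrix}")
        mat = np.array(m, dtype=np.float64)
    go, ge = gap_penalties
    res = smith_waterman(encode_aa(query), encode_aa(subject), mat, _AA_IDENT, go, ge)
    if res is None:
        return []
    score, qs, qe, ss, se, alen, ident = res
    K, lam = KA_PARAMS["aa"]
    n = subject_total_len if subject_total_len is not None else len(subject)
    return [
        LocalAlignmentHit(
            query_id, subject_id, qs, qe, ss, se, "+", alen,
            ident / alen if alen else 0.0, score,
            estimate_evalue(score, len(query), n, K, lam),
        )
    ]


# ------------------------------------------------------------------ MEMs

def _mems_forward(a: str, b: str, min_len: int) -> list[tuple[int, int, int, int]]:
    """All maximal exact matches (same strand) of length >= min_len.

    Seeds with k = min(min_len, 14)-mers and extends maximally; every match
    of length >= min_len contains a seed, so enumeration is complete. N is
    never part of a match.
    """
    k = min(min_len, 14)
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    covered: dict[int, int] = {}  # diagonal -> a_end of last maximal run found
    out = []
    for i in range(len(a) - k + 1):
        kmer = a[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            d = j - i
            if covered.get(d, 0) > i:
                continue  # seed lies inside the previously found run
            ai, bj = i, j
            while ai > 0 and bj > 0 and a[ai - 1] == b[bj - 1] != "N":
                ai -= 1
                bj -= 1
            ae, be = i + k, j + k
            while ae < len(a) and be < len(b) and a[ae] == b[be] != "N":
                ae += 1
                be += 1
            covered[d] = ae
            if ae - ai >= min_len:
                out.append((ai, ae, bj, be))
    return out


def maximal_exact_matches(a: str, b: str, min_len: int) -> list[ExactMatch]:
    """Enumerate all maximal exact matches of length >= min_len between
    ``a`` and ``b``, on both strands."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not a or not b:
        raise ValueError("empty sequence")
    matches = [
        ExactMatch(ai, ae, bj, be, ae - ai, "+")
        for ai, ae, bj, be in _mems_forward(a, b, min_len)
    ]
    rb = revcomp(b)
    nb = len(b)
    for ai, ae, bj, be in _mems_forward(a, rb, min_len):
        matches.append(ExactMatch(ai, ae, nb - be, nb - bj, ae - ai, "-"))
    matches.sort(key=lambda m: (-m.length, m.a_start, m.b_start, m.strand))
    return matches


# ------------------------------------------------------------------ export

BLAST_TAB_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "score",
]


def hits_to_table(hits: list[LocalAlignmentHit]):
    """Hits as a 12-column tabular frame (1-based inclusive coordinates in
    this file only, matching the de-facto standard)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "query": h.query_id,
                "subject": h.subject_id,
                "pident": round(h.identity * 100, 2),
                "length": h.align_len,
                "mismatches": h.mismatches,
                "gapopens": 0,
                "qstart": h.q_start + 1,
                "qend": h.q_end,
                "sstart": h.s_start + 1 if h.strand == "+" else h.s_end,
                "send": h.s_end if h.strand == "+" else h.s_start + 1,
                "evalue": h.evalue,
                "score": h.score,
            }
        )
    return pd.DataFrame(rows, columns=BLAST_TAB_COLUMNS)
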