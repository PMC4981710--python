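"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: borders are found by
direct prefix/suffix comparison, maximal exact matches by full diagonal
scanning, and optimal local alignment scores come from Biopython's
exhaustive PairwiseAligner.
"""
from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def brute_border(seq: str, max_len: int = 200) -> int:
    """Longest L <= max_len with seq[:L] == seq[-L:] (direct comparison)."""
    n = len(seq)
    best = 0
    for L in range(1, min(max_len, n - 1) + 1):
        if seq[:L] == seq[n - L :]:
            best = L
    return best


def _diag_runs(a: str, b: str, min_len: int):
    """Maximal equal runs per diagonal via full numpy scanning."""
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    nN = ord("N")
    out = []
    for d in range(-(len(a) - 1), len(b)):
        i0 = max(0, -d)
        j0 = i0 + d
        L = min(len(a) - i0, len(b) - j0)
        if L < min_len:
            continue
        av = aa[i0 : i0 + L]
        bv_ = bb[j0 : j0 + L]
        eq = (av == bv_) & (av != nN)
        padded = np.concatenate([[False], eq, [False]]).astype(np.int8)
        delta = np.diff(padded)
        starts = np.nonzero(delta == 1)[0]
        ends = np.nonzero(delta == -1)[0]
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                out.append((i0 + s, i0 + e, j0 + s, j0 + e))
    return out


def brute_mems(a: str, b: str, min_len: int) -> set:
    """All maximal common substrings >= min_len, both strands, as
    (a_start, a_end, b_start, b_end, strand) tuples."""
    res = {(ai, ae, bj, be, "+") for ai, ae, bj, be in _diag_runs(a, b, min_len)}
    rb = rc(b)
    nb = len(b)
    for ai, ae, bj, be in _diag_runs(a, rb, min_len):
        res.add((ai, ae, nb - be, nb - bj, "-"))
    return res


def nt_aligner(match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Biopython exhaustive local aligner for the package's nt scoring.

    The package charges open + L*extend for a length-L gap; Biopython
    charges open + (L-1)*extend, hence the open_gap_score shift.
    """
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open + gap_extend
    al.extend_gap_score = gap_extend
    return al


def aa_aligner(matrix="BLOSUM45", gap_open=-15, gap_extend=-2):
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = gap_open + gap_extend
    al.extend_gap_score = gap_extend
    return al
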