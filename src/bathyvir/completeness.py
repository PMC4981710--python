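"""Terminal-redundancy detection of complete (circle-like) viral genomes.

Caudoviral genomes replicate as concatemers; a fosmid insert longer than one
genome therefore carries the beginning of the genome again at its end. A
contig whose prefix reappears exactly as its suffix (a terminal direct
repeat longer than the threshold, strictly >50 bp by default) is called a
complete, circularly-permuted genome; trimming the second repeat copy
yields the circular genome sequence.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import Contig, Topology


@dataclass
class CircularityCall:
    """Verdict on genome completeness via terminal direct repeats."""

    contig_id: str
    is_complete: bool
    repeat_len: int
    repeat_seq: str
    trimmed_len: int
    #: interval [start, end) of the second (suffix) repeat copy; None when
    #: incomplete
    repeat2_interval: Optional[tuple[int, int]] = None


def _longest_border(t: str, probe_len: int = 16) -> int:
    """Length of the longest proper prefix of ``t`` that is also a suffix.

    Borders shorter than ``probe_len`` are checked directly; longer ones are
    found by locating occurrences of the length-``probe_len`` prefix, which
    any border of at least that length must start with.
    """
    n = len(t)
    if n < 2:
        return 0
    kp = min(probe_len, n - 1)
    best = 0
    for L in range(1, kp):
        if t[:L] == t[n - L :]:
            best = L
    probe = t[:kp]
    start = 1
    while True:
        pos = t.find(probe, start)
        if pos == -1:
            break
        L = n - pos
        if L >= kp and t[:L] == t[pos:] and L > best:
            best = L
        start = pos + 1
    return best


def detect_terminal_repeat(
    contig: Contig, min_repeat: int = 50, max_offset: int = 0
) -> CircularityCall:
    """Find the longest exact terminal direct repeat of ``contig``.

    With ``max_offset`` > 0 the repeat may start/end within that many bp of
    the contig termini (ragged assembly ends). A contig is complete iff the
    repeat is strictly longer than ``min_repeat``.
    """
    n = len(contig)
    if n <= 2 * min_repeat:
        raise ValueError(
            f"contig {contig.id} too short ({n} bp) for min_repeat={min_repeat}"
        )
    seq = contig.seq
    best_len = 0
    best = (0, 0)  # (start offset i, end offset j) of the winning slice
    for i in range(max_offset + 1):
        for j in range(max_offset + 1):
            sub = seq[i : n - j] if (i or j) else seq
            L = _longest_border(sub)
            if L > best_len:
                best_len = L
                best = (i, j)
    if best_len > min_repeat:
        i, j = best
        rep_start = i
        second_start = n - j - best_len
        return CircularityCall(
            contig_id=contig.id,
            is_complete=True,
            repeat_len=best_len,
            repeat_seq=seq[rep_start : rep_start + best_len],
            trimmed_len=n - best_len,
            repeat2_interval=(second_start, second_start + best_len),
        )
    return CircularityCall(
        contig_id=contig.id,
        is_complete=False,
        repeat_len=0,
        repeat_seq="",
        trimmed_len=n,
    )


def trim_circular(contig: Contig, call: CircularityCall) -> Contig:
    """Remove the second copy of the terminal repeat and mark the genome
    circular. Only valid for complete calls."""
    if not call.is_complete:
        raise ValueError(f"contig {contig.id} was not called complete")
    if call.contig_id != contig.id:
        raise ValueError("circularity call does not belong to this contig")
    s2_start, s2_end = call.repeat2_interval
    trimmed = contig.seq[:s2_start] + contig.seq[s2_end:]
    assert len(trimmed) == call.trimmed_len
    return Contig(
        id=contig.id,
        seq=trimmed,
        library=contig.library,
        topology=Topology.CIRCULAR,
    )


def circularity_report(calls: Iterable[CircularityCall]) -> pd.DataFrame:
    calls = list(calls)
    return pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in calls],
            "is_complete": [c.is_complete for c in calls],
            "repeat_len": [c.repeat_len for c in calls],
            "trimmed_len": [c.trimmed_len for c in calls],
        }
    )
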