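"""Per-read GC-content distributions and bimodality detection.

Deep-water metagenomes and viromes show a bimodal GC distribution (a
low-GC and a high-GC community component) while photic-zone datasets show a
single low-GC peak; this module computes per-read GC histograms and detects
modes on a smoothed histogram by prominence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .records import ReadSet

logger = logging.getLogger(__name__)


@dataclass
class GCProfile:
    dataset_id: str
    bin_width: float
    histogram: np.ndarray        # counts per GC% bin over [0, 100]
    bin_edges: np.ndarray
    mean_gc: float               # percent
    n_reads: int = 0
    n_excluded: int = 0
    peaks: list = field(default_factory=list)  # bin centers (percent)


def gc_profile(reads: ReadSet, bin_width: float = 1.0) -> GCProfile:
    """Histogram of per-read GC percent (N bases ignored; reads with no
    non-N bases are excluded with a warning)."""
    if len(reads) == 0:
        raise ValueError("empty read set")
    values = []
    excluded = 0
    for rid, seq in reads.reads:
        denom = len(seq) - seq.count("N")
        if denom == 0:
            logger.warning("read %s has no non-N bases; excluded", rid)
            excluded += 1
            continue
        values.append(100.0 * (seq.count("G") + seq.count("C")) / denom)
    if not values:
        raise ValueError("no reads with non-N bases")
    arr = np.asarray(values)
    nbins = int(round(100 / bin_width))
    hist, edges = np.histogram(arr, bins=nbins, range=(0.0, 100.0))
    return GCProfile(
        dataset_id=reads.dataset_id,
        bin_width=bin_width,
        histogram=hist,
        bin_edges=edges,
        mean_gc=float(arr.mean()),
        n_reads=len(values),
        n_excluded=excluded,
    )


def detect_modes(
    profile: GCProfile,
    smooth_window: int = 5,
    min_separation: float = 10.0,
    min_prominence: float = 0.05,
) -> list[float]:
    """Modes of the smoothed histogram.

    The histogram is smoothed with a moving average of ``smooth_window``
    bins; local maxima separated by at least ``min_separation`` percent GC
    and with prominence at least ``min_prominence`` of the smoothed maximum
    are reported as modes (bin centers, ascending GC). The histogram is
    zero-padded so a mode at the histogram edge is still detected.
    """
    counts = profile.histogram.astype(float)
    if counts.max() == 0:
        return []
    w = max(1, int(smooth_window))
    smoothed = np.convolve(counts, np.ones(w) / w, mode="same")
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    distance = max(1, int(round(min_separation / profile.bin_width)))
    idx, _ = find_peaks(
        padded,
        prominence=min_prominence * smoothed.max(),
        distance=distance,
    )
    centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
    peaks = sorted(float(centers[i - 1]) for i in idx)
    profile.peaks = peaks
    return peaks
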