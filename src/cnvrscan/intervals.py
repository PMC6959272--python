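"""Interval arithmetic on 1-based inclusive genomic coordinates.

All intervals in this package are 1-based and end-inclusive (the rawcnv
convention); a single base pair is the interval (p, p) of length 1.
"""

from __future__ import annotations

import numpy as np


def merge(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping or bookended (end + 1 == next start) intervals.

    Parameters
    ----------
    intervals : (n, 2) integer array of 1-based inclusive [start, end].

    Returns
    -------
    (m, 2) sorted, disjoint, non-adjacent array.
    """
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.shape[0] == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = []
    cs, ce = int(iv[0, 0]), int(iv[0, 1])
    for s, e in iv[1:]:
        if s <= ce + 1:
            ce = max(ce, int(e))
        else:
            out.append((cs, ce))
            cs, ce = int(s), int(e)
    out.append((cs, ce))
    return np.array(out, dtype=np.int64)


def covered_bp(intervals: np.ndarray) -> int:
    """Total base pairs covered by the union of the intervals."""
    m = merge(intervals)
    if m.shape[0] == 0:
        return 0
    return int(np.sum(m[:, 1] - m[:, 0] + 1))


def overlap_len(s1: int, e1: int, s2: int, e2: int) -> int:
    """Length of the intersection of two inclusive intervals (0 if disjoint)."""
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """Reciprocal overlap fraction: shared bp over the LONGER interval.

    Two calls match at threshold t iff the shared length is at least t of
    each interval, which is equivalent to at least t of the longer one.
    """
    shared = overlap_len(s1, e1, s2, e2)
    if shared == 0:
        return 0.0
    longer = max(e1 - s1 + 1, e2 - s2 + 1)
    return shared / longer
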