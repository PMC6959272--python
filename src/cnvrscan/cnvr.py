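"""Construction of copy-number-variable regions (CNVRs).

A CNVR is a maximal run of consecutive markers at which the number of
distinct class-matching carriers exceeds both the non-singleton bound
(>= 2 carriers) and the frequency bound (> 0.03% of QC-passing samples),
spanning < 1 Mb. Runs that exceed the span bound are split recursively
at their minimum-count interior marker (leftmost on ties), removing that
marker, until every piece satisfies the bound. Region boundaries are the
positions of the first and last qualifying markers.

Classes: DEL counts copy number 0 or 1; HD (homozygous deletion) counts
copy number 0 only; DUP counts copy number >= 3. A sample contributes at
most once per class at each marker regardless of overlapping calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import CNV_CLASSES, CnvCall, SnpMap


@dataclass(frozen=True)
class CnvrConfig:
    freq_threshold: float = 0.0003  # carrier frequency must be strictly greater
    min_carriers: int = 2  # "non-singleton": at least 2 carriers
    max_span_bp: int = 1_000_000  # regions span strictly less than this

    def count_threshold(self, n_samples: int) -> float:
        """Qualifying markers need carrier count strictly above this."""
        return max(self.min_carriers - 1, self.freq_threshold * n_samples)


class MarkerStateCounts:
    """Per-marker distinct-carrier counts for each CNV class."""

    def __init__(self, snp_map: SnpMap, n_samples: int):
        self.snp_map = snp_map
        self.n_samples = n_samples
        self.counts: dict[str, dict[str, np.ndarray]] = {
            cls: {c: np.zeros(len(snp_map.positions(c)), dtype=np.int64) for c in snp_map.chroms}
            for cls in CNV_CLASSES
        }

    def of(self, cnv_class: str, chrom: str) -> np.ndarray:
        return self.counts[cnv_class][chrom]


@dataclass(frozen=True)
class Cnvr:
    chrom: str
    start: int  # position of the first qualifying marker
    end: int  # position of the last qualifying marker
    cnv_class: str
    marker_names: tuple[str, ...]
    carrier_count: Optional[int] = None
    frequency: Optional[float] = None
    recurrent: Optional[bool] = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def count_marker_states(
    calls: Sequence[CnvCall],
    snp_map: SnpMap,
    kept_samples: Iterable[str],
) -> MarkerStateCounts:
    """Count, per marker and class, the distinct samples covering it.

    Calls on chromosomes absent from the map are skipped with a warning.
    """
    kept = set(kept_samples)
    counts = MarkerStateCounts(snp_map, n_samples=len(kept))
    missing_chroms: set[str] = set()
    # per class: chrom -> list of (sample, i0, i1) marker index ranges
    for cls in CNV_CLASSES:
        per_chrom: dict[str, list[tuple[str, int, int]]] = {}
        for c in calls:
            if c.sample_id not in kept or not c.matches_class(cls):
                continue
            if c.chrom not in snp_map._pos:
                missing_chroms.add(c.chrom)
                continue
            rng = snp_map.marker_range(c.chrom, c.start, c.end)
            if rng is None:
                continue
            per_chrom.setdefault(c.chrom, []).append((c.sample_id, rng[0], rng[1]))
        for chrom, entries in per_chrom.items():
            arr = counts.counts[cls][chrom]
            diff = np.zeros(len(arr) + 1, dtype=np.int64)
            entries.sort()
            # merge overlapping index ranges of the same sample so each
            # sample contributes at most 1 per marker
            cur_sid, cur_i0, cur_i1 = None, 0, -1
            for sid, i0, i1 in entries:
                if sid == cur_sid and i0 <= cur_i1 + 1:
                    cur_i1 = max(cur_i1, i1)
                    continue
                if cur_sid is not None:
                    diff[cur_i0] += 1
                    diff[cur_i1 + 1] -= 1
                cur_sid, cur_i0, cur_i1 = sid, i0, i1
            if cur_sid is not None:
                diff[cur_i0] += 1
                diff[cur_i1 + 1] -= 1
            arr += np.cumsum(diff[:-1])
    if missing_chroms:
        warnings.warn(f"calls on chromosomes absent from the SNP map skipped: {sorted(missing_chroms)}")
    return counts


def _segment_run(
    positions: np.ndarray,
    names: np.ndarray,
    cvec: np.ndarray,
    idx: np.ndarray,
    max_span_bp: int,
) -> list[np.ndarray]:
    """Recursively enforce the span bound on one qualifying run.

    ``idx``: map indices of the run's markers (ascending). When the span
    is too large, the minimum-count interior marker (leftmost tie) is
    removed and both sides are re-segmented.
    """
    if idx.size == 0:
        return []
    span = positions[idx[-1]] - positions[idx[0]] + 1
    if span < max_span_bp:
        return [idx]
    if idx.size <= 2:
        # no interior marker to remove: degenerate run, emit single markers
        return [idx[i : i + 1] for i in range(idx.size)]
    interior = idx[1:-1]
    k = 1 + int(np.argmin(cvec[interior]))  # leftmost interior minimum
    return _segment_run(positions, names, cvec, idx[:k], max_span_bp) + _segment_run(
        positions, names, cvec, idx[k + 1 :], max_span_bp
    )


def build_cnvrs(
    counts: MarkerStateCounts,
    cfg: CnvrConfig = CnvrConfig(),
    classes: Sequence[str] = CNV_CLASSES,
) -> list[Cnvr]:
    """Form CNVRs from marker state counts for each requested class."""
    thr = cfg.count_threshold(counts.n_samples)
    out: list[Cnvr] = []
    for cls in classes:
        for chrom in counts.snp_map.chroms:
            cvec = counts.of(cls, chrom)
            ok = cvec > thr
            if not ok.any():
                continue
            positions = counts.snp_map.positions(chrom)
            names = counts.snp_map.names(chrom)
            # maximal runs of consecutive qualifying markers
            run_starts = []
            run_ends = []
            in_run = False
            for i, q in enumerate(ok):
                if q and not in_run:
                    run_starts.append(i)
                    in_run = True
                elif not q and in_run:
                    run_ends.append(i - 1)
                    in_run = False
            if in_run:
                run_ends.append(len(ok) - 1)
            for rs, re_ in zip(run_starts, run_ends):
                idx = np.arange(rs, re_ + 1)
                for piece in _segment_run(positions, names, cvec, idx, cfg.max_span_bp):
                    out.append(
                        Cnvr(
                            chrom=chrom,
                            start=int(positions[piece[0]]),
                            end=int(positions[piece[-1]]),
                            cnv_class=cls,
                            marker_names=tuple(str(n) for n in names[piece]),
                        )
                    )
    return out


def assign_carriers(
    cnvrs: Sequence[Cnvr],
    calls: Sequence[CnvCall],
    n_samples: int,
    kept_samples: Optional[Iterable[str]] = None,
) -> list[Cnvr]:
    """Fill carrier_count/frequency/recurrent for each CNVR.

    A carrier is a distinct sample with a class-matching call overlapping
    the region by >= 1 bp. Recurrent iff at least 2 carriers.
    """
    kept = set(kept_samples) if kept_samples is not None else None
    trees: dict[tuple[str, str], IntervalTree] = {}
    for cls in {r.cnv_class for r in cnvrs}:
        for c in calls:
            if kept is not None and c.sample_id not in kept:
                continue
            if c.matches_class(cls):
                trees.setdefault((cls, c.chrom), IntervalTree()).addi(
                    c.start, c.end + 1, c.sample_id
                )
    out = []
    for r in cnvrs:
        tree = trees.get((r.cnv_class, r.chrom))
        carriers = {iv.data for iv in tree.overlap(r.start, r.end + 1)} if tree else set()
        n = len(carriers)
        out.append(
            replace(
                r,
                carrier_count=n,
                frequency=n / n_samples if n_samples else 0.0,
                recurrent=n >= 2,
            )
        )
    return out


def summarize_cnvrs(cnvrs: Sequence[Cnvr], freq_bins: int = 20) -> dict:
    """Per-class counts, recurrent fraction (to 0.1%), frequency histogram."""
    summary: dict = {}
    for cls in CNV_CLASSES:
        sub = [r for r in cnvrs if r.cnv_class == cls]
        if not sub:
            summary[cls] = {"n_cnvrs": 0}
            continue
        with_carriers = [r for r in sub if r.recurrent is not None]
        n_rec = sum(1 for r in with_carriers if r.recurrent)
        entry = {"n_cnvrs": len(sub)}
        if with_carriers:
            entry["n_recurrent"] = n_rec
            entry["recurrent_pct"] = round(100.0 * n_rec / len(with_carriers), 1)
            freqs = np.array([r.frequency for r in with_carriers if r.frequency is not None])
            if freqs.size:
                hist, edges = np.histogram(freqs, bins=freq_bins, range=(0.0, float(freqs.max())))
                entry["frequency_hist"] = {"counts": hist.tolist(), "edges": edges.tolist()}
        summary[cls] = entry
    return summary
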