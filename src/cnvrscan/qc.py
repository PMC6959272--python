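"""Sample-level quality control and validation statistics.

Filters: array call rate, LRR (log R ratio) standard deviation, residual
GC-wave factor, total CNV call count, duplicate samples (call-profile
Jaccard), and carriers of known syndromic CNVs. Thresholds are strict as
printed: a sample is kept iff call_rate > 0.98, lrr_sd < 0.25,
|gc_wave| < 0.02 and call count < 100.

Validation statistics: genomic inflation factor λ, trio inheritance rate
and replicate concordance (both at 50% reciprocal overlap by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import merge, reciprocal_overlap
from .io_formats import CnvCall, SampleRecord

REASON_CODES = ("CALL_RATE", "LRR_SD", "GC_WAVE", "CALL_COUNT", "DUPLICATE", "SYNDROMIC")

# median of a 1-df chi-square distribution
CHI2_1DF_MEDIAN = 0.4549364


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.98  # kept iff call_rate > this
    max_lrr_sd: float = 0.25  # kept iff lrr_sd < this
    max_abs_gc_wave: float = 0.02  # kept iff |gc_wave| < this
    max_cnv_calls: int = 100  # kept iff call count < this
    duplicate_similarity: float = 0.8  # Jaccard on covered bp


@dataclass
class QcReport:
    kept: list[str]
    excluded: dict[str, list[str]]  # sample id -> reason codes

    @property
    def counts_per_reason(self) -> dict[str, int]:
        counts = {r: 0 for r in REASON_CODES}
        for reasons in self.excluded.values():
            for r in reasons:
                counts[r] += 1
        return counts


@dataclass(frozen=True)
class InflationResult:
    lambda_gc: float
    n_tests: int


def apply_sample_filters(
    samples: Sequence[SampleRecord],
    calls: Sequence[CnvCall],
    thresholds: QcThresholds = QcThresholds(),
) -> QcReport:
    """Apply the four per-sample metric filters.

    A sample failing several criteria carries every applicable reason
    code. The result is independent of the order criteria are checked.
    """
    n_calls: dict[str, int] = {}
    for c in calls:
        n_calls[c.sample_id] = n_calls.get(c.sample_id, 0) + 1
    kept, excluded = [], {}
    for s in samples:
        reasons = []
        if not s.call_rate > thresholds.min_call_rate:
            reasons.append("CALL_RATE")
        if not s.lrr_sd < thresholds.max_lrr_sd:
            reasons.append("LRR_SD")
        if not abs(s.gc_wave) < thresholds.max_abs_gc_wave:
            reasons.append("GC_WAVE")
        if not n_calls.get(s.sample_id, 0) < thresholds.max_cnv_calls:
            reasons.append("CALL_COUNT")
        if reasons:
            excluded[s.sample_id] = reasons
        else:
            kept.append(s.sample_id)
    return QcReport(kept=kept, excluded=excluded)


def _class_footprints(calls: Iterable[CnvCall]) -> dict[str, dict[tuple[str, str], np.ndarray]]:
    """Per (sample, chrom) merged covered intervals, per DEL/DUP class."""
    raw: dict[str, dict[tuple[str, str], list]] = {"DEL": {}, "DUP": {}}
    for c in calls:
        raw[c.cnv_class].setdefault((c.sample_id, c.chrom), []).append((c.start, c.end))
    return {
        cls: {k: merge(np.array(v)) for k, v in d.items()} for cls, d in raw.items()
    }


def detect_duplicates(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    similarity: float = 0.8,
) -> tuple[list[tuple[str, str]], set[str]]:
    """Flag duplicate sample pairs; exclude one member of each pair.

    Pairs are flagged when the Jaccard of per-class covered base pairs is
    >= ``similarity``, or when a declared ``replicate_of`` link exists.
    The member with the lower call rate is excluded (declared replicates:
    the replicate itself).

    One plane sweep per (class, chromosome) accumulates the exact shared
    bp of every overlapping sample pair, so the cost scales with the
    number of pairwise interval overlaps rather than with n^2 samples.
    """
    call_rate = {s.sample_id: s.call_rate for s in samples}
    foot = _class_footprints(calls)
    total_bp: dict[str, int] = {}
    for cls in ("DEL", "DUP"):
        for (sid, _), iv in foot[cls].items():
            total_bp[sid] = total_bp.get(sid, 0) + int(np.sum(iv[:, 1] - iv[:, 0] + 1))
    shared_bp: dict[tuple[str, str], int] = {}
    for cls in ("DEL", "DUP"):
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for (sid, ch), iv in foot[cls].items():
            by_chrom.setdefault(ch, []).extend((int(s), int(e), sid) for s, e in iv)
        for entries in by_chrom.values():
            entries.sort()
            active: list[tuple[int, str]] = []  # (end, sid); footprints are merged,
            for s, e, sid in entries:  # so per-pair overlaps sum to intersection bp
                active = [(ae, asid) for ae, asid in active if ae >= s]
                for ae, asid in active:
                    if asid != sid:
                        pair = (sid, asid) if sid < asid else (asid, sid)
                        shared_bp[pair] = shared_bp.get(pair, 0) + min(e, ae) - s + 1
                active.append((e, sid))
    flagged: list[tuple[str, str]] = []
    for (a, b), inter in sorted(shared_bp.items()):
        union = total_bp[a] + total_bp[b] - inter
        if union and inter / union >= similarity:
            flagged.append((a, b))
    for s in samples:
        if s.replicate_of and s.replicate_of in call_rate:
            pair = tuple(sorted((s.sample_id, s.replicate_of)))
            if pair not in flagged:
                flagged.append(pair)
    excluded: set[str] = set()
    declared = {tuple(sorted((s.sample_id, s.replicate_of))): s.sample_id
                for s in samples if s.replicate_of}
    for a, b in flagged:
        if (a, b) in declared:
            excluded.add(declared[(a, b)])
        else:
            excluded.add(a if call_rate.get(a, 1.0) <= call_rate.get(b, 1.0) else b)
    return flagged, excluded


def exclude_syndromic(
    calls: Sequence[CnvCall],
    syndromic_regions: Sequence[tuple[str, int, int, str]],
    min_reciprocal_overlap: float = 0.5,
) -> set[str]:
    """Samples with a class-matching call reciprocally overlapping a
    known syndromic CNV region by at least ``min_reciprocal_overlap``.

    ``syndromic_regions``: (chrom, start, end, cnv_class) tuples.
    """
    flagged: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, cls in syndromic_regions:
        by_chrom.setdefault(chrom, []).append((s, e, cls))
    for c in calls:
        for s, e, cls in by_chrom.get(c.chrom, ()):
            if c.matches_class(cls) and reciprocal_overlap(c.start, c.end, s, e) >= min_reciprocal_overlap:
                flagged.add(c.sample_id)
                break
    return flagged


def run_qc(
    samples: Sequence[SampleRecord],
    calls: Sequence[CnvCall],
    thresholds: QcThresholds = QcThresholds(),
    syndromic_regions: Optional[Sequence[tuple[str, int, int, str]]] = None,
) -> QcReport:
    """Full QC: metric filters + duplicate detection + syndromic exclusion."""
    report = apply_sample_filters(samples, calls, thresholds)
    _, dup_excluded = detect_duplicates(calls, samples, thresholds.duplicate_similarity)
    syn = exclude_syndromic(calls, syndromic_regions) if syndromic_regions else set()
    kept, excluded = [], dict(report.excluded)
    for sid in report.kept:
        reasons = []
        if sid in dup_excluded:
            reasons.append("DUPLICATE")
        if sid in syn:
            reasons.append("SYNDROMIC")
        if reasons:
            excluded[sid] = reasons
        else:
            kept.append(sid)
    for sid in list(excluded):
        if sid in dup_excluded and "DUPLICATE" not in excluded[sid]:
            excluded[sid].append("DUPLICATE")
        if sid in syn and "SYNDROMIC" not in excluded[sid]:
            excluded[sid].append("SYNDROMIC")
    return QcReport(kept=kept, excluded=excluded)


def filter_calls(calls: Sequence[CnvCall], kept_ids: Iterable[str]) -> list[CnvCall]:
    kept = set(kept_ids)
    return [c for c in calls if c.sample_id in kept]


def genomic_inflation(p_values: Sequence[float]) -> InflationResult:
    """λ = median observed 1-df chi-square / 0.4549364.

    A case/control matching diagnostic: λ near 1 under a well-calibrated
    null; λ >> 1 indicates stratification or batch mismatch.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("genomic_inflation requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return InflationResult(lambda_gc=float(np.median(chi2) / CHI2_1DF_MEDIAN), n_tests=p.size)


def _matched(call: CnvCall, others: Sequence[CnvCall], threshold: float) -> bool:
    return any(
        o.chrom == call.chrom
        and o.cnv_class == call.cnv_class
        and reciprocal_overlap(call.start, call.end, o.start, o.end) >= threshold
        for o in others
    )


def trio_inheritance_rate(
    calls: Sequence[CnvCall],
    trios: Sequence[tuple[str, str, str]],
    min_reciprocal_overlap: float = 0.5,
) -> Optional[float]:
    """Fraction of child calls matched by a same-class parental call.

    ``trios``: (child, father, mother) id triples. Returns None when the
    children carry no calls (undefined, not zero).
    """
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    n_child = n_inh = 0
    for child, father, mother in trios:
        parental = by_sample.get(father, []) + by_sample.get(mother, [])
        for call in by_sample.get(child, []):
            n_child += 1
            if _matched(call, parental, min_reciprocal_overlap):
                n_inh += 1
    return n_inh / n_child if n_child else None


def replicate_concordance(
    calls: Sequence[CnvCall],
    pairs: Sequence[tuple[str, str]],
    min_reciprocal_overlap: float = 0.5,
) -> Optional[float]:
    """Symmetric per-call concordance over replicate pairs."""
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    n_total = n_match = 0
    for a, b in pairs:
        for x, y in ((a, b), (b, a)):
            partner = by_sample.get(y, [])
            for call in by_sample.get(x, []):
                n_total += 1
                if _matched(call, partner, min_reciprocal_overlap):
                    n_match += 1
    return n_match / n_total if n_total else None
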