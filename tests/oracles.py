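"""Independent brute-force oracles used only by the test suite.

These re-derive the expected results by direct enumeration, independent
of the package's vectorised implementations.
"""

from math import comb


def fisher_two_sided_enum(a, b, c, d, rel_tol=1e-7):
    """Two-sided Fisher p by full hypergeometric enumeration.

    Conditions on all margins; sums P(table) over tables whose
    probability is <= the observed one (with a relative tie tolerance).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = comb(r1, a) * comb(r2, c1 - a) / denom
    total = 0.0
    for x in range(lo, hi + 1):
        p_x = comb(r1, x) * comb(r2, c1 - x) / denom
        if p_x <= p_obs * (1 + rel_tol):
            total += p_x
    return min(total, 1.0)


def brute_marker_counts(calls, snp_map, kept, cnv_class):
    """Distinct-carrier count per marker by direct point-in-interval tests."""
    kept = set(kept)
    out = {}
    for chrom in snp_map.chroms:
        counts = []
        for pos in snp_map.positions(chrom):
            carriers = {
                c.sample_id
                for c in calls
                if c.sample_id in kept
                and c.chrom == chrom
                and c.matches_class(cnv_class)
                and c.start <= pos <= c.end
            }
            counts.append(len(carriers))
        out[chrom] = counts
    return out


def _split_run(markers, max_span_bp):
    """markers: list of (pos, name, count). Recursive interior-minimum split."""
    if not markers:
        return []
    span = markers[-1][0] - markers[0][0] + 1
    if span < max_span_bp:
        return [markers]
    if len(markers) <= 2:
        return [[m] for m in markers]
    interior = markers[1:-1]
    k = 1 + min(range(len(interior)), key=lambda i: interior[i][2])
    return _split_run(markers[:k], max_span_bp) + _split_run(markers[k + 1 :], max_span_bp)


def brute_cnvrs(calls, snp_map, kept, cfg, classes=("DEL", "DUP", "HD")):
    """CNVRs by per-marker counting, run detection and recursive splitting.

    Returns a set of (class, chrom, start, end, marker_names) tuples.
    """
    n = len(set(kept))
    thr = max(cfg.min_carriers - 1, cfg.freq_threshold * n)
    regions = set()
    for cls in classes:
        counts = brute_marker_counts(calls, snp_map, kept, cls)
        for chrom, cvec in counts.items():
            pos = snp_map.positions(chrom)
            names = snp_map.names(chrom)
            run = []
            for i, cnt in enumerate(list(cvec) + [0]):  # sentinel flushes
                if i < len(cvec) and cnt > thr:
                    run.append((int(pos[i]), str(names[i]), cnt))
                elif run:
                    for piece in _split_run(run, cfg.max_span_bp):
                        regions.add(
                            (
                                cls,
                                chrom,
                                piece[0][0],
                                piece[-1][0],
                                tuple(m[1] for m in piece),
                            )
                        )
                    run = []
    return regions


def brute_carriers(calls, kept, cnv_class, chrom, start, end):
    """Distinct class-matching samples overlapping [start, end] by >= 1 bp."""
    kept = set(kept)
    return {
        c.sample_id
        for c in calls
        if c.sample_id in kept
        and c.chrom == chrom
        and c.matches_class(cnv_class)
        and c.start <= end
        and c.end >= start
    }
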