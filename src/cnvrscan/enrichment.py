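"""Permutation-based annotation enrichment of CNVR sets.

The enrichment ratio (ER) of a CNVR set against an annotation track is
the observed number of CNVRs overlapping the track divided by the mean
of that count over random re-placements of the CNVRs. Placement keeps
each region on its own chromosome with its length, drawing the start
uniformly (rejection sampling against an optional excluded-region set).
Empirical p-values are one-tailed on the enriched side and mirrored for
depletion.

Also here: genic/exonic overlap fractions and the "unreported"
classification against a DGV-style catalog (<50% of the region's length
covered by any single catalog interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import GenomeIntervalSet


@dataclass(frozen=True)
class EnrichConfig:
    n_permutations: int = 10_000
    seed: int = 0
    max_attempts: int = 1000  # rejection-sampling cap per region

    def __post_init__(self):
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass(frozen=True)
class EnrichmentResult:
    track: str
    observed: int
    permuted_mean: float
    permuted_sd: float
    er: float  # observed / permuted mean (inf when the null mean is 0)
    p: float
    n_permutations: int


Region = tuple[str, int, int]


def _as_regions(cnvrs) -> list[Region]:
    out = []
    for r in cnvrs:
        if isinstance(r, tuple):
            out.append(r)
        else:
            out.append((r.chrom, r.start, r.end))
    return out


def overlaps_any(cnvrs, track: GenomeIntervalSet) -> int:
    """Number of CNVRs sharing >= 1 bp with any track interval."""
    return sum(1 for chrom, s, e in _as_regions(cnvrs) if track.overlaps(chrom, s, e))


def random_placement(
    cnvrs,
    chrom_sizes: dict[str, int],
    excluded: Optional[GenomeIntervalSet],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> list[Region]:
    """Re-place each region uniformly at random on its own chromosome.

    Length is preserved; placements intersecting the excluded set are
    rejected and redrawn, up to ``max_attempts`` per region.
    """
    placed: list[Region] = []
    for chrom, s, e in _as_regions(cnvrs):
        length = e - s + 1
        size = chrom_sizes[chrom]
        hi = size - length + 1
        if hi < 1:
            raise ValueError(f"region {chrom}:{s}-{e} does not fit on its chromosome")
        for attempt in range(max_attempts):
            start = int(rng.integers(1, hi + 1))
            if excluded is None or not excluded.overlaps(chrom, start, start + length - 1):
                placed.append((chrom, start, start + length - 1))
                break
        else:
            raise ValueError(
                f"could not place region {chrom}:{s}-{e} outside excluded regions"
            )
    return placed


def enrichment_ratio(
    cnvrs,
    track: GenomeIntervalSet,
    chrom_sizes: dict[str, int],
    cfg: EnrichConfig = EnrichConfig(),
    excluded: Optional[GenomeIntervalSet] = None,
) -> EnrichmentResult:
    """ER = observed overlap count / mean count over random placements."""
    regions = _as_regions(cnvrs)
    observed = overlaps_any(regions, track)
    rng = np.random.default_rng(cfg.seed)
    counts = np.empty(cfg.n_permutations, dtype=np.int64)
    for k in range(cfg.n_permutations):
        placed = random_placement(regions, chrom_sizes, excluded, rng, cfg.max_attempts)
        counts[k] = overlaps_any(placed, track)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if cfg.n_permutations > 1 else 0.0
    n = cfg.n_permutations
    if mean == 0.0:
        if observed == 0:
            return EnrichmentResult(track.name, 0, 0.0, sd, 1.0, 1.0, n)
        return EnrichmentResult(track.name, observed, 0.0, sd, math.inf, 1.0 / (n + 1), n)
    er = observed / mean
    if er >= 1.0:
        p = (1 + int(np.sum(counts >= observed))) / (n + 1)
    else:
        p = (1 + int(np.sum(counts <= observed))) / (n + 1)
    return EnrichmentResult(track.name, observed, mean, sd, er, p, n)


def genic_exonic_fractions(
    cnvrs, gene_track: GenomeIntervalSet, exon_track: GenomeIntervalSet
) -> dict:
    """Fractions of CNVRs overlapping >= 1 gene and >= 1 coding exon."""
    regions = _as_regions(cnvrs)
    n = len(regions)
    n_genic = overlaps_any(regions, gene_track)
    n_exonic = overlaps_any(regions, exon_track)
    return {
        "n_cnvrs": n,
        "n_genic": n_genic,
        "n_exonic": n_exonic,
        "genic_fraction": n_genic / n if n else 0.0,
        "exonic_fraction": n_exonic / n if n else 0.0,
    }


def classify_unreported(cnvrs, dgv_track: GenomeIntervalSet) -> list[bool]:
    """Unreported iff no catalog interval covers >= 50% of the region."""
    return [
        dgv_track.max_interval_overlap_fraction(chrom, s, e) < 0.5
        for chrom, s, e in _as_regions(cnvrs)
    ]
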