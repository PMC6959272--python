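"""Hardy-Weinberg screen for homozygous-deletion depletion.

Common deletion regions at which no homozygous (CN=0) carrier is ever
observed are candidates for embryonic lethality or early death. The null
model is Hardy-Weinberg equilibrium: a deletion carrier frequency f
implies an allele frequency q = f/2 (rare-variant approximation
2q(1-q) ~ 2q), so the probability of observing zero homozygotes among N
subjects is (1 - q^2)^N, evaluated in log space. A region is flagged
when it is screenable (f >= 1.25% by default), has zero observed
homozygous carriers, and (1 - q^2)^N < alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .cnvr import Cnvr
from .io_formats import CnvCall


@dataclass(frozen=True)
class LethalityConfig:
    min_carrier_freq: float = 0.0125
    alpha: float = 0.05


@dataclass(frozen=True)
class LethalityResult:
    cnvr: Cnvr
    carrier_freq: float
    allele_freq: float
    expected_hd: float
    observed_hd: int
    p_zero: float
    flagged: bool


def zero_hd_pvalue(carrier_freq: float, n_samples: int) -> float:
    """P(zero CN=0 carriers among n_samples) under the HWE null.

    q = carrier_freq / 2; p = (1 - q^2)^N computed as exp(N * log1p(-q^2)).
    Strictly decreasing in both arguments.
    """
    if not 0.0 < carrier_freq < 1.0:
        raise ValueError("carrier_freq must lie in (0, 1)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    q = carrier_freq / 2.0
    return math.exp(n_samples * math.log1p(-q * q))


def min_screenable_frequency(alpha: float, n_samples: int) -> float:
    """Smallest carrier frequency at which a zero count can reach alpha.

    Solves (1 - (f/2)^2)^N = alpha under the small-q approximation
    exp(-N q^2): f* = 2 sqrt(-ln(alpha) / N).
    """
    return 2.0 * math.sqrt(-math.log(alpha) / n_samples)


def hd_carriers_per_region(
    del_cnvrs: Sequence[Cnvr], calls: Sequence[CnvCall]
) -> list[int]:
    """Distinct CN=0 carriers overlapping each region by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for c in calls:
        if c.copy_number == 0:
            trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end + 1, c.sample_id)
    out = []
    for r in del_cnvrs:
        tree = trees.get(r.chrom)
        out.append(len({iv.data for iv in tree.overlap(r.start, r.end + 1)}) if tree else 0)
    return out


def lethality_scan(
    del_cnvrs: Sequence[Cnvr],
    hd_counts: Sequence[int],
    n_samples: int,
    cfg: LethalityConfig = LethalityConfig(),
) -> list[LethalityResult]:
    """Screen common deletion CNVRs for homozygote depletion.

    Only regions with carrier frequency >= cfg.min_carrier_freq enter the
    screen. ``hd_counts`` gives the observed CN=0 carrier count per region
    (same order as ``del_cnvrs``), computed over the same sample set.
    """
    if len(hd_counts) != len(del_cnvrs):
        raise ValueError("hd_counts must align with del_cnvrs")
    out = []
    for region, observed in zip(del_cnvrs, hd_counts):
        if region.frequency is None:
            raise ValueError("del_cnvrs must carry frequencies (run assign_carriers)")
        f = region.frequency
        if f < cfg.min_carrier_freq:
            continue
        q = f / 2.0
        p_zero = zero_hd_pvalue(f, n_samples)
        out.append(
            LethalityResult(
                cnvr=region,
                carrier_freq=f,
                allele_freq=q,
                expected_hd=n_samples * q * q,
                observed_hd=int(observed),
                p_zero=p_zero,
                flagged=(observed == 0 and p_zero < cfg.alpha),
            )
        )
    return out
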