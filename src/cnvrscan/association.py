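"""Per-SNP case/control association scans and disease-associated CNVRs.

The unit of testing is carrier status at a marker: for each disease
category, CNV class and marker, a 2x2 table of carriers vs non-carriers
in cases and controls is tested with the two-sided Fisher exact test
(minimum-likelihood summation). Runs of consecutive, same-direction
significant markers collapse into disease-associated CNVRs (DA-CNVRs).
Family-wise calibration uses label permutations: the genome-wide minimum
p per permutation yields empirical thresholds and adjusted p-values.
The evidence filter applies the three-lines rule: independent same-
direction replication at p < 0.05, permutation support, and absence of
control enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import fisher_exact

from .cnvr import count_marker_states
from .io_formats import CNV_CLASSES, DISEASE_CATEGORIES, CnvCall, SampleRecord, SnpMap


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier 2x2 table: a/b = case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def direction(self) -> str:
        # case-enriched iff carrier fraction higher in cases; ties count as
        # control-enriched (they are never significant)
        return (
            "case-enriched"
            if self.a * (self.c + self.d) > self.c * (self.a + self.b)
            else "control-enriched"
        )


@dataclass(frozen=True)
class AssocConfig:
    nominal_alpha: float = 0.05
    genomewide_alpha: float = 5e-8  # DEL/DUP extended-results threshold
    table_alpha: float = 9e-14  # headline threshold
    hd_alpha: float = 5e-4  # homozygous-deletion threshold
    n_permutations: int = 200
    seed: int = 0
    require_replication: bool = True


@dataclass(frozen=True)
class AssociationResult:
    marker: str
    chrom: str
    pos: int
    cnv_class: str
    category: str
    table: ContingencyTable
    odds_ratio: Optional[float]
    p: float
    direction: str


@dataclass
class DaCnvr:
    """A run of consecutive same-direction significant markers."""

    chrom: str
    start: int
    end: int
    cnv_class: str
    category: str
    min_p: float
    peak_marker: str
    peak_table: ContingencyTable
    direction: str
    marker_names: tuple[str, ...]
    replicated: Optional[bool] = None  # None = not evaluable
    permutation_pass: Optional[bool] = None
    not_control_enriched: bool = True

    @property
    def retained(self) -> bool:
        flags = [self.not_control_enriched]
        if self.replicated is not None:
            flags.append(self.replicated)
        if self.permutation_pass is not None:
            flags.append(self.permutation_pass)
        return all(flags)


@lru_cache(maxsize=2_000_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_two_sided(table: ContingencyTable) -> tuple[float, Optional[float]]:
    """Two-sided Fisher exact p and the sample odds ratio (a*d)/(b*c).

    The p-value sums hypergeometric probabilities no larger than the
    observed table's (with a small relative tolerance for ties) and is
    clipped to (0, 1]. The odds ratio is absent when b*c = 0.

    Raises on a zero group margin (no cases or no controls).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("fisher_two_sided: empty case or control group")
    p = min(_fisher_cached(a, b, c, d), 1.0)
    orat = (a * d) / (b * c) if b * c > 0 else None
    return p, orat


@dataclass
class ScanResult:
    results: list[AssociationResult]
    n_markers: int  # total markers on the map (incl. untested carrier-free ones)
    case_n: dict[str, int] = field(default_factory=dict)
    control_n: int = 0

    def nominal(self, alpha: float = 0.05) -> list[AssociationResult]:
        return [r for r in self.results if r.p < alpha]


def marker_scan(
    calls: Sequence[CnvCall],
    snp_map: SnpMap,
    samples: Sequence[SampleRecord],
    kept_ids: Iterable[str],
    cfg: AssocConfig = AssocConfig(),
    classes: Sequence[str] = CNV_CLASSES,
    categories: Sequence[str] = DISEASE_CATEGORIES,
) -> ScanResult:
    """Fisher scan of every marker for each (class, category) pair.

    Controls are CONTROL-phenotype samples only. Markers without a single
    carrier in either group are not tested (their p is 1 by construction)
    but count toward ``n_markers``.
    """
    kept = set(kept_ids)
    pheno: dict[str, list[str]] = {}
    for s in samples:
        if s.sample_id in kept:
            pheno.setdefault(s.phenotype, []).append(s.sample_id)
    controls = pheno.get("CONTROL", [])
    if not controls:
        raise ValueError("no control samples after QC")
    ctl_counts = count_marker_states(calls, snp_map, controls)
    n_ctl = len(controls)
    out = ScanResult(results=[], n_markers=snp_map.n_markers, control_n=n_ctl)
    for category in categories:
        cases = pheno.get(category, [])
        if not cases:
            raise ValueError(f"no samples in category {category!r}")
        n_case = len(cases)
        out.case_n[category] = n_case
        case_counts = count_marker_states(calls, snp_map, cases)
        for cls in classes:
            for chrom in snp_map.chroms:
                a_vec = case_counts.of(cls, chrom)
                c_vec = ctl_counts.of(cls, chrom)
                tested = np.flatnonzero((a_vec > 0) | (c_vec > 0))
                names = snp_map.names(chrom)
                positions = snp_map.positions(chrom)
                for i in tested:
                    tab = ContingencyTable(
                        int(a_vec[i]), n_case - int(a_vec[i]), int(c_vec[i]), n_ctl - int(c_vec[i])
                    )
                    p, orat = fisher_two_sided(tab)
                    out.results.append(
                        AssociationResult(
                            marker=str(names[i]),
                            chrom=chrom,
                            pos=int(positions[i]),
                            cnv_class=cls,
                            category=category,
                            table=tab,
                            odds_ratio=orat,
                            p=p,
                            direction=tab.direction,
                        )
                    )
    return out


def collapse_significant_markers(
    results: Sequence[AssociationResult],
    snp_map: SnpMap,
    threshold: float,
) -> list[DaCnvr]:
    """Merge runs of consecutive same-direction significant markers.

    ``results`` must come from a single (class, category) scan. Markers
    are consecutive when adjacent on the marker map.
    """
    keys = {(r.cnv_class, r.category) for r in results}
    if len(keys) > 1:
        raise ValueError("collapse expects results from one (class, category) scan")
    sig = [r for r in results if r.p < threshold]
    if not sig:
        return []
    cls, category = next(iter(keys))
    indexed = sorted(
        ((snp_map.locate(r.marker), r) for r in sig),
        key=lambda t: (t[0][0], t[0][1]),
    )
    regions: list[DaCnvr] = []
    run: list[tuple[tuple[str, int, int], AssociationResult]] = []

    def _flush():
        if not run:
            return
        rs = [r for _, r in run]
        best = min(rs, key=lambda r: r.p)
        regions.append(
            DaCnvr(
                chrom=run[0][0][0],
                start=run[0][0][2],
                end=run[-1][0][2],
                cnv_class=cls,
                category=category,
                min_p=best.p,
                peak_marker=best.marker,
                peak_table=best.table,
                direction=best.direction,
                marker_names=tuple(r.marker for r in rs),
                not_control_enriched=best.direction == "case-enriched",
            )
        )

    for loc, r in indexed:
        if run and (
            loc[0] != run[-1][0][0]
            or loc[1] != run[-1][0][1] + 1
            or r.direction != run[-1][1].direction
        ):
            _flush()
            run = []
        run.append((loc, r))
    _flush()
    return regions


@dataclass
class PermutationResult:
    min_p: np.ndarray  # genome-wide minimum p per permutation
    n_permutations: int

    def adjusted_p(self, observed_p: float) -> float:
        return (1 + int(np.sum(self.min_p <= observed_p))) / (self.n_permutations + 1)

    def threshold(self, alpha: float = 0.05) -> float:
        """Empirical family-wise threshold: alpha-quantile of min p."""
        return float(np.quantile(self.min_p, alpha))


def permutation_familywise(
    calls: Sequence[CnvCall],
    snp_map: SnpMap,
    samples: Sequence[SampleRecord],
    kept_ids: Iterable[str],
    cnv_class: str,
    category: str,
    cfg: AssocConfig = AssocConfig(),
) -> PermutationResult:
    """Permute case/control labels; record the genome-wide minimum p.

    Each sample keeps its full call profile; only the labels move, which
    preserves the spatial structure of the CNVs under the null.
    """
    if cfg.n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    kept = set(kept_ids)
    pool = [
        s.sample_id
        for s in samples
        if s.sample_id in kept and s.phenotype in (category, "CONTROL")
    ]
    n_case = sum(
        1 for s in samples if s.sample_id in kept and s.phenotype == category
    )
    col = {sid: j for j, sid in enumerate(pool)}
    # sparse marker x sample carrier incidence over the pooled group
    rows: list[int] = []
    cols: list[int] = []
    offsets: dict[str, int] = {}
    off = 0
    for chrom in snp_map.chroms:
        offsets[chrom] = off
        off += len(snp_map.positions(chrom))
    for c in calls:
        j = col.get(c.sample_id)
        if j is None or not c.matches_class(cnv_class):
            continue
        rng = snp_map.marker_range(c.chrom, c.start, c.end)
        if rng is None:
            continue
        base = offsets[c.chrom]
        for i in range(rng[0], rng[1] + 1):
            rows.append(base + i)
            cols.append(j)
    m = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(off, len(pool)),
    )
    m.data[:] = 1  # collapse duplicate entries from overlapping calls
    m.sum_duplicates()
    m = (m > 0).astype(np.int64)
    row_tot = np.asarray(m.sum(axis=1)).ravel()
    active = np.flatnonzero(row_tot)
    m_active = m[active]
    n_pool = len(pool)
    n_ctl = n_pool - n_case
    rng_perm = np.random.default_rng(cfg.seed)
    min_p = np.ones(cfg.n_permutations)
    for k in range(cfg.n_permutations):
        ind = np.zeros(n_pool, dtype=np.int64)
        ind[rng_perm.choice(n_pool, size=n_case, replace=False)] = 1
        a = np.asarray(m_active @ ind).ravel()
        c = row_tot[active] - a
        best = 1.0
        for aj, cj in zip(a, c):
            p = _fisher_cached(int(aj), n_case - int(aj), int(cj), n_ctl - int(cj))
            if p < best:
                best = p
        min_p[k] = best
    return PermutationResult(min_p=min_p, n_permutations=cfg.n_permutations)


def evidence_filter(
    da_cnvrs: Sequence[DaCnvr],
    replication_results: Optional[Sequence[AssociationResult]],
    cfg: AssocConfig = AssocConfig(),
    permutation: Optional[PermutationResult] = None,
    permutation_alpha: float = 0.05,
) -> tuple[list[DaCnvr], list[DaCnvr]]:
    """Apply the three-lines-of-evidence rule.

    Returns (all regions with flags set, retained regions). A region is
    retained when it is case-enriched, replicates with the same direction
    at p < 0.05 in the held-out cohort (unless replication is not
    evaluable and not required), and passes the permutation criterion
    when a permutation null is supplied.
    """
    rep_by_marker = {}
    if replication_results:
        for r in replication_results:
            rep_by_marker[(r.marker, r.cnv_class, r.category)] = r
    flagged: list[DaCnvr] = []
    for region in da_cnvrs:
        rep = rep_by_marker.get((region.peak_marker, region.cnv_class, region.category))
        if replication_results is None:
            replicated = None  # single-cohort input: not evaluable
        elif rep is None:
            replicated = False
        else:
            replicated = rep.p < cfg.nominal_alpha and rep.direction == region.direction
        perm_pass = None
        if permutation is not None:
            perm_pass = permutation.adjusted_p(region.min_p) < permutation_alpha
        flagged.append(
            replace(
                region,
                replicated=replicated,
                permutation_pass=perm_pass,
                not_control_enriched=region.direction == "case-enriched",
            )
        )
    retained = [
        r
        for r in flagged
        if r.retained and not (r.replicated is None and cfg.require_replication)
    ]
    return flagged, retained
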