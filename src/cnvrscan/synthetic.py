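"""Synthetic SNP-array CNV cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
marker panel, a manifest of samples in four disease categories plus
controls, background deletion/duplication calls calibrated to a target
mean per-genome burden, planted recurrent CNVRs, planted
disease-associated loci with configured odds ratios, loci with
Hardy-Weinberg-consistent homozygous deletions, "lethal" deletion loci
that never emit a homozygous carrier, family trios with a configurable
de novo rate, replicate pairs, and QC-failing samples.

A single global seed drives named substreams (markers / samples /
background / planted / trios / replicates / tracks), so enabling one
component does not perturb the draws of another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    CnvCall,
    GenomeIntervalSet,
    SampleRecord,
    SnpMap,
    write_chrom_sizes,
    write_bed,
    write_rawcnv,
    write_sample_table,
    write_snp_map,
)

# substream labels -> spawn indices of the root SeedSequence
_STREAMS = {
    "markers": 0,
    "samples": 1,
    "background": 2,
    "planted": 3,
    "trios": 4,
    "replicates": 5,
    "tracks": 6,
}

# category mix of the 100,028-subject study population:
# autoimmune 11,489; cancer 9,105; cardio-metabolic 2,581; neuro 43,841;
# remainder healthy controls.
DEFAULT_CATEGORY_FRACTIONS = {
    "AID": 0.1149,
    "CANCER": 0.0910,
    "CARDIO": 0.0258,
    "NEURO": 0.4383,
    "CONTROL": 0.3300,
}

DEFAULT_CHROM_SIZES = {"chr1": 60_000_000, "chr2": 45_000_000, "chr3": 30_000_000}


@dataclass(frozen=True)
class PlantedCnvr:
    chrom: str
    start: int
    end: int
    cnv_class: str  # DEL / DUP / HD
    frequency: float  # carrier frequency


@dataclass(frozen=True)
class PlantedAssociation:
    chrom: str
    start: int
    end: int
    cnv_class: str
    category: str  # disease category enriched for carriers
    odds_ratio: float
    control_frequency: float = 0.01


@dataclass(frozen=True)
class LethalLocus:
    """Deletion locus at which homozygous (CN=0) carriers never occur."""

    chrom: str
    start: int
    end: int
    carrier_frequency: float


@dataclass(frozen=True)
class HweDeletionLocus:
    """Deletion locus with genotypes drawn from Hardy-Weinberg equilibrium.

    CN=0 with probability q^2, CN=1 with probability 2q(1-q) for allele
    frequency q; used to exercise the lethality screen's null.
    """

    chrom: str
    start: int
    end: int
    allele_frequency: float


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic cohort.

    Background rates are calibrated so the mean per-genome burden matches
    the configured targets (defaults: 370 kb duplicated, 285 kb deleted,
    of which 9.5 kb homozygous-deleted). Call lengths are log-normal,
    truncated to [length_min, length_max].
    """

    n_samples: int = 5_000
    n_markers: int = 10_000
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    category_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS)
    )
    mean_del_burden_bp: float = 285_000.0
    mean_dup_burden_bp: float = 370_000.0
    mean_hd_burden_bp: float = 9_500.0
    length_log_mean: float = math.log(30_000.0)
    length_log_sd: float = 1.1
    length_min: int = 1_000
    length_max: int = 2_000_000
    planted_cnvrs: Sequence[PlantedCnvr] = ()
    planted_associations: Sequence[PlantedAssociation] = ()
    lethal_loci: Sequence[LethalLocus] = ()
    hwe_del_loci: Sequence[HweDeletionLocus] = ()
    trio_count: int = 0
    de_novo_rate: float = 0.06
    replicate_pairs: int = 0
    discordance_rate: float = 0.02
    qc_fail_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "CALL_RATE": 0.005,
            "LRR_SD": 0.005,
            "GC_WAVE": 0.003,
            "CALL_COUNT": 0.002,
        }
    )
    include_tracks: bool = True
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"category fractions sum to {total}, expected 1")
        for p in self.planted_cnvrs:
            if not 0.0 <= p.frequency <= 1.0:
                raise ValueError(f"planted frequency {p.frequency} outside [0, 1]")
        for a in self.planted_associations:
            if a.odds_ratio <= 0:
                raise ValueError("odds_ratio must be > 0")
            if not 0.0 <= a.control_frequency <= 1.0:
                raise ValueError("control_frequency outside [0, 1]")
        if not 0.0 <= self.de_novo_rate <= 1.0:
            raise ValueError("de_novo_rate outside [0, 1]")
        if not 0.0 <= self.discordance_rate <= 1.0:
            raise ValueError("discordance_rate outside [0, 1]")
        if 3 * self.trio_count + 2 * self.replicate_pairs > self.n_samples:
            raise ValueError("trio_count/replicate_pairs exceed available samples")
        if self.length_min >= self.length_max:
            raise ValueError("length_min must be < length_max")

    def mean_call_length(self) -> float:
        """Analytic mean of the truncated log-normal call-length law."""
        mu, sd = self.length_log_mean, self.length_log_sd
        a, b = math.log(self.length_min), math.log(self.length_max)
        z = stats.norm.cdf((b - mu) / sd) - stats.norm.cdf((a - mu) / sd)
        tail = stats.norm.cdf((b - mu - sd * sd) / sd) - stats.norm.cdf((a - mu - sd * sd) / sd)
        return math.exp(mu + sd * sd / 2.0) * tail / z


@dataclass
class SyntheticCohort:
    snp_map: SnpMap
    samples: list[SampleRecord]
    calls: list[CnvCall]
    tracks: dict[str, GenomeIntervalSet]
    truth: dict
    config: SimConfig


def association_case_frequency(odds_ratio: float, control_frequency: float) -> float:
    """Carriage probability in cases for a target carriage odds ratio.

    Inverts the odds model: p_case = OR*p0 / (1 - p0 + OR*p0), so the true
    carriage odds ratio between cases and controls is exactly OR.
    """
    p0 = control_frequency
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(cfg_seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def _truncated_lognormal(rng, n, cfg: SimConfig) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    need = np.arange(n)
    while need.size:
        draw = rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, need.size)
        ok = (draw >= cfg.length_min) & (draw <= cfg.length_max)
        out[need[ok]] = draw[ok].astype(np.int64)
        need = need[~ok]
    return out


def _make_snp_map(cfg: SimConfig, rng) -> SnpMap:
    total = sum(cfg.chrom_sizes.values())
    markers = []
    counter = 0
    chroms = sorted(cfg.chrom_sizes)
    alloc = {c: int(round(cfg.n_markers * cfg.chrom_sizes[c] / total)) for c in chroms}
    # fix rounding drift on the first chromosome
    alloc[chroms[0]] += cfg.n_markers - sum(alloc.values())
    for chrom in chroms:
        n_c = alloc[chrom]
        size = cfg.chrom_sizes[chrom]
        pos: np.ndarray = np.unique(rng.integers(1, size + 1, size=int(n_c * 1.2) + 10))
        while pos.size < n_c:
            pos = np.unique(np.concatenate([pos, rng.integers(1, size + 1, size=n_c)]))
        pos = np.sort(rng.choice(pos, size=n_c, replace=False))
        for p in pos:
            counter += 1
            markers.append((f"rs{counter:07d}", chrom, int(p)))
    return SnpMap(markers)


def _make_samples(cfg: SimConfig, rng) -> list[SampleRecord]:
    n = cfg.n_samples
    cats = list(cfg.category_fractions)
    counts = [int(math.floor(cfg.category_fractions[c] * n)) for c in cats]
    # distribute the rounding remainder over the largest fractions
    rem = n - sum(counts)
    order = np.argsort([-cfg.category_fractions[c] for c in cats])
    for k in range(rem):
        counts[order[k % len(cats)]] += 1
    phenos = np.repeat(cats, counts)
    rng.shuffle(phenos)
    cohorts = np.where(rng.random(n) < 0.523, "COH1", "COH2")

    call_rate = rng.uniform(0.985, 0.999, n)
    lrr_sd = rng.uniform(0.05, 0.20, n)
    gc_wave = rng.uniform(-0.015, 0.015, n)
    # planted QC failures (disjoint sample sets per reason)
    fail_pool = rng.permutation(n)
    cursor = 0
    fail_call_count: set[int] = set()
    for reason, frac in cfg.qc_fail_fractions.items():
        k = int(round(frac * n))
        idx = fail_pool[cursor : cursor + k]
        cursor += k
        if reason == "CALL_RATE":
            call_rate[idx] = rng.uniform(0.90, 0.98, k)
        elif reason == "LRR_SD":
            lrr_sd[idx] = rng.uniform(0.25, 0.40, k)
        elif reason == "GC_WAVE":
            gc_wave[idx] = rng.choice([-1, 1], k) * rng.uniform(0.02, 0.05, k)
        elif reason == "CALL_COUNT":
            fail_call_count.update(int(i) for i in idx)

    samples = []
    for i in range(n):
        sid = f"S{i + 1:06d}"
        father = mother = replicate = None
        if i < 3 * cfg.trio_count and i % 3 == 2:  # trios laid out F, M, child
            father, mother = f"S{i - 1:06d}", f"S{i:06d}"
        rep_base = 3 * cfg.trio_count
        if rep_base <= i < rep_base + 2 * cfg.replicate_pairs and (i - rep_base) % 2 == 1:
            replicate = f"S{i:06d}"  # the preceding sample
        samples.append(
            SampleRecord(
                sample_id=sid,
                cohort_id=str(cohorts[i]),
                phenotype=str(phenos[i]),
                call_rate=float(call_rate[i]),
                lrr_sd=float(lrr_sd[i]),
                gc_wave=float(gc_wave[i]),
                father_id=father,
                mother_id=mother,
                replicate_of=replicate,
            )
        )
    # stash call-count failures for the call generator
    samples_fail_cc = [f"S{i + 1:06d}" for i in sorted(fail_call_count)]
    return samples, samples_fail_cc


def _background_calls_for(
    cfg: SimConfig, rng, sample_ids: Sequence[str], extra_counts: Optional[dict[str, int]] = None
) -> list[CnvCall]:
    """Draw Poisson per-sample DEL and DUP calls matching the burden targets."""
    mean_len = cfg.mean_call_length()
    lam_del = cfg.mean_del_burden_bp / mean_len
    lam_dup = cfg.mean_dup_burden_bp / mean_len
    hd_frac = cfg.mean_hd_burden_bp / cfg.mean_del_burden_bp if cfg.mean_del_burden_bp else 0.0
    chroms = sorted(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.float64)
    weights = sizes / sizes.sum()

    calls: list[CnvCall] = []
    for kind, lam in (("DEL", lam_del), ("DUP", lam_dup)):
        counts = rng.poisson(lam, len(sample_ids))
        if extra_counts and kind == "DEL":
            for j, sid in enumerate(sample_ids):
                counts[j] += extra_counts.get(sid, 0)
        total = int(counts.sum())
        if total == 0:
            continue
        lens = _truncated_lognormal(rng, total, cfg)
        ci = rng.choice(len(chroms), size=total, p=weights)
        starts = np.empty(total, dtype=np.int64)
        for k in range(len(chroms)):
            m = ci == k
            hi = np.maximum(int(sizes[k]) - lens[m] + 1, 1)
            starts[m] = (rng.random(m.sum()) * hi).astype(np.int64) + 1
        if kind == "DEL":
            cn = np.where(rng.random(total) < hd_frac, 0, 1)
        else:
            cn = np.where(rng.random(total) < 0.05, 4, 3)
        owner = np.repeat(np.arange(len(sample_ids)), counts)
        for j in range(total):
            chrom = chroms[ci[j]]
            s = int(starts[j])
            e = min(int(s + lens[j] - 1), cfg.chrom_sizes[chrom])
            calls.append(CnvCall(sample_ids[owner[j]], chrom, s, e, int(cn[j])))
    return calls


def _one_background_call(cfg: SimConfig, rng, sample_id: str) -> CnvCall:
    """One fresh background-style call (used for de novo and discordant calls)."""
    chroms = sorted(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.float64)
    chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
    length = int(_truncated_lognormal(rng, 1, cfg)[0])
    start = int(rng.integers(1, max(cfg.chrom_sizes[chrom] - length + 1, 1) + 1))
    p_dup = cfg.mean_dup_burden_bp / (cfg.mean_dup_burden_bp + cfg.mean_del_burden_bp)
    cn = 3 if rng.random() < p_dup else 1
    return CnvCall(sample_id, chrom, start, min(start + length - 1, cfg.chrom_sizes[chrom]), cn)


_CLASS_CN = {"DEL": 1, "HD": 0, "DUP": 3}


def _check_on_map(snp_map: SnpMap, chrom: str, start: int, end: int, what: str) -> None:
    if snp_map.marker_range(chrom, start, end) is None:
        raise ValueError(f"planted {what} {chrom}:{start}-{end} covers no marker on the map")


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a complete cohort; byte-identical for identical config."""
    cfg.validate()
    snp_map = _make_snp_map(cfg, _rng(cfg.seed, "markers"))
    samples, fail_call_count = _make_samples(cfg, _rng(cfg.seed, "samples"))
    sample_ids = [s.sample_id for s in samples]
    pheno = {s.sample_id: s.phenotype for s in samples}

    n_trio_members = 3 * cfg.trio_count
    trio_children = {sample_ids[3 * t + 2] for t in range(cfg.trio_count)}
    rep_base = n_trio_members
    replicate_pairs = [
        (sample_ids[rep_base + 2 * r], sample_ids[rep_base + 2 * r + 1])
        for r in range(cfg.replicate_pairs)
    ]
    rep_seconds = {b for _, b in replicate_pairs}
    independent = [s for s in sample_ids if s not in trio_children and s not in rep_seconds]

    bg_rng = _rng(cfg.seed, "background")
    extra = {sid: 150 for sid in fail_call_count if sid in independent}
    calls = _background_calls_for(cfg, bg_rng, independent, extra_counts=extra)

    # planted loci (carriers only among independent samples; children and
    # replicate copies pick them up through transmission/copying below)
    planted_rng = _rng(cfg.seed, "planted")
    truth: dict = {
        "planted_cnvrs": [],
        "planted_associations": [],
        "lethal_loci": [],
        "hwe_del_loci": [],
    }
    for p in cfg.planted_cnvrs:
        chrom = p.chrom if p.chrom.startswith("chr") else "chr" + p.chrom
        _check_on_map(snp_map, chrom, p.start, p.end, "CNVR")
        carriers = [sid for sid in independent if planted_rng.random() < p.frequency]
        cn = _CLASS_CN[p.cnv_class]
        rng_range = snp_map.marker_range(chrom, p.start, p.end)
        n_snps = rng_range[1] - rng_range[0] + 1
        for sid in carriers:
            calls.append(CnvCall(sid, chrom, p.start, p.end, cn, n_snps=n_snps))
        truth["planted_cnvrs"].append({**asdict(p), "n_carriers": len(carriers)})
    for a in cfg.planted_associations:
        chrom = a.chrom if a.chrom.startswith("chr") else "chr" + a.chrom
        _check_on_map(snp_map, chrom, a.start, a.end, "association locus")
        p_case = association_case_frequency(a.odds_ratio, a.control_frequency)
        cn = _CLASS_CN[a.cnv_class]
        rng_range = snp_map.marker_range(chrom, a.start, a.end)
        n_snps = rng_range[1] - rng_range[0] + 1
        n_case = n_ctl = 0
        for sid in independent:
            prob = p_case if pheno[sid] == a.category else a.control_frequency
            if planted_rng.random() < prob:
                calls.append(CnvCall(sid, chrom, a.start, a.end, cn, n_snps=n_snps))
                if pheno[sid] == a.category:
                    n_case += 1
                elif pheno[sid] == "CONTROL":
                    n_ctl += 1
        truth["planted_associations"].append(
            {**asdict(a), "case_frequency": p_case, "n_case_carriers": n_case,
             "n_control_carriers": n_ctl}
        )
    # lethal loci admit no homozygous deletion anywhere in the cohort:
    # demote any background CN=0 call overlapping one to hemizygous
    if cfg.lethal_loci:
        lethal_iv = [
            (l.chrom if l.chrom.startswith("chr") else "chr" + l.chrom, l.start, l.end)
            for l in cfg.lethal_loci
        ]
        for i, c in enumerate(calls):
            if c.copy_number == 0 and any(
                c.chrom == lc and c.start <= le and c.end >= ls for lc, ls, le in lethal_iv
            ):
                calls[i] = CnvCall(c.sample_id, c.chrom, c.start, c.end, 1, c.n_snps, c.confidence)
    for l in cfg.lethal_loci:
        chrom = l.chrom if l.chrom.startswith("chr") else "chr" + l.chrom
        _check_on_map(snp_map, chrom, l.start, l.end, "lethal locus")
        rng_range = snp_map.marker_range(chrom, l.start, l.end)
        n_snps = rng_range[1] - rng_range[0] + 1
        n_car = 0
        for sid in independent:
            if planted_rng.random() < l.carrier_frequency:
                calls.append(CnvCall(sid, chrom, l.start, l.end, 1, n_snps=n_snps))
                n_car += 1
        truth["lethal_loci"].append({**asdict(l), "n_carriers": n_car})
    for h in cfg.hwe_del_loci:
        chrom = h.chrom if h.chrom.startswith("chr") else "chr" + h.chrom
        _check_on_map(snp_map, chrom, h.start, h.end, "HWE locus")
        rng_range = snp_map.marker_range(chrom, h.start, h.end)
        n_snps = rng_range[1] - rng_range[0] + 1
        q = h.allele_frequency
        n_het = n_hom = 0
        for sid in independent:
            u = planted_rng.random()
            if u < q * q:
                calls.append(CnvCall(sid, chrom, h.start, h.end, 0, n_snps=n_snps))
                n_hom += 1
            elif u < q * q + 2 * q * (1 - q):
                calls.append(CnvCall(sid, chrom, h.start, h.end, 1, n_snps=n_snps))
                n_het += 1
        truth["hwe_del_loci"].append({**asdict(h), "n_het": n_het, "n_hom": n_hom})

    # trios: each child call is a copy of a random parental call with
    # probability 1 - de_novo_rate, otherwise an independent placement
    trio_rng = _rng(cfg.seed, "trios")
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    trios = []
    truth["trios"] = []
    n_inherited = n_denovo = 0
    for t in range(cfg.trio_count):
        f, m, child = sample_ids[3 * t], sample_ids[3 * t + 1], sample_ids[3 * t + 2]
        trios.append((child, f, m))
        parental = by_sample.get(f, []) + by_sample.get(m, [])
        n_child = int(trio_rng.poisson(max(len(parental) / 2.0, 1.0)))
        child_calls: list[CnvCall] = []
        for _ in range(n_child):
            if parental and trio_rng.random() >= cfg.de_novo_rate:
                src = parental[int(trio_rng.integers(len(parental)))]
                child_calls.append(
                    CnvCall(child, src.chrom, src.start, src.end, src.copy_number, src.n_snps)
                )
                n_inherited += 1
            else:
                child_calls.append(_one_background_call(cfg, trio_rng, child))
                n_denovo += 1
        calls.extend(child_calls)
        by_sample[child] = child_calls
    truth["trio_transmitted"] = n_inherited
    truth["trio_de_novo"] = n_denovo
    truth["trios"] = trios

    # replicates: copy of the partner's call set with per-call discordance
    rep_rng = _rng(cfg.seed, "replicates")
    for a_id, b_id in replicate_pairs:
        b_calls = []
        for c in by_sample.get(a_id, []):
            if rep_rng.random() < cfg.discordance_rate:
                b_calls.append(_one_background_call(cfg, rep_rng, b_id))
            else:
                b_calls.append(CnvCall(b_id, c.chrom, c.start, c.end, c.copy_number, c.n_snps))
        calls.extend(b_calls)
        by_sample[b_id] = b_calls
    truth["replicate_pairs"] = replicate_pairs

    # recompute n_snps from the marker map (background calls carry a default)
    calls = _annotate_n_snps(calls, snp_map)

    tracks = _make_tracks(cfg, snp_map, _rng(cfg.seed, "tracks")) if cfg.include_tracks else {}
    truth["qc_fail_call_count_samples"] = fail_call_count
    return SyntheticCohort(snp_map, samples, calls, tracks, truth, cfg)


def _annotate_n_snps(calls: list[CnvCall], snp_map: SnpMap) -> list[CnvCall]:
    out = []
    for c in calls:
        rng_range = snp_map.marker_range(c.chrom, c.start, c.end)
        n = 1 if rng_range is None else rng_range[1] - rng_range[0] + 1
        out.append(CnvCall(c.sample_id, c.chrom, c.start, c.end, c.copy_number, max(n, 1),
                           c.confidence))
    return out


def _random_track(rng, chrom_sizes, n_per_chrom, mean_len) -> list[tuple[str, int, int]]:
    iv = []
    for chrom, size in sorted(chrom_sizes.items()):
        lens = np.maximum(rng.exponential(mean_len, n_per_chrom).astype(np.int64), 200)
        starts = (rng.random(n_per_chrom) * np.maximum(size - lens, 1)).astype(np.int64) + 1
        iv.extend((chrom, int(s), int(min(s + l - 1, size))) for s, l in zip(starts, lens))
    return iv


def _make_tracks(cfg: SimConfig, snp_map: SnpMap, rng) -> dict[str, GenomeIntervalSet]:
    """Random annotation tracks with plausible genome coverage."""
    sizes = cfg.chrom_sizes
    genes = _random_track(rng, sizes, n_per_chrom=400, mean_len=45_000)
    exons = []
    for chrom, s, e in genes:
        for _ in range(int(rng.integers(2, 9))):
            es = int(rng.integers(s, e + 1))
            exons.append((chrom, es, min(es + int(rng.integers(80, 300)), e)))
    keep = rng.random(len(genes)) < 0.15
    omim = [g for g, k in zip(genes, keep) if k]
    gwas = _random_track(rng, sizes, n_per_chrom=120, mean_len=10_000)
    hotspots = _random_track(rng, sizes, n_per_chrom=200, mean_len=2_000)
    dgv = _random_track(rng, sizes, n_per_chrom=300, mean_len=40_000)
    # DGV additionally includes the planted loci (they are "known" CNVs)
    for p in list(cfg.planted_cnvrs) + list(cfg.planted_associations):
        dgv.append((p.chrom if p.chrom.startswith("chr") else "chr" + p.chrom, p.start, p.end))
    return {
        "genes": GenomeIntervalSet("genes", genes),
        "exons": GenomeIntervalSet("exons", exons),
        "omim": GenomeIntervalSet("omim", omim),
        "gwas": GenomeIntervalSet("gwas", gwas),
        "hotspots": GenomeIntervalSet("hotspots", hotspots),
        "dgv": GenomeIntervalSet("dgv", dgv),
    }


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort directory consumed by the CLI stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_rawcnv(outdir / "calls.rawcnv", cohort.calls)
    write_snp_map(outdir / "snp_map.tsv", cohort.snp_map)
    write_sample_table(outdir / "samples.tsv", cohort.samples)
    write_chrom_sizes(outdir / "chrom.sizes", cohort.config.chrom_sizes)
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for name, track in cohort.tracks.items():
        write_bed(tracks_dir / f"{name}.bed", track)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, default=str)
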