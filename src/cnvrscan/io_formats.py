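"""Domain types and readers/writers for the external text formats.

Formats handled here:

* PennCNV ``rawcnv`` call lists (the primary input dialect),
* BED3 annotation tracks (converted to 1-based inclusive on read; this is
  the only place a coordinate convention conversion happens),
* TSV tables for the SNP marker map, the sample manifest, CNVR and
  association outputs,
* two-column ``chrom.sizes``.

Internal coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import merge as _merge_intervals

PHENOTYPES = ("AID", "CANCER", "CARDIO", "NEURO", "CONTROL")
DISEASE_CATEGORIES = ("AID", "CANCER", "CARDIO", "NEURO")
CNV_CLASSES = ("DEL", "DUP", "HD")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    return c if c.startswith("chr") else "chr" + c


@dataclass(frozen=True)
class CnvCall:
    """One sample's CNV segment with its integer copy-number state.

    DEL means copy number 0 or 1 (CN=0 additionally counts as HD,
    homozygous deletion); DUP means copy number >= 3. Diploid (CN=2)
    segments are not calls and are rejected.
    """

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    copy_number: int
    n_snps: int = 1
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValueError(f"invalid copy number {self.copy_number} (must be >=0 and != 2)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def cnv_class(self) -> str:
        return "DUP" if self.copy_number >= 3 else "DEL"

    @property
    def is_hd(self) -> bool:
        return self.copy_number == 0

    def matches_class(self, cnv_class: str) -> bool:
        """Whether this call belongs to a class (HD is a subset of DEL)."""
        if cnv_class == "DEL":
            return self.copy_number <= 1
        if cnv_class == "HD":
            return self.copy_number == 0
        if cnv_class == "DUP":
            return self.copy_number >= 3
        raise ValueError(f"unknown CNV class {cnv_class!r}")


@dataclass(frozen=True)
class SampleRecord:
    """Manifest row: phenotype category, platform cohort and array QC metrics."""

    sample_id: str
    cohort_id: str
    phenotype: str
    call_rate: float
    lrr_sd: float
    gc_wave: float
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    replicate_of: Optional[str] = None

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"call_rate {self.call_rate} outside [0, 1]")


def _chrom_sort_key(chrom: str):
    m = re.match(r"chr(\d+)$", chrom)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


class SnpMap:
    """Ordered SNP marker panel: (name, chrom, 1-based position) triples.

    Positions are strictly increasing within each chromosome; names are
    unique. Out-of-order input is sorted with a warning.
    """

    def __init__(self, markers: Iterable[tuple[str, str, int]]):
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        seen: set[str] = set()
        for name, chrom, pos in markers:
            name = str(name)
            if name in seen:
                raise ParseError(f"duplicate marker name {name!r}")
            seen.add(name)
            by_chrom.setdefault(normalize_chrom(chrom), []).append((int(pos), name))
        self._chroms = sorted(by_chrom, key=_chrom_sort_key)
        self._pos: dict[str, np.ndarray] = {}
        self._names: dict[str, np.ndarray] = {}
        self._index: dict[str, tuple[str, int]] = {}
        for chrom in self._chroms:
            entries = by_chrom[chrom]
            pos = np.array([p for p, _ in entries], dtype=np.int64)
            if np.any(np.diff(pos) < 0):
                warnings.warn(f"SNP map positions out of order on {chrom}; sorting")
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            if np.any(np.diff(pos) == 0):
                raise ParseError(f"duplicate marker position on {chrom}")
            names = np.array([entries[i][1] for i in order], dtype=object)
            self._pos[chrom] = pos
            self._names[chrom] = names
            for i, nm in enumerate(names):
                self._index[nm] = (chrom, i)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos[chrom]

    def names(self, chrom: str) -> np.ndarray:
        return self._names[chrom]

    def locate(self, name: str) -> tuple[str, int, int]:
        """Return (chrom, index-on-chrom, position) for a marker name."""
        chrom, i = self._index[name]
        return chrom, i, int(self._pos[chrom][i])

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def marker_range(self, chrom: str, start: int, end: int) -> Optional[tuple[int, int]]:
        """Inclusive index range of markers with start <= pos <= end, or None."""
        if chrom not in self._pos:
            return None
        pos = self._pos[chrom]
        i0 = int(np.searchsorted(pos, start, side="left"))
        i1 = int(np.searchsorted(pos, end, side="right")) - 1
        if i1 < i0:
            return None
        return i0, i1

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        for chrom in self._chroms:
            for name, pos in zip(self._names[chrom], self._pos[chrom]):
                yield str(name), chrom, int(pos)


class GenomeIntervalSet:
    """A named annotation track: sorted, overlap-merged 1-based intervals."""

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]]):
        self.name = name
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start > end:
                raise ParseError(f"{name}: interval {chrom}:{start}-{end} has start > end")
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
        self._iv = {c: _merge_intervals(np.array(v)) for c, v in by_chrom.items()}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._iv, key=_chrom_sort_key)

    def intervals(self, chrom: Optional[str] = None) -> Iterator[tuple[str, int, int]]:
        chroms = [chrom] if chrom is not None else self.chroms
        for c in chroms:
            for s, e in self._iv.get(c, ()):
                yield c, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._iv.values())

    @property
    def total_bp(self) -> int:
        return int(sum(np.sum(v[:, 1] - v[:, 0] + 1) for v in self._iv.values()))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Whether [start, end] shares >= 1 bp with any track interval."""
        iv = self._iv.get(normalize_chrom(chrom))
        if iv is None or len(iv) == 0:
            return False
        # merged intervals: starts and ends are both sorted
        i = int(np.searchsorted(iv[:, 0], end, side="right"))
        return i > 0 and iv[i - 1, 1] >= start

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        iv = self._iv.get(normalize_chrom(chrom))
        if iv is None or len(iv) == 0:
            return 0
        lo = np.minimum(iv[:, 1], end)
        hi = np.maximum(iv[:, 0], start)
        return int(np.sum(np.clip(lo - hi + 1, 0, None)))

    def max_interval_overlap_fraction(self, chrom: str, start: int, end: int) -> float:
        """Max over track intervals of (shared bp / query length)."""
        iv = self._iv.get(normalize_chrom(chrom))
        if iv is None or len(iv) == 0:
            return 0.0
        length = end - start + 1
        shared = np.clip(np.minimum(iv[:, 1], end) - np.maximum(iv[:, 0], start) + 1, 0, None)
        return float(shared.max()) / length


# ---------------------------------------------------------------------------
# rawcnv

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")
_STATE_RE = re.compile(r"^state(?P<state>\d+),cn=(?P<cn>\d+)$")
# PennCNV HMM state for each copy number, for writing
_CN_TO_STATE = {0: 1, 1: 2, 3: 5, 4: 6}


def read_rawcnv(path) -> list[CnvCall]:
    """Parse a PennCNV-style rawcnv text file into CnvCall records.

    Each line:
    ``chrN:start-end numsnp=K length=L stateS,cn=C sample [conf=..] ...``
    Malformed lines are collected and reported together with line numbers.
    """
    calls: list[CnvCall] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split()
            region = _REGION_RE.match(tokens[0])
            if region is None:
                errors.append(f"line {lineno}: bad region field {tokens[0]!r}")
                continue
            cn = None
            sample = None
            kv: dict[str, str] = {}
            for tok in tokens[1:]:
                m = _STATE_RE.match(tok)
                if m:
                    cn = int(m.group("cn"))
                elif "=" in tok:
                    k, _, v = tok.partition("=")
                    kv[k] = v
                elif sample is None:
                    sample = tok
            if cn is None:
                errors.append(f"line {lineno}: missing cn token")
                continue
            if sample is None:
                errors.append(f"line {lineno}: missing sample id")
                continue
            start = int(region.group("start"))
            end = int(region.group("end"))
            if start > end:
                errors.append(f"line {lineno}: start > end")
                continue
            try:
                calls.append(
                    CnvCall(
                        sample_id=sample,
                        chrom=normalize_chrom(region.group("chrom")),
                        start=start,
                        end=end,
                        copy_number=cn,
                        n_snps=int(kv.get("numsnp", 1)),
                        confidence=float(kv["conf"]) if "conf" in kv else None,
                    )
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    return calls


def write_rawcnv(path, calls: Sequence[CnvCall]) -> None:
    with open(path, "w") as fh:
        for c in calls:
            state = _CN_TO_STATE.get(c.copy_number, 6 if c.copy_number > 2 else 1)
            fields = [
                f"{c.chrom}:{c.start}-{c.end}",
                f"numsnp={c.n_snps}",
                f"length={c.length}",
                f"state{state},cn={c.copy_number}",
                c.sample_id,
            ]
            if c.confidence is not None:
                fields.append(f"conf={c.confidence:g}")
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk <-> 1-based inclusive in memory)


def read_bed(path, name: Optional[str] = None) -> GenomeIntervalSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path} line {lineno}: expected >=3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ParseError(f"{path} line {lineno}: BED end <= start")
            intervals.append((chrom, start0 + 1, end0))
    return GenomeIntervalSet(name or Path(path).stem, intervals)


def write_bed(path, intervals: "GenomeIntervalSet | Iterable[tuple[str, int, int]]") -> None:
    rows = intervals.intervals() if isinstance(intervals, GenomeIntervalSet) else intervals
    with open(path, "w") as fh:
        for chrom, start, end in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_snp_map(path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str, "pos": np.int64})
    for col in ("name", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: SNP map missing column {col!r}")
    return SnpMap(df[["name", "chrom", "pos"]].itertuples(index=False, name=None))


def write_snp_map(path, snp_map: SnpMap) -> None:
    pd.DataFrame(list(snp_map), columns=["name", "chrom", "pos"]).to_csv(
        path, sep="\t", index=False
    )


_SAMPLE_COLS = [
    "sample_id",
    "cohort_id",
    "phenotype",
    "call_rate",
    "lrr_sd",
    "gc_wave",
    "father_id",
    "mother_id",
    "replicate_of",
]


def read_sample_table(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "cohort_id", "phenotype", "call_rate", "lrr_sd", "gc_wave"):
        if col not in df.columns:
            raise ParseError(f"{path}: sample table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].unique()
        raise ParseError(f"{path}: duplicate sample ids {list(dups)[:5]}")
    records = []
    for row in df.itertuples(index=False):
        if row.phenotype not in PHENOTYPES:
            raise ParseError(f"{path}: unknown phenotype label {row.phenotype!r}")
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                cohort_id=row.cohort_id,
                phenotype=row.phenotype,
                call_rate=float(row.call_rate),
                lrr_sd=float(row.lrr_sd),
                gc_wave=float(row.gc_wave),
                father_id=getattr(row, "father_id", "") or None,
                mother_id=getattr(row, "mother_id", "") or None,
                replicate_of=getattr(row, "replicate_of", "") or None,
            )
        )
    return records


def write_sample_table(path, samples: Sequence[SampleRecord]) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "cohort_id": s.cohort_id,
            "phenotype": s.phenotype,
            "call_rate": s.call_rate,
            "lrr_sd": s.lrr_sd,
            "gc_wave": s.gc_wave,
            "father_id": s.father_id or "",
            "mother_id": s.mother_id or "",
            "replicate_of": s.replicate_of or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_SAMPLE_COLS).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[normalize_chrom(chrom)] = int(size)
    return sizes


def write_chrom_sizes(path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes, key=_chrom_sort_key):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


_CNVR_COLS = [
    "chrom",
    "start",
    "end",
    "cnv_class",
    "n_markers",
    "carrier_count",
    "frequency",
    "recurrent",
]


def write_cnvr_table(path, cnvrs) -> None:
    """Write CNVRs as TSV plus a .bed companion for genome-browser use."""
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "cnv_class": r.cnv_class,
            "n_markers": len(r.marker_names),
            "carrier_count": r.carrier_count if r.carrier_count is not None else "",
            "frequency": r.frequency if r.frequency is not None else "",
            "recurrent": int(r.recurrent) if r.recurrent is not None else "",
        }
        for r in cnvrs
    ]
    pd.DataFrame(rows, columns=_CNVR_COLS).to_csv(path, sep="\t", index=False)
    write_bed(str(path) + ".bed", [(r.chrom, r.start, r.end) for r in cnvrs])


_ASSOC_COLS = [
    "marker",
    "chrom",
    "pos",
    "cnv_class",
    "category",
    "case_carriers",
    "case_n",
    "control_carriers",
    "control_n",
    "odds_ratio",
    "p",
    "direction",
]


def write_assoc_table(path, results) -> None:
    rows = [
        {
            "marker": r.marker,
            "chrom": r.chrom,
            "pos": r.pos,
            "cnv_class": r.cnv_class,
            "category": r.category,
            "case_carriers": r.table.a,
            "case_n": r.table.a + r.table.b,
            "control_carriers": r.table.c,
            "control_n": r.table.c + r.table.d,
            "odds_ratio": r.odds_ratio if r.odds_ratio is not None else "",
            "p": r.p,
            "direction": r.direction,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_ASSOC_COLS).to_csv(path, sep="\t", index=False)
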