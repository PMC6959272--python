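"""End-to-end pipeline: simulate -> qc -> cnvr -> burden -> assoc -> enrich -> lethality.

Stages read and write plain-text tables in an output directory and never
mutate another stage's outputs; a run manifest records the seed, stage
outputs with SHA-256 checksums and per-stage record counts, so a rerun
with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .association import AssocConfig, collapse_significant_markers, evidence_filter, marker_scan
from .burden import cohort_burden_summary, cohort_burdens
from .cnvr import CnvrConfig, assign_carriers, build_cnvrs, count_marker_states, summarize_cnvrs
from .enrichment import EnrichConfig, classify_unreported, enrichment_ratio, genic_exonic_fractions
from .io_formats import (
    read_bed,
    read_chrom_sizes,
    read_rawcnv,
    read_sample_table,
    read_snp_map,
    write_assoc_table,
    write_cnvr_table,
)
from .lethality import LethalityConfig, hd_carriers_per_region, lethality_scan
from .qc import QcThresholds, run_qc, filter_calls
from .synthetic import SimConfig, generate_cohort, write_cohort

log = logging.getLogger("cnvrscan")

STAGES = ("simulate", "qc", "cnvr", "burden", "assoc", "enrich", "lethality")


@dataclass
class PipelineConfig:
    cohort_dir: str = "cohort"
    tracks_dir: Optional[str] = None  # defaults to <cohort_dir>/tracks
    output_dir: str = "out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    cnvr: CnvrConfig = field(default_factory=CnvrConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    lethality: LethalityConfig = field(default_factory=LethalityConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("cohort_dir", "tracks_dir", "output_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, klass in (
            ("sim", SimConfig),
            ("qc", QcThresholds),
            ("cnvr", CnvrConfig),
            ("assoc", AssocConfig),
            ("enrich", EnrichConfig),
            ("lethality", LethalityConfig),
        ):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        cfg = cls(**kwargs)
        # the global seed feeds stages that do not set their own
        if "sim" not in raw or "seed" not in (raw.get("sim") or {}):
            cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        if "assoc" not in raw or "seed" not in (raw.get("assoc") or {}):
            cfg.assoc = dataclasses.replace(cfg.assoc, seed=cfg.seed + 1)
        if "enrich" not in raw or "seed" not in (raw.get("enrich") or {}):
            cfg.enrich = dataclasses.replace(cfg.enrich, seed=cfg.seed + 2)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class PipelineRun:
    """Stateful runner; stages share loaded inputs through this object."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "stages": {},
        }
        self._calls = None
        self._snp_map = None
        self._samples = None
        self._kept = None
        self._cnvrs = None

    # -- input loading -----------------------------------------------------
    @property
    def cohort_dir(self) -> Path:
        return Path(self.cfg.cohort_dir)

    @property
    def tracks_dir(self) -> Path:
        return Path(self.cfg.tracks_dir) if self.cfg.tracks_dir else self.cohort_dir / "tracks"

    def _load_inputs(self):
        if self._calls is None:
            self._calls = read_rawcnv(self.cohort_dir / "calls.rawcnv")
            self._snp_map = read_snp_map(self.cohort_dir / "snp_map.tsv")
            self._samples = read_sample_table(self.cohort_dir / "samples.tsv")
            self._chrom_sizes = read_chrom_sizes(self.cohort_dir / "chrom.sizes")

    def _load_kept(self):
        self._load_inputs()
        if self._kept is None:
            qc_path = self.outdir / "qc_report.json"
            if qc_path.exists():
                with open(qc_path) as fh:
                    self._kept = json.load(fh)["kept"]
            else:
                self._kept = [s.sample_id for s in self._samples]
        return self._kept

    def _record(self, stage: str, outputs: list[Path], counts: dict):
        self.manifest["stages"][stage] = {
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "counts": counts,
        }

    # -- stages ------------------------------------------------------------
    def simulate(self):
        log.info("simulate: n=%d samples", self.cfg.sim.n_samples)
        cohort = generate_cohort(self.cfg.sim)
        write_cohort(cohort, self.cohort_dir)
        self._record(
            "simulate",
            [self.cohort_dir / "calls.rawcnv", self.cohort_dir / "samples.tsv"],
            {"samples": len(cohort.samples), "calls": len(cohort.calls)},
        )

    def qc(self):
        self._load_inputs()
        report = run_qc(self._samples, self._calls, self.cfg.qc)
        self._kept = report.kept
        out = self.outdir / "qc_report.json"
        with open(out, "w") as fh:
            json.dump(
                {
                    "kept": report.kept,
                    "excluded": report.excluded,
                    "counts_per_reason": report.counts_per_reason,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        self._record("qc", [out], {"kept": len(report.kept), "excluded": len(report.excluded)})

    def cnvr(self):
        self._load_inputs()
        kept = self._load_kept()
        calls = filter_calls(self._calls, kept)
        counts = count_marker_states(calls, self._snp_map, kept)
        cnvrs = build_cnvrs(counts, self.cfg.cnvr)
        cnvrs = assign_carriers(cnvrs, calls, len(kept), kept)
        self._cnvrs = cnvrs
        out = self.outdir / "cnvr.tsv"
        write_cnvr_table(out, cnvrs)
        summary = summarize_cnvrs(cnvrs)
        sum_path = self.outdir / "cnvr_summary.json"
        with open(sum_path, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        self._record("cnvr", [out, sum_path], {"cnvrs": len(cnvrs)})

    def burden(self):
        self._load_inputs()
        kept = self._load_kept()
        calls = filter_calls(self._calls, kept)
        burdens = cohort_burdens(calls, kept)
        out = self.outdir / "burden.tsv"
        with open(out, "w") as fh:
            fh.write("sample_id\tdel_bp\tdup_bp\thd_bp\n")
            for b in burdens:
                fh.write(f"{b.sample_id}\t{b.del_bp}\t{b.dup_bp}\t{b.hd_bp}\n")
        summary = cohort_burden_summary(burdens)
        sum_path = self.outdir / "burden_summary.json"
        with open(sum_path, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        self._record("burden", [out, sum_path], {"samples": len(burdens)})

    def assoc(self):
        self._load_inputs()
        kept = self._load_kept()
        calls = filter_calls(self._calls, kept)
        scan = marker_scan(calls, self._snp_map, self._samples, kept, self.cfg.assoc)
        out = self.outdir / "assoc.tsv"
        write_assoc_table(out, scan.nominal(self.cfg.assoc.nominal_alpha))
        regions = []
        for cls in ("DEL", "DUP", "HD"):
            thr = self.cfg.assoc.hd_alpha if cls == "HD" else self.cfg.assoc.genomewide_alpha
            for cat in sorted({r.category for r in scan.results}):
                sub = [r for r in scan.results if r.cnv_class == cls and r.category == cat]
                if sub:
                    regions.extend(collapse_significant_markers(sub, self._snp_map, thr))
        flagged, retained = evidence_filter(
            regions, replication_results=None, cfg=dataclasses.replace(
                self.cfg.assoc, require_replication=False
            ),
        )
        da_path = self.outdir / "da_cnvr.tsv"
        with open(da_path, "w") as fh:
            fh.write(
                "chrom\tstart\tend\tcnv_class\tcategory\tmin_p\tpeak_marker\tdirection\tretained\n"
            )
            for r in flagged:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.cnv_class}\t{r.category}\t"
                    f"{r.min_p:.3e}\t{r.peak_marker}\t{r.direction}\t{int(r.retained)}\n"
                )
        self._record(
            "assoc", [out, da_path], {"nominal_markers": len(scan.nominal()), "da_cnvrs": len(flagged)}
        )

    def enrich(self):
        self._load_inputs()
        if not self.tracks_dir.is_dir():
            raise FileNotFoundError(f"tracks directory {self.tracks_dir} does not exist")
        if self._cnvrs is None:
            self.cnvr()
        tracks = {p.stem: read_bed(p) for p in sorted(self.tracks_dir.glob("*.bed"))}
        rows = []
        for name, track in tracks.items():
            res = enrichment_ratio(self._cnvrs, track, self._chrom_sizes, self.cfg.enrich)
            rows.append(res)
        out = self.outdir / "enrichment.tsv"
        with open(out, "w") as fh:
            fh.write("track\tobserved\texpected\tsd\ter\tp\n")
            for r in rows:
                fh.write(
                    f"{r.track}\t{r.observed}\t{r.permuted_mean:.3f}\t{r.permuted_sd:.3f}\t"
                    f"{r.er:.4f}\t{r.p:.3e}\n"
                )
        extras = {}
        if "genes" in tracks and "exons" in tracks:
            extras["genic_exonic"] = genic_exonic_fractions(
                self._cnvrs, tracks["genes"], tracks["exons"]
            )
        if "dgv" in tracks:
            unreported = classify_unreported(self._cnvrs, tracks["dgv"])
            extras["unreported_fraction"] = (
                sum(unreported) / len(unreported) if unreported else 0.0
            )
        extra_path = self.outdir / "enrichment_extras.json"
        with open(extra_path, "w") as fh:
            json.dump(extras, fh, indent=1, sort_keys=True)
        self._record("enrich", [out, extra_path], {"tracks": len(tracks)})

    def lethality(self):
        self._load_inputs()
        kept = self._load_kept()
        calls = filter_calls(self._calls, kept)
        if self._cnvrs is None:
            self.cnvr()
        del_cnvrs = [r for r in self._cnvrs if r.cnv_class == "DEL"]
        hd_counts = hd_carriers_per_region(del_cnvrs, calls)
        results = lethality_scan(del_cnvrs, hd_counts, len(kept), self.cfg.lethality)
        out = self.outdir / "lethality.tsv"
        with open(out, "w") as fh:
            fh.write("chrom\tstart\tend\tcarrier_freq\texpected_hd\tobserved_hd\tp_zero\tflagged\n")
            for r in results:
                fh.write(
                    f"{r.cnvr.chrom}\t{r.cnvr.start}\t{r.cnvr.end}\t{r.carrier_freq:.5f}\t"
                    f"{r.expected_hd:.3f}\t{r.observed_hd}\t{r.p_zero:.4e}\t{int(r.flagged)}\n"
                )
        self._record(
            "lethality", [out], {"screened": len(results), "flagged": sum(r.flagged for r in results)}
        )

    # -- orchestration -----------------------------------------------------
    def run(self, stages=STAGES):
        if "enrich" in stages and not (
            "simulate" in stages or self.tracks_dir.is_dir()
        ):
            raise FileNotFoundError(
                f"tracks directory {self.tracks_dir} does not exist (enrich enabled)"
            )
        for stage in STAGES:  # dependency order
            if stage not in stages:
                continue
            log.info("stage %s", stage)
            try:
                getattr(self, stage)()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest_path = self.outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        return self.manifest


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    return PipelineRun(config).run(stages)
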