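# cnvrscan

Analysis toolkit for population-scale copy-number-variant (CNV) call
sets from SNP and CGH arrays: it turns per-sample PennCNV-style calls
into copy-number-variable regions (CNVRs), computes per-genome burden,
tests disease-category association per SNP with permutation-based
family-wise calibration, measures annotation enrichment against random
interval placement, and screens common deletions for Hardy-Weinberg
depletion of homozygotes (embryonic-lethality candidates). A bundled
synthetic-cohort generator reproduces the statistical structure these
analyses assume, so the whole pipeline is testable without any
access-controlled genotype data.

Intended users: statistical geneticists and bioinformaticians working
with array-based CNV calls in large case/control biobanks.

## The statistics at the core

* **CNVR construction.** For each CNV class — deletion (CN ∈ {0,1}),
  duplication (CN ≥ 3) and homozygous deletion (CN = 0) — each SNP
  marker gets a distinct-carrier count. A CNVR is a maximal run of
  consecutive markers whose count exceeds both the non-singleton bound
  (≥ 2 carriers) and a frequency bound (> 0.03% of QC-passing samples),
  spanning < 1 Mb; over-long runs split recursively at their
  minimum-count interior marker.
* **Burden.** Per sample and class, merged covered base pairs; the
  cohort total is mean(del) + mean(dup) with homozygous deletions
  reported separately (they are a subset of deletions).
* **Association.** Per marker, class and disease category, a 2×2
  carrier table against healthy controls is tested with the two-sided
  Fisher exact test; runs of adjacent same-direction significant
  markers collapse into disease-associated CNVRs. Label permutations
  give the genome-wide minimum-p null, hence empirical family-wise
  thresholds and adjusted p-values. Retention requires three lines of
  evidence: same-direction replication at p < 0.05 in a held-out
  cohort, permutation support, and absence of control enrichment.
* **Enrichment.** ER = observed count of CNVRs overlapping a track,
  divided by its mean over random length- and chromosome-preserving
  re-placements (10,000 permutations by default).
* **Lethality screen.** A deletion carrier frequency f implies allele
  frequency q = f/2 under Hardy-Weinberg equilibrium; the probability
  of seeing zero CN=0 carriers among N subjects is (1 − q²)^N. Common
  deletion CNVRs (f ≥ 1.25%) with zero observed homozygotes and
  (1 − q²)^N < 0.05 are flagged.

## Worked example

```python
from cnvrscan.synthetic import SimConfig, PlantedCnvr, LethalLocus, generate_cohort
from cnvrscan.qc import run_qc, filter_calls
from cnvrscan.cnvr import CnvrConfig, count_marker_states, build_cnvrs, \
    assign_carriers, summarize_cnvrs
from cnvrscan.burden import cohort_burdens, cohort_burden_summary
from cnvrscan.lethality import hd_carriers_per_region, lethality_scan, zero_hd_pvalue

cfg = SimConfig(
    n_samples=4000, n_markers=8000, seed=42,
    planted_cnvrs=[PlantedCnvr("chr1", 20_000_000, 20_600_000, "DEL", 0.01)],
    lethal_loci=[LethalLocus("chr2", 10_000_000, 10_500_000, 0.07)],
)
cohort = generate_cohort(cfg)
report = run_qc(cohort.samples, cohort.calls)
calls = filter_calls(cohort.calls, report.kept)

counts = count_marker_states(calls, cohort.snp_map, report.kept)
cnvr_cfg = CnvrConfig(freq_threshold=0.005)   # ~20 carriers at this cohort size
cnvrs = assign_carriers(build_cnvrs(counts, cnvr_cfg), calls,
                        len(report.kept), report.kept)

dels = [r for r in cnvrs if r.cnv_class == "DEL"]
results = lethality_scan(dels, hd_carriers_per_region(dels, calls), len(report.kept))
```

Output (printed by the summary calls shown in `docs/methods.md`):

```
QC: kept 3940/4000 samples; reasons {'CALL_RATE': 20, 'LRR_SD': 20,
    'GC_WAVE': 12, 'CALL_COUNT': 8, 'DUPLICATE': 0, 'SYNDROMIC': 0}
CNVRs: DEL 4 (100.0% recurrent), DUP 32, HD 0
burden: del 334 kb, dup 373 kb, total 707 kb, hd 10.3 kb
lethality: screened 2 common deletion CNVRs, flagged 1
  chr2:10001838-10487381 f=0.0906 expected_hd=8.1 observed=0 p_zero=0.0003
reference-scale: zero_hd_pvalue(0.0125, 100028) = 0.0201
```

Reading it: 60 of 4,000 samples fail array QC; the planted 1%-frequency
deletion and the 9% lethal deletion surface as deletion CNVRs; the mean
per-genome burden decomposes into deleted plus duplicated base pairs;
and the lethal locus — common, yet with zero homozygous carriers where
8.1 were expected under Hardy-Weinberg — is flagged at p ≈ 3 × 10⁻⁴.
The last line evaluates the same zero-homozygote probability at a
100,028-subject cohort's screening floor (1.25% carriers): p ≈ 0.02,
i.e. a zero count is already significant at that scale.

The same pipeline runs from the shell:

```sh
cnvrscan all --out out/ --seed 42          # simulate → qc → … → lethality
cnvrscan qc --config run.yaml              # or stage by stage, YAML-configured
```

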