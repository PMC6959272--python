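# Methods

This note documents the models, conventions and numerical choices
behind cnvrscan, and what the synthetic cohorts do and do not emulate.

## Coordinates and call classes

All internal coordinates are 1-based and end-inclusive, the convention
of the rawcnv dialect that is the package's primary input; BED tracks
are converted at the I/O boundary and nowhere else. A call's class is
derived from its integer copy number: DEL for CN ∈ {0, 1}, DUP for
CN ≥ 3, and HD (homozygous deletion) for CN = 0. HD is deliberately a
subset of DEL — a homozygous deletion is still a deletion — which gives
the invariants hd_count ≤ del_count per marker and hd_bp ≤ del_bp per
sample. CN = 2 segments are rejected at parse time: a diploid segment
is not a CNV call. Chromosome names are normalised to `chrN`; the
package works on whatever chromosomes appear in the marker map and
makes no assumption about their number (analyses of sex chromosomes
would need dosage handling this package does not attempt).

## Sample QC

Thresholds follow the quoted screening rules literally, with strict
inequalities on the kept side: call rate > 0.98, LRR SD < 0.25,
|GC-wave factor| < 0.02, CNV call count < 100 (a sample with exactly
100 calls is excluded). A sample failing several criteria carries every
applicable reason code, and the report is independent of evaluation
order.

Duplicate detection works on call profiles because genotypes are not
part of the package's inputs: the Jaccard index of per-class covered
base pairs, threshold 0.8, computed by a plane sweep that accumulates
the exact pairwise intersection so the cost scales with interval
overlaps rather than with sample pairs squared. Of a flagged pair, the
member with the lower call rate is dropped; declared replicates are
always flagged and the replicate dropped. Syndromic exclusion flags any
sample whose class-matching call reciprocally overlaps a configured
syndromic region by ≥ 50%.

The reciprocal-overlap threshold for trio inheritance, replicate
concordance and syndromic matching is 50% — the field's conventional
value; it is exposed as an argument because the choice is not forced by
anything in the data.

The genomic inflation factor is λ = median(χ²₁(p)) / 0.4549364. Two
caveats at desk scale: Fisher's exact test is discrete, and markers
with very few carriers produce p = 1 en masse, so a null scan's λ is
*deflated* well below 1 rather than near it. The diagnostic's operative
direction — detecting inflation from case/control mismatch — is
unaffected, and the tests assert λ ≤ 1.1 on null scans rather than a
two-sided band that only a 100k-sample cohort with ubiquitous carriers
could attain.

## CNVR construction

Qualifying markers need a distinct-carrier count strictly above
max(min_carriers − 1, freq_threshold · N) with min_carriers = 2
("non-singleton") and freq_threshold = 0.03%. Both bounds are kept
because at small N the frequency bound alone would admit singletons.
Maximal runs of consecutive qualifying markers form candidate regions;
a run spanning ≥ 1 Mb is split at its minimum-count interior marker
(leftmost on ties), the marker removed, recursively until every piece
fits. A degenerate over-long run of ≤ 2 markers has no interior marker
to remove and is emitted as single-marker regions. Region boundaries
are the first and last qualifying marker positions, not call
boundaries: the definition is marker-based. Carriers are distinct
samples with a class-matching call overlapping the region by ≥ 1 bp;
recurrent means ≥ 2 carriers.

At cohort sizes far below 100k the 0.03% bound is weaker than the
two-carrier floor and regions absorb flanking background markers; the
worked example therefore raises `freq_threshold` to 0.5% for a
4,000-sample cohort. The carrier-frequency denominator pools all
QC-passing samples; a per-platform denominator would be a one-line
variant but pooling matches how the region definitions are stated.

## Burden

Per class, a sample's intervals are merged (overlapping or bookended)
before summing lengths, making burden invariant to call order and to
splitting a call in two. The cohort total is mean(del_bp) +
mean(dup_bp); HD is reported separately and non-additively since it is
counted inside DEL.

## Association

The unit of testing is carrier status at a marker, against
CONTROL-phenotype samples only (never other disease categories). The
two-sided Fisher p sums hypergeometric probabilities no larger than the
observed table's, with a 10⁻⁷ relative tie tolerance (scipy's
implementation; verified in tests against an independent enumeration
oracle for every table up to total N = 30). The odds ratio is the
sample ratio ad/bc, reported absent when bc = 0. Ties in carrier
fraction are labelled control-enriched; they carry p = 1 and can never
be retained, so the label choice is inert.

Collapsing merges runs of map-adjacent markers that pass a threshold
with the same direction; the reported region records the minimum p and
its peak marker. Thresholds are configuration presets (5 × 10⁻⁸ for
DEL/DUP, 5 × 10⁻⁴ for HD, 9 × 10⁻¹⁴ as a headline preset), not derived
quantities.

Family-wise calibration permutes phenotype labels within the pooled
case + control set, keeping each sample's full call profile intact so
the spatial correlation of CNVs survives under the null. Each
permutation contributes its genome-wide minimum p; the adjusted p of a
locus is (1 + #{min-p ≤ observed}) / (n_perm + 1). The min-p
distribution is itself discrete (small carrier counts, exact test), so
the empirical α-threshold brackets α rather than attaining it; the
tests assert the bracket. The carrier incidence is held as a sparse
marker × sample matrix and Fisher p-values are memoised on the 2×2
table, which makes hundreds of permutations over 10⁴ markers cheap.

The evidence filter: replicated = same-direction p < 0.05 at the peak
marker in a held-out cohort scan (not evaluable on single-cohort input,
in which case retention depends on `require_replication`);
permutation_pass = adjusted p below α when a permutation null is
supplied; not_control_enriched = the peak is case-enriched. Retained
requires all evaluable flags true.

## Enrichment

The null re-places each region uniformly on its own chromosome with its
length preserved, rejection-sampling against an excluded set (≤ 1000
attempts, then an error naming the region). Marker density is *not*
preserved — this is the standard interval-permutation null; a
density-matched null is a known alternative of unquantified difference.
The package permutes the regions, not the annotations. The empirical p
is one-tailed on the side of the observed ratio: (1 + #{count ≥
observed})/(n + 1) for ER ≥ 1, mirrored below — so over both possible
sides the null rejection rate is bounded by twice the nominal level;
discreteness keeps it near nominal in practice. Degenerate cases: null
mean 0 with observed 0 reports ER 1, p 1; null mean 0 with observed > 0
reports ER = ∞ at the resolution floor p = 1/(n+1). "Unreported"
regions overlap < 50% of their own length with any single catalog
(DGV-style) interval; the fraction is of the region's length, not
reciprocal, because that is the natural reading of the rule — note the
boundary: exactly 50% counts as reported.

## Lethality screen

The null links carrier and allele frequency by HWE with the
rare-variant approximation f ≈ 2q (so q = f/2), giving
P(zero homozygotes) = (1 − q²)^N, computed as exp(N·log1p(−q²)) to
avoid cancellation. The screen floor f ≥ 1.25% is consistent with this
model: the smallest screenable frequency at α = 0.05 and N = 100,028 is
f* = 2·√(−ln 0.05/N) ≈ 1.09%, so the floor is strictly conservative;
at the floor itself p ≈ 0.020. Only zero counts are tested — an
observed homozygote is never flagged — and no population-structure
correction is applied.

## Synthetic cohorts

The generator emulates the study design the analyses assume:

* **Category mix** (defaults): AID 11.49%, CANCER 9.10%, CARDIO 2.58%,
  NEURO 43.83%, CONTROL 33.00% — the four disease categories and
  healthy controls in their study proportions; two platform cohorts
  split 52.3/47.7.
* **Background calls**: per-sample Poisson counts with log-normal
  lengths (median 30 kb, log-SD 1.1, truncated to [1 kb, 2 Mb] — a
  heavy-tailed law consistent with per-genome burden histograms without
  claiming the true length distribution). The Poisson means are set
  from the *analytic* truncated-log-normal mean so that expected
  per-genome burden hits the targets: 285 kb deleted, 370 kb
  duplicated, 9.5 kb homozygous-deleted (the HD target is realised by
  making that fraction of deletion calls CN = 0). The per-genome call
  *count* distribution is calibrated only through these means; no
  claim is made about its true shape.
* **Planted structure**: recurrent CNVRs with Bernoulli carriers at a
  configured frequency; association loci where the target category's
  carriage probability is p₁ = OR·p₀/(1 − p₀ + OR·p₀), the exact
  odds-model inversion, so the true carriage odds ratio equals OR;
  lethal deletion loci that emit heterozygous carriers only (any
  background CN = 0 call overlapping one is demoted to CN = 1, so no
  homozygote ever appears there); and HWE-consistent deletion loci
  (CN 0 with probability q², CN 1 with 2q(1−q)) for null calibration of
  the lethality screen.
* **Families and replicates**: trios in which each child call copies a
  random parental call with probability 1 − de_novo_rate (default 0.06,
  matching a 94% inheritance rate) or is placed independently;
  replicate pairs whose second member copies the first with per-call
  discordance 0.02 (98% concordance).
* **QC failures**: small configurable fractions of samples get metric
  values beyond each threshold (defaults 0.5%/0.5%/0.3%/0.2% for call
  rate/LRR SD/GC wave/call count — not dictated by anything; chosen
  once as plausibly rare).
* **Determinism**: one global seed feeds named substreams (markers,
  samples, background, planted, trios, replicates, tracks), so enabling
  one component never perturbs another's draws and equal configs give
  byte-identical cohorts.

Library defaults are 5,000 samples and 10,000 markers on a three-
chromosome 135 Mb genome — a marker density comparable to a 520k panel
on a full genome — with cohort size fully configurable. Tests and the
acceptance suite use 300–20,000 samples depending on what the check
needs.

What the generator does **not** emulate: linkage disequilibrium between
markers, platform-specific sensitivity differences, raw LRR/BAF
intensities, population structure, or realistic annotation content
(tracks are random intervals with plausible coverage). Passing tests
therefore demonstrate the correctness and calibration of the
*algorithms* under the stated statistical model, not performance on
real array data.

## Problem sizes in the test suite

The suite's heavier checks run at deliberately chosen scales: oracle
equivalence on 200 random cohorts of ≤ 50 samples × ≤ 200 markers and
exhaustive Fisher verification to N = 30; planted-association recovery
over 20 cohorts of 10k cases + 10k controls × 800 markers; type-I
calibration on a 2,000-sample × 10⁴-marker null cohort; enrichment
nulls at 1,000–2,000 permutations (the production default is 10,000);
lethality type-I on 60 HWE loci at N·q² ≈ 3, the regime where the flag
has nontrivial firing probability.

## Known limitations

* Duplicate detection sees only CNV call profiles; twins with few CNVs
  are invisible to it (genotype relatedness would be needed).
* The enrichment null ignores marker density and assembly gaps unless
  an excluded-region set is supplied.
* Carrier frequencies pool platforms; batch-specific artefacts would
  need the per-cohort scan plus the replication filter to be caught.
* The lethality model treats carriers as independent and panmictic;
  inbreeding or structure would inflate the expected homozygote count
  and make the screen anti-conservative.
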