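# Methods

## Problem and model

A de novo structural variant (dnSV) is a deletion, duplication or inversion
present heterozygously in a proband's germline and absent from both parents'
somatic genomes. Given a jointly genotyped population SV callset over
sire–dam–proband trios, the package (i) screens for Mendelian-inconsistent
candidates, (ii) filters them on genotyper evidence, (iii) reviews
breakpoint-local read and depth signal with explicit rules, (iv)
characterises the survivors (phase, mechanism, clustering, genic context,
mosaicism, transmission) and (v) estimates the per-generation dnSV rate.

Breakend-class records (breakpoints not assignable to a canonical SV type)
are excluded from all analysis; they are retained on loading and flagged.

## Coordinate and size conventions

Coordinates are 1-based; an SV's `start` is the VCF POS (base before the
event), `end` the INFO END, and its size `end − start`, the convention under
which published dnSV tables' printed sizes are exactly reproduced. Whether
POS anchors the base before the event or the first affected base is not
decidable from a callset alone; the size is invariant to that choice, and
absolute anchoring follows the input VCF. BED input is converted from
0-based half-open on read.

## Filter cascade

Every inequality is implemented strictly as stated in `Thresholds`
(defaults: GQ sum > 120; AF ≤ 0.1 with equality retained; DEL DHFFC < 0.8
and parent mean > 0.8, AB > 0.05, SU ≥ 3; DUP DHBFC > 1.1 and parent
mean < 1.2, AB > 0.1, SU ≥ 3; INV AB > 0.2, SU ≥ 5; each parent
individually AB < 0.1 and SU ≤ 3). Choices made where the procedure leaves
room:

* **Missing data.** A missing parent genotype or any missing evidence field
  required by a filter fails that filter (conservative). A missing genotype
  in an *unrelated* sample counts as non-carrier: missingness is common in
  joint callsets and the allele-frequency cap backstops.
* **Unrelated samples.** "No other cohort sample carries the allele" exempts
  the proband's own sequenced third-generation offspring, who inherit a
  genuine dnSV half the time; the AF cap of 0.1 was chosen (by the original
  procedure) precisely to tolerate such transmissions.
* **Per-parent checks.** "A maximum of three supporting reads in either
  parent" is applied to each parent individually, likewise the parent AB
  cap.
* **AF denominator** counts non-missing genotypes only.
* **Order.** All per-candidate filters are pure predicates, so the survivor
  set is order-independent (property-tested); the implemented order
  (Mendelian → GQ → AF → type → uniqueness) is for trace readability. The
  GQ filter runs after the Mendelian screen; the ordering is immaterial to
  the result.
* **Uniqueness.** After a Mendelian screen that requires *all* unrelated
  samples to be non-carriers, a site can never be a candidate in two
  probands (each proband is unrelated from the other trio's viewpoint), so
  the uniqueness filter cannot fire on fully genotyped data. It is kept as
  an independently tested backstop for callsets where the unrelated-sample
  requirement is relaxed or genotypes are missing.

`DHFFC` uses the median depth of the concatenated 1 kb flanks; a zero flank
median yields +∞ (treated as a failing fold-change for deletions). `DHBFC`
stratifies genome bins by GC in 0.05-wide bins of GC fraction; an empty
stratum falls back to the genome-wide median and is flagged.

## Review rules

The five rejection criteria of manual inspection are encoded as predicates;
a candidate is spurious iff at least one fires. Numeric choices the
original, visual procedure leaves open:

* repeat overlap means ≥1 bp intersection between a ±50 bp breakpoint
  window and a repeat interval (window configurable);
* "not at all overlapping" reads = no position covered by ≥2 supporting
  reads at that breakpoint;
* the coverage step is the median depth on the SV-interior side of each
  breakpoint over the exterior side, 500 bp windows, with the interior
  window capped at the SV length so short SVs are not diluted; "clear"
  change reuses the cascade's fold-change cutoffs (≤ 0.8 for deletions,
  ≥ 1.1 for duplications) as a proxy — these are labelled proxy parameters
  and configurable;
* the expected coverage change must be present at **both** breakpoints
  (the stricter reading of the criterion); inversions are copy-neutral and
  skip rule 5.

## Characterisation

**Parent of origin.** For deletions, an informative SNP shows the proband
apparently homozygous (minor read fraction ≤ 0.05) while exactly one parent
is homozygous for the other allele; the deletion lies on that parent's
haplotype. This generalises the absent-allele logic to both homozygous
states of the proband. For duplications (and inverted duplications), an
informative SNP is het in the proband with minor fraction in [0.28, 0.40]
(expected 1/3 under a 2:1 ratio; tolerance configurable), one parent
homozygous and the other het; the over-represented allele's forced parental
source names the duplicated haplotype. All informative SNPs must agree;
disagreement or absence yields `unknown`. Plain inversions carry no
copy-number signal and are reported `unknown`.

**Junction homology.** The homology at a junction is the longer of the
common suffix of the sequences ending at the two breakpoints and the common
prefix of the sequences following them (micro-homology may be assigned to
either side), with the reverse complement of the far flank also tried for
inversions; flanks of 20 bp are used and a supplied junction consensus
shorter than twice the flank is `unresolved`. Classes: 0–1 bp `NON-HOM`,
2–15 bp `MICRO-HOM`, >15 bp `unresolved` (macro-homology is not reliably
measurable with short reads).

**Clustering.** Single-linkage on each chromosome with a 50 kb window
(configurable). The window has no published definition; both observed
cluster extents in the motivating data (197 bp and ~25 kb) fall well inside
it, and the clustered-SNV literature uses <20 kb. Clusters report both the
genomic span and the component-size sum, because published "cluster sizes"
use the span for non-overlapping members and the component sum when members
overlap. A cluster counts as one mutation event for the rate.

**Mosaicism.** With `r` the pooled minor/major read ratio over het SNPs
inside a deletion and `m = 1 − r` the carrier cell fraction, the deleted-DNA
fraction is `d = m/2`. Zygosity is `germline` for `d ∈ [0.4, 0.5]`
(δ = 0.1, configurable) and `mosaic` otherwise; mosaic calls are excluded
from the rate. Whether mosaicism is somatic or germline cannot be resolved
from these data and is not labelled.

**Rate.** `k/n` with the Wilson score interval at z = 1.959964 for 95%
(Φ⁻¹, not 1.96 — immaterial at these n but documented). Endpoints at k = 0
and k = n are set to exactly 0 and 1. The standard Wilson interval for
k = 4, n = 37 is (0.0428, 0.2472); a published interval of (0.038–0.255)
for the same counts does not match this or common alternatives exactly, so
the package reports standard Wilson (cross-checked against statsmodels)
rather than reverse-engineering a variant.

**Transmission.** P(≥1 of n sequenced offspring inherits) = 1 − (1/2)ⁿ
under independent Mendelian transmission; a dnSV is `validated` when at
least one sequenced offspring is het at the site.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline targets: 2
commercial lines × 20 trios (40 trios, 124 samples including 4 sequenced
third-generation offspring of 2 line-1 probands), mean depth 30× with ±2×
per-sample jitter, 10 strong de novo SVs (DEL/DUP/INV cycling, planted
junction homologies 0–15 bp), 200 inherited polymorphisms (per-site allele
frequency uniform on [0.05, 0.5], Hardy–Weinberg founders, Mendelian
transmission), 1 mosaic deletion at cell fraction m = 0.5, and 50 false
positives cycling through seven failure modes, each engineered to pass
every stage before the one meant to catch it. The reference is random
i.i.d. sequence over three 1 Mb chromosomes — enough to place all variants
with 3 kb separation while keeping a full run in seconds; repeat intervals
are planted around repeat-mode breakpoints plus decoys elsewhere.

Evidence model for a het carrier with cell fraction m: allelic balance
centred at 0.5·m (binomial over Poisson site depth); supporting reads
Poisson with mean depth/2·m, split evenly into split-read and paired-end
components; GQ normal (70, 10) clipped to [1, 99]; per-bin depth Poisson
(100 bp bins) with the carrier's SV interval scaled by 1 − m/4 (deletions)
or 1 + m/4 (duplications), so DHFFC/DHBFC — computed from the simulated
profiles by the same functions the pipeline uses — centre at 0.75 / 1.25
for germline hets. These centres are deliberately conservative relative to
ideal copy arithmetic (0.5 / 1.5): short-read depth estimators shrink
fold-changes toward 1, and the chosen centres still clear the cascade
cutoffs with margin. A calibration test verifies the 0.75 centre to ±0.02
over 1000 planted deletions. One consequence is intentional and documented:
a mosaic deletion at m = 0.5 centres at DHFFC 0.875, above the 0.8 cutoff,
so the default pipeline rejects it at the depth filter — mirroring how
conservative evidence thresholds push low-fraction mosaics below the
detection floor; the 2:1-ratio mosaic inference itself is exercised by its
worked examples and on confirmed deletions (hemizygous SNP signal →
d = 0.5, germline).

What the generator does **not** emulate: real genome sequence composition
and repeat structure, alignment and genotyping error processes, batch or
GC-coverage bias (a GC track exists but no bias curve is applied by
default), relatedness beyond the declared pedigree, and depth-correlated
call-count artefacts. Passing the planted-recovery tests therefore shows
the pipeline implements its rules correctly and recovers signals at least
as clean as its thresholds assume — not that those thresholds are optimal
on real data.

## Problem sizes and determinism

Defaults were chosen so a full simulate-plus-pipeline run completes in a
few seconds (3 Mb genome, 263 SV sites × 124 samples, 100 bp depth bins)
and the entire test suite in well under a minute; all sizes scale through
`SimConfig`. Every stochastic step draws from a single seeded
`numpy.random.Generator`; identical configs give byte-identical serialized
cohorts, and the pipeline itself is deterministic given its inputs.

## Known limitations

* The review rules are numeric proxies for a visual procedure; their
  default cutoffs borrow the cascade's thresholds and should be tuned
  against curated calls before use on real data.
* Parent-of-origin phasing requires informative SNPs inside the SV; small
  SVs usually yield `unknown`, and plain inversions always do.
* The uniqueness filter is unreachable under strict unrelated-sample
  screening (see above); pipelines on sparser genotypes may see it fire.
* Insertions, translocations and the whole breakend class are out of
  scope, as are read-level (BAM) re-analysis and genotype-likelihood
  recomputation.
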