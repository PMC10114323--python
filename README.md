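# dnsv — trio-based de novo structural variant discovery

`dnsv` is a pipeline for finding and characterising **de novo structural
variants (dnSVs)** — deletions, duplications and inversions that appear in an
offspring's germline but are absent from both parents — from population SV
callsets of deeply sequenced sire–dam–proband trios, as produced by
short-read SV genotyping (Lumpy/SVTyper-style VCFs with per-sample genotype,
allelic-balance, supporting-read and depth fold-change fields).

It is aimed at groups studying germline mutation in pedigreed populations
(livestock breeding programmes are the motivating design: large families,
short generation intervals, routinely sequenced three-generation pedigrees),
where the rarity of dnSVs (~0.1 per generation) means the analysis is
dominated by separating a handful of true events from thousands of
Mendelian-inconsistent artefacts.

## What it computes

**Candidate screen and filter cascade.** A site is a candidate in a trio
when the proband is heterozygous and both parents and every unrelated cohort
sample lack the allele. Candidates must then pass, with all inequalities
strict:

* trio genotype-quality sum `GQ_sire + GQ_dam + GQ_proband > 120`;
* cohort allele frequency ≤ 0.1 (the cap is permissive on purpose, so a
  dnSV transmitted to sequenced third-generation offspring is not lost);
* per-type evidence —
  * deletions: proband `DHFFC < 0.8`, parents' mean `DHFFC > 0.8`,
    proband `AB > 0.05`, proband `SU ≥ 3`;
  * duplications: proband `DHBFC > 1.1`, parents' mean `DHBFC < 1.2`,
    proband `AB > 0.1`, proband `SU ≥ 3`;
  * inversions: proband `AB > 0.2`, proband `SU ≥ 5`;
  * all types: each parent `AB < 0.1` and `SU ≤ 3`;
* uniqueness: an identical site that is a candidate in more than one proband
  is discarded (a dnSV is a one-time event).

`DHFFC` is the median depth inside the SV over the median depth of its 1 kb
flanks; `DHBFC` the same numerator over the median depth of genome bins with
matching GC content (0.05-wide strata).

**Rule-based review.** The manual browser-inspection step is encoded as five
pure predicates over breakpoint-local evidence: (1) both breakpoints in
repeats, (2) support on one side only, (3) fewer than three supporting reads
at either breakpoint, (4) mutually non-overlapping supporting reads,
(5) no coverage drop (deletions) / rise (duplications) at the breakpoints.
Any firing rule makes the candidate spurious.

**Characterisation.** Confirmed dnSVs are phased to a parental haplotype
from informative SNPs inside the SV (apparent-homozygosity rule for
deletions, 2:1 read-ratio rule for duplications), classified by junction
homology (`NON-HOM` for 0–1 bp, `MICRO-HOM` for 2–15 bp), clustered by
single-linkage within 50 kb, annotated against gene models, checked for
transmission in sequenced offspring, and screened for mosaicism: with `r`
the pooled minor/major read ratio at het SNPs inside a deletion, the deleted
DNA fraction is `d = (1 − r)/2` (germline het → 0.5; a 2:1 ratio → 0.25,
i.e. one haplotype lost in half the cells).

**Rate.** With `k` de novo mutation events (a cluster counts once) in `n`
trios, the per-generation rate is `k/n` with a Wilson score interval

    centre = (k + z²/2)/(n + z²),  half-width = z·√(k(n−k)/n + z²/4)/(n + z²).

**Synthetic cohorts.** Because real trio data of this kind are rarely
shareable, `dnsv.simulate` generates a pedigree-structured cohort (two
lines × 20 trios at ~30× by default) with planted inherited, de novo,
mosaic and false-positive variants, a random reference with exact
junction-homology lengths, phased informative SNPs and per-sample depth
profiles — every planted truth is recorded, so the whole pipeline is
testable end to end.

## Worked example

```bash
$ dnsv all --seed 7 --out demo_run
candidates screened: 54
confirmed dnSVs: 10 (planted de novo recovered: 10/10)
dnSV rate: 0.250 per generation (95% CI 0.142-0.402, Wilson)
outputs in demo_run
```

54 (site, trio) pairs survive the Mendelian screen; the cascade and review
reject 44 of them (every planted false positive among these is caught by the
rule its failure mode targets) and confirm all 10 planted de novo SVs, none
of the 200 inherited polymorphisms, giving 10 events in 40 trios, i.e. a
rate of 0.250 with Wilson 95% CI (0.142, 0.402). `demo_run/confirmed.tsv`
holds one row per confirmed dnSV:

```
sv_id  svtype chrom start  end    size parent_of_origin locus   genic_context intron     mechanism homology_len ...
dn010  DEL    chr1 196398 196915  517 maternal         gene008 intronic      intron 1/3 MICRO_HOM 15
dn006  INV    chr1 471538 472557 1019 unknown          gene005 intronic      intron 1/3 MICRO_HOM 4
```

Each row reports the phased parent of origin (inversions are copy-neutral
and stay `unknown`), the genic context with the intron ordinal, and the
junction-homology mechanism class. `rejections.log` records every discarded
candidate with the filter trace that removed it, and `rate.json` the Wilson
rate summary.

For library use, `dnsv.simulate.simulate_cohort`,
`dnsv.filters.run_cascade`, `dnsv.review.review_candidate` and
`dnsv.characterise.*` expose the same stages programmatically; every filter
threshold is a `Thresholds` field or CLI flag.

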