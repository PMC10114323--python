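"""Characterisation of confirmed dnSVs and rate estimation.

Covers parent-of-origin assignment from informative SNPs, breakpoint
micro-homology measurement and mechanism classification, single-linkage
mutation clustering, genic-context annotation, mosaic-fraction inference
from allelic read ratios, transmission checks in sequenced third-generation
offspring, and the per-generation dnSV rate with a Wilson score interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from dnsv.svio import Genotype, Pedigree, SmallVariant, SVRecord, SVType, Trio

PATERNAL = "paternal"
MATERNAL = "maternal"
UNKNOWN = "unknown"

NON_HOM = "NON_HOM"
MICRO_HOM = "MICRO_HOM"
UNRESOLVED = "unresolved"

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class DnSVCharacterisation:
    sv_id: str
    parent_of_origin: str = UNKNOWN
    mechanism: str = UNRESOLVED
    homology_len: int | None = None
    cluster_id: str | None = None
    genic_context: str = "intergenic"
    gene_ids: list[str] = field(default_factory=list)
    intron: str | None = None
    zygosity: str = "germline"
    deleted_fraction: float | None = None
    transmission: str = "no_offspring"


@dataclass
class MutationCluster:
    """De novo mutations co-occurring within a clustering window.

    ``span`` is the genomic extent (max end minus min start); ``size_sum``
    the sum of member sizes.  The two differ for overlapping members, and
    published cluster "sizes" use either depending on the cluster's
    structure, so both are reported.
    """

    cluster_id: str
    chrom: str
    members: list[SVRecord] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return (max(m.end or m.start for m in self.members)
                - min(m.start for m in self.members))

    @property
    def size_sum(self) -> int:
        return sum(m.length or 0 for m in self.members)


@dataclass
class RateEstimate:
    count: int
    trios: int
    rate: float
    ci_low: float
    ci_high: float
    method: str = "wilson"
    z: float = float("nan")


# ---------------------------------------------------------------------------
# Parent of origin
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasingConfig:
    hom_max_minor: float = 0.05    # apparent-homozygosity cap on minor fraction
    dup_minor_lo: float = 0.28     # accepted minor-allele fraction window for
    dup_minor_hi: float = 0.40     # the duplication 2:1 read ratio (exp. 1/3)


def _minor_fraction(ref_reads: int, alt_reads: int) -> float | None:
    total = ref_reads + alt_reads
    if total == 0:
        return None
    return min(ref_reads, alt_reads) / total


def assign_parent_of_origin(dnsv: SVRecord, snvs: Sequence[SmallVariant],
                            trio: Trio,
                            config: PhasingConfig = PhasingConfig()) -> str:
    """Phase a dnSV to the paternal or maternal haplotype from SNPs inside it.

    Deletions: an informative SNP shows the proband apparently homozygous for
    one allele while exactly one parent is homozygous for the other.  That
    parent's obligately transmitted allele is absent from the proband's
    reads, so the deletion removed the haplotype inherited from that parent.

    Duplications: an informative SNP is heterozygous in the proband with a
    2:1 read ratio, one parent homozygous and the other heterozygous.  The
    over-represented allele is traced to the parent that must have donated
    it (the homozygous parent when it matches their allele, otherwise the
    heterozygous parent); the duplication lies on that parent's haplotype.

    All informative SNPs must agree; disagreement or absence of informative
    SNPs yields ``unknown``.  Inverted duplications phase like duplications.
    """
    inside = [v for v in snvs
              if v.chrom == dnsv.chrom and dnsv.start < v.pos <= (dnsv.end or 0)]
    votes: set[str] = set()
    for snv in inside:
        vote = (_del_vote(snv, trio, config) if dnsv.svtype is SVType.DEL
                else _dup_vote(snv, trio, config)
                if dnsv.svtype in (SVType.DUP, SVType.INV) else None)
        if vote is not None:
            votes.add(vote)
    if len(votes) == 1:
        return votes.pop()
    return UNKNOWN


def _apparent_allele(snv: SmallVariant, sample: str,
                     config: PhasingConfig) -> str | None:
    """Allele a sample's reads look homozygous for, judged from counts when
    available, else from the called genotype."""
    counts = snv.allele_depths.get(sample)
    if counts is not None and sum(counts) > 0:
        minor = _minor_fraction(*counts)
        if minor is not None and minor <= config.hom_max_minor:
            return "ref" if counts[0] >= counts[1] else "alt"
        return None
    gt = snv.genotypes.get(sample, Genotype.missing)
    if gt is Genotype.hom_ref:
        return "ref"
    if gt is Genotype.hom_alt:
        return "alt"
    return None


def _del_vote(snv: SmallVariant, trio: Trio, config: PhasingConfig) -> str | None:
    proband_allele = _apparent_allele(snv, trio.proband, config)
    if proband_allele is None:
        return None
    other = "alt" if proband_allele == "ref" else "ref"
    hom_other = []
    for label, parent in ((PATERNAL, trio.sire), (MATERNAL, trio.dam)):
        gt = snv.genotypes.get(parent, Genotype.missing)
        if (gt is Genotype.hom_ref and other == "ref") or \
           (gt is Genotype.hom_alt and other == "alt"):
            hom_other.append(label)
    if len(hom_other) == 1:
        return hom_other[0]
    return None


def _dup_vote(snv: SmallVariant, trio: Trio, config: PhasingConfig) -> str | None:
    if snv.genotypes.get(trio.proband) is not Genotype.het:
        return None
    counts = snv.allele_depths.get(trio.proband)
    if counts is None or sum(counts) == 0:
        return None
    minor = _minor_fraction(*counts)
    if minor is None or not (config.dup_minor_lo <= minor <= config.dup_minor_hi):
        return None
    over = "ref" if counts[0] > counts[1] else "alt"
    gt_s = snv.genotypes.get(trio.sire, Genotype.missing)
    gt_d = snv.genotypes.get(trio.dam, Genotype.missing)
    pair = {gt_s, gt_d}
    hom_gts = {Genotype.hom_ref, Genotype.hom_alt}
    if Genotype.het not in pair or not (pair & hom_gts):
        return None
    if gt_s in hom_gts and gt_d is Genotype.het:
        hom_label, het_label, hom_gt = PATERNAL, MATERNAL, gt_s
    elif gt_d in hom_gts and gt_s is Genotype.het:
        hom_label, het_label, hom_gt = MATERNAL, PATERNAL, gt_d
    else:
        return None
    hom_allele = "ref" if hom_gt is Genotype.hom_ref else "alt"
    return hom_label if over == hom_allele else het_label


# ---------------------------------------------------------------------------
# Junction homology and mechanism
# ---------------------------------------------------------------------------

def _common_suffix(a: str, b: str) -> int:
    n = 0
    for ca, cb in zip(reversed(a), reversed(b)):
        if ca != cb:
            break
        n += 1
    return n


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        n += 1
    return n


def junction_homology(reference: Mapping[str, str] | str, sv: SVRecord,
                      junction: str | None = None, flank: int = 20,
                      ) -> int | None:
    """Length of the exact sequence homology shared by the two breakpoint
    flanks of an SV junction.

    The donor-side flank ending at the first breakpoint is compared with the
    acceptor-side flank ending at the second: the homology is the longer of
    the common suffix of the sequences ending at the breakpoints and the
    common prefix of the sequences following them (micro-homology can be
    assigned to either side of a junction).  For inversions the reverse
    complement of the second flank is also tried.  Returns ``None``
    (unresolved) when a supplied junction/consensus sequence is shorter than
    ``2 * flank`` or the SV does not leave ``flank`` bp of sequence on each
    side.
    """
    seq = reference[sv.chrom] if not isinstance(reference, str) else reference
    if junction is not None and len(junction) < 2 * flank:
        return None
    bp1, bp2 = sv.start, sv.end or sv.start
    if bp1 - flank < 0 or bp2 + flank > len(seq):
        return None
    # 1-based: flank ending at bp = seq[bp-flank:bp]
    left_end = seq[bp1 - flank:bp1]
    right_end = seq[bp2 - flank:bp2]
    after1 = seq[bp1:bp1 + flank]
    after2 = seq[bp2:bp2 + flank]
    h = max(_common_suffix(left_end, right_end), _common_prefix(after1, after2))
    if sv.svtype is SVType.INV:
        h = max(h,
                _common_suffix(left_end, _revcomp(after2)),
                _common_prefix(after1, _revcomp(right_end)))
    return min(h, flank)


def classify_mechanism(homology_len: int | None) -> str:
    """0-1 bp homology -> NON_HOM; 2-15 bp -> MICRO_HOM; longer homologies
    (macro-homology) are unresolved with short-read data, as is a missing
    measurement."""
    if homology_len is None:
        return UNRESOLVED
    if homology_len < 0:
        raise ValueError("homology length cannot be negative")
    if homology_len <= 1:
        return NON_HOM
    if homology_len <= 15:
        return MICRO_HOM
    return UNRESOLVED


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_dnms(dnms: Sequence[SVRecord], window_bp: int = 50_000,
                 ) -> list[MutationCluster]:
    """Single-linkage clustering of de novo mutations on each chromosome.

    Two mutations join one cluster when their intervals are within
    ``window_bp`` of each other; clusters chain transitively.  dnSNVs may be
    included as zero-length records.  Output order follows genomic order and
    is invariant to input order.
    """
    by_chrom: dict[str, list[SVRecord]] = {}
    for rec in dnms:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    clusters: list[MutationCluster] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end or r.start, r.id))
        current: list[SVRecord] = []
        current_max = -math.inf
        for rec in recs:
            if current and rec.start > current_max + window_bp:
                clusters.append(MutationCluster(
                    cluster_id=f"cluster_{len(clusters) + 1}",
                    chrom=chrom, members=current))
                current, current_max = [], -math.inf
            current.append(rec)
            current_max = max(current_max, rec.end or rec.start)
        if current:
            clusters.append(MutationCluster(
                cluster_id=f"cluster_{len(clusters) + 1}",
                chrom=chrom, members=current))
    return clusters


# ---------------------------------------------------------------------------
# Mosaicism
# ---------------------------------------------------------------------------

def mosaic_fraction(ref_reads: Sequence[int], alt_reads: Sequence[int],
                    germline_delta: float = 0.1) -> tuple[float, str]:
    """Deleted-DNA fraction and zygosity from het SNPs inside a deletion.

    Pools the per-SNP minor and major read counts; with ``r`` the pooled
    minor/major ratio, the carrier cell fraction is ``m = 1 - r`` and the
    deleted-DNA fraction ``d = m / 2``.  A germline heterozygous deletion
    removes half the DNA (``d = 0.5``, all reads from one haplotype); a 2:1
    ratio (``r = 0.5``) gives ``d = 0.25``, i.e. one haplotype deleted in
    half the cells.  Zygosity is germline when ``d`` lies within
    ``[0.5 - germline_delta, 0.5]``, else mosaic.
    """
    ref_reads = list(ref_reads)
    alt_reads = list(alt_reads)
    if len(ref_reads) != len(alt_reads) or not ref_reads:
        raise ValueError("need matched, non-empty ref/alt read counts")
    minor = sum(min(r, a) for r, a in zip(ref_reads, alt_reads))
    major = sum(max(r, a) for r, a in zip(ref_reads, alt_reads))
    if major == 0:
        return 0.5, "germline"   # hemizygous signal: no reads at all -> treat
    r = minor / major
    d = (1.0 - r) / 2.0
    zygosity = "germline" if (0.5 - germline_delta) <= d <= 0.5 else "mosaic"
    return d, zygosity


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

def estimate_rate(k: int, n: int, conf: float = 0.95) -> RateEstimate:
    """Per-generation dnSV rate ``k / n`` with a Wilson score interval.

    centre = (k + z^2/2) / (n + z^2),
    half-width = z * sqrt(k (n - k) / n + z^2 / 4) / (n + z^2).
    """
    if n < 1:
        raise ValueError("need at least one trio")
    if not 0 <= k <= n:
        raise ValueError("count must lie in [0, n]")
    z = float(stats.norm.ppf(1 - (1 - conf) / 2))
    rate = k / n
    denom = n + z * z
    centre = (k + z * z / 2) / denom
    half = z * math.sqrt(k * (n - k) / n + z * z / 4) / denom
    ci_low = 0.0 if k == 0 else max(0.0, centre - half)
    ci_high = 1.0 if k == n else min(1.0, centre + half)  # exact at the ends
    return RateEstimate(count=k, trios=n, rate=rate,
                        ci_low=ci_low, ci_high=ci_high, z=z)


def transmission_probability(n_offspring: int) -> float:
    """Probability that at least one of ``n`` sequenced offspring inherited a
    heterozygous proband's dnSV, under independent Mendelian transmission:
    ``1 - (1/2)^n``."""
    if n_offspring < 0:
        raise ValueError("offspring count cannot be negative")
    return 1.0 - 0.5 ** n_offspring


def check_transmission(dnsv: SVRecord, pedigree: Pedigree,
                       records: Sequence[SVRecord] | None = None,
                       proband: str | None = None) -> str:
    """Transmission status of a dnSV in the proband's sequenced offspring.

    ``validated`` when at least one sequenced offspring is heterozygous at
    the same site; ``no_offspring`` when none are sequenced; otherwise
    ``not_observed``.  By default genotypes are read from the dnSV record
    itself; ``records`` may supply a different callset to search.
    """
    if proband is None:
        carrier = [t.proband for t in pedigree.trios
                   if dnsv.evidence.get(t.proband) is not None
                   and dnsv.evidence[t.proband].genotype is Genotype.het]
        proband = carrier[0] if carrier else None
    offspring = pedigree.offspring_links.get(proband or "", [])
    if not offspring:
        return "no_offspring"
    site_rec = dnsv
    if records is not None:
        for rec in records:
            if rec.site_key == dnsv.site_key:
                site_rec = rec
                break
    for kid in offspring:
        ev = site_rec.evidence.get(kid)
        if ev is not None and ev.genotype is Genotype.het:
            return "validated"
    return "not_observed"


# ---------------------------------------------------------------------------
# Genic context
# ---------------------------------------------------------------------------

def genic_context(dnsv: SVRecord, gff_path: str,
                  ) -> tuple[str, list[str], str | None]:
    """Annotate an SV against gene/exon features of a GFF3 file.

    Returns ``(context, gene_ids, intron_label)`` with context ``exonic``
    when the SV intersects any exon, ``intronic`` when inside a gene body
    without touching an exon, else ``intergenic``.  For an intronic SV fully
    between two consecutive exons of a gene with ``E`` exons the label is
    ``"intron i/(E-1)"``.
    """
    import gffutils

    try:
        db = gffutils.create_db(str(gff_path), ":memory:",
                                merge_strategy="create_unique", force=True,
                                keep_order=True)
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {gff_path}: {exc}") from exc

    sv_lo, sv_hi = dnsv.start + 1, dnsv.end or dnsv.start + 1
    genes = []
    for gene in db.features_of_type("gene"):
        if gene.seqid == dnsv.chrom and gene.start <= sv_hi and gene.end >= sv_lo:
            genes.append(gene)
    if not genes:
        return "intergenic", [], None
    gene_ids = [g.id for g in genes]
    exon_hit = False
    intron_label: str | None = None
    for gene in genes:
        exons = sorted(
            (f for f in db.children(gene, featuretype="exon")),
            key=lambda f: f.start)
        for ex in exons:
            if ex.start <= sv_hi and ex.end >= sv_lo:
                exon_hit = True
        if not exon_hit and len(exons) >= 2:
            n_introns = len(exons) - 1
            for i in range(n_introns):
                intron_lo, intron_hi = exons[i].end + 1, exons[i + 1].start - 1
                if intron_lo <= sv_lo and sv_hi <= intron_hi:
                    ordinal = (i + 1 if gene.strand != "-"
                               else n_introns - i)
                    intron_label = f"intron {ordinal}/{n_introns}"
                    break
    context = "exonic" if exon_hit else "intronic"
    return context, gene_ids, intron_label
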