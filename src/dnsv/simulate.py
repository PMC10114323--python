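"""Synthetic trio cohort generator with planted ground truth.

Generates a pedigree-structured SV callset with the evidence fields a
population SV genotyper emits, per-sample binned depth profiles, a random
reference with controlled junction homology, informative SNPs with known
parental phase, and a truth table — so that every stage of the dnSV pipeline
is testable without the (restricted) study data.

Planted classes
---------------
* ``inherited`` — polymorphic SVs with Mendelian-consistent genotypes drawn
  from a per-site population allele frequency.
* ``de_novo`` — heterozygous in exactly one proband, absent everywhere else,
  with strong supporting evidence, a known parental haplotype of origin
  (marked by informative SNPs) and a planted junction-homology length.
* ``mosaic`` — a deletion present in a fraction ``m`` of the proband's
  cells; all evidence scales with ``m``.
* ``false_positive`` — candidates engineered to trip exactly one review
  rule or cascade filter, one per failure mode.

Evidence model (per-sample, heterozygous carrier with cell fraction ``m``)
--------------------------------------------------------------------------
Supporting-read counts are Binomial/Poisson around the coverage expected for
the carried allele; the allelic balance is centred at ``0.5 m``; depth
inside a deletion is attenuated by ``1 - m/4`` and inside a duplication
elevated by ``1 + m/4``, so a germline het deletion has an expected DHFFC of
0.75 and a germline het duplication an expected DHBFC of 1.25.  These
centres are deliberately conservative relative to the ideal copy arithmetic
(which would put a het deletion at 0.5): short-read depth estimators shrink
fold-changes toward 1, and the chosen centres still clear the cascade
thresholds (0.8 / 1.1) with margin.  All centres are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dnsv.svio import (
    DepthProfile,
    Genotype,
    Pedigree,
    SampleEvidence,
    SampleMeta,
    SmallVariant,
    SVRecord,
    SVType,
    Trio,
    write_bed,
    write_cohort,
    write_snv_vcf,
    save_depth_profiles,
)
from dnsv.filters import compute_dhffc, compute_dhbfc, gc_stratum_medians

# planted classes
INHERITED = "inherited"
DE_NOVO = "de_novo"
MOSAIC = "mosaic"
FALSE_POSITIVE = "false_positive"

# failure modes for false positives
REPEAT_BOTH = "repeat_both_breakpoints"
ONE_SIDED = "one_sided_support"
LOW_READ = "low_read_support"
NON_OVERLAPPING = "non_overlapping_reads"
NO_COVERAGE_SHIFT = "no_coverage_shift"
PARENTAL_EVIDENCE = "parental_evidence"
RECURRENT = "recurrent_in_cohort"

FAILURE_MODES = (REPEAT_BOTH, ONE_SIDED, LOW_READ, NON_OVERLAPPING,
                 NO_COVERAGE_SHIFT, PARENTAL_EVIDENCE, RECURRENT)

#: where each failure mode must be caught: ("review", rule id) or
#: ("cascade", acceptable failed-filter names).  Recurrent sites carry an
#: unrelated het carrier and are therefore already removed by the Mendelian
#: screen; the uniqueness filter is the backstop.
EXPECTED_REJECTION: dict[str, tuple[str, set]] = {
    REPEAT_BOTH: ("review", {1}),
    ONE_SIDED: ("review", {2}),
    LOW_READ: ("review", {3}),
    NON_OVERLAPPING: ("review", {4}),
    NO_COVERAGE_SHIFT: ("review", {5}),
    PARENTAL_EVIDENCE: ("cascade", {"sire_ab", "dam_ab", "sire_su", "dam_su"}),
    RECURRENT: ("mendelian", {"unrelated_carrier", "unique_in_cohort"}),
}

_BASES = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Ground truth for one planted variant."""

    sv_id: str
    planted_class: str
    svtype: str
    chrom: str
    start: int
    end: int
    failure_mode: str | None = None
    parent_of_origin: str = "none"
    homology_len: int = 0
    mosaic_cell_fraction: float = 1.0
    carrier_probands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.planted_class != MOSAIC and self.mosaic_cell_fraction != 1.0:
            raise ValueError("cell fraction < 1 is reserved for mosaic variants")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the study design: two commercial lines of deeply
    sequenced sire-dam-proband trios (~30x), a small number of genuine
    de novo SVs against a background of inherited polymorphisms, and false
    positives spanning every known evidence failure mode.  ``seed`` fixes
    the full output byte-for-byte.
    """

    n_trios_per_line: int = 20
    n_lines: int = 2
    mean_depth: float = 30.0
    depth_jitter: float = 2.0
    n_denovo: int = 10
    n_inherited: int = 200
    n_false_positive: int = 50
    n_mosaic: int = 1
    n_bnd: int = 2
    sv_size_range: tuple[int, int] = (150, 3000)
    homology_lengths: tuple[int, ...] = (0, 0, 0, 1, 2, 4, 5, 8, 12, 15)
    snp_density: float = 1 / 300.0       # informative SNPs per bp inside SVs
    mosaic_cell_fraction: float = 0.5
    inherited_af_range: tuple[float, float] = (0.05, 0.5)
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 1_000_000), ("chr2", 1_000_000), ("chr3", 1_000_000))
    depth_bin_size: int = 100
    gq_mean: float = 70.0
    gq_sd: float = 10.0
    base_error: float = 0.005
    n_offspring_probands: int = 2
    offspring_per_proband: int = 2
    n_decoy_repeats: int = 20
    max_place_attempts: int = 200
    seed: int = 1234

    def __post_init__(self) -> None:
        for name in ("n_trios_per_line", "n_denovo", "n_inherited",
                     "n_false_positive", "n_mosaic", "n_bnd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedCohort:
    """Everything :func:`simulate_cohort` produces."""

    config: SimConfig
    records: list[SVRecord]
    pedigree: Pedigree
    depth_profiles: dict[str, dict[str, DepthProfile]]
    snvs: list[SmallVariant]
    truth: dict[str, TruthRecord]
    reference: dict[str, str]
    repeats: dict[str, list[tuple[int, int]]]
    read_support: dict[str, dict[str, list[tuple[int, int, str]]]]
    gff_text: str
    mean_depths: dict[str, float]


# ---------------------------------------------------------------------------
# junction homology planting
# ---------------------------------------------------------------------------

def _pick_base(rng: np.random.Generator, exclude: set[str]) -> str:
    allowed = [b for b in "ACGT" if b not in exclude]
    return allowed[int(rng.integers(len(allowed)))]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def plant_junction(reference: np.ndarray, sv: SVRecord, homology_len: int,
                   flank: int = 20,
                   rng: np.random.Generator | None = None) -> str:
    """Engineer the reference so the SV's two breakpoint flanks share exactly
    ``homology_len`` identical bases, and return the junction contig.

    ``reference`` is a mutable per-base array (dtype ``<U1``) for the SV's
    chromosome.  The homology is written as a common suffix of the sequences
    ending at the two breakpoints; the bases immediately outside the planted
    stretch (and, for inversions, the reverse-complement pairings) are forced
    to mismatch so that the recovered homology equals ``homology_len``
    exactly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if homology_len < 0 or homology_len > flank:
        raise ValueError(f"homology_len must be in [0, {flank}]")
    bp1, bp2 = sv.start, sv.end
    if bp2 is None:
        raise ValueError("cannot plant a junction for a breakend record")
    if bp1 - flank - 1 < 0 or bp2 + flank >= len(reference):
        raise ValueError("SV too close to the reference edge for planting")
    k = homology_len
    # copy the k bases ending at bp1 to the k bases ending at bp2
    for i in range(1, k + 1):
        reference[bp2 - i] = reference[bp1 - i]
    if sv.svtype is SVType.INV:
        # guard the reverse-complement pairings before setting the breakers
        if k >= 1 and reference[bp1] == _COMP[str(reference[bp1 - 1])]:
            reference[bp1] = _pick_base(rng, {_COMP[str(reference[bp1 - 1])]})
    # suffix breaker: position k+1 before each breakpoint must differ
    excl = {str(reference[bp1 - k - 1])}
    if sv.svtype is SVType.INV and k == 0:
        excl.add(_COMP[str(reference[bp1])])
    reference[bp2 - k - 1] = _pick_base(rng, excl)
    # prefix breaker: first base after each breakpoint must differ
    excl = {str(reference[bp1])}
    if sv.svtype is SVType.INV:
        excl.add(_COMP[str(reference[bp1 - 1])])
        if k == 0:
            # RC-prefix guard: base after bp1 vs complement of base before bp2
            if reference[bp1] == _COMP[str(reference[bp2 - 1])]:
                reference[bp2 - 1] = _pick_base(
                    rng, {_COMP[str(reference[bp1])], str(reference[bp1 - 1])})
    reference[bp2] = _pick_base(rng, excl)

    left = "".join(reference[bp1 - flank:bp1])
    if sv.svtype is SVType.DEL:
        right = "".join(reference[bp2:bp2 + flank])
    elif sv.svtype is SVType.DUP:
        right = "".join(reference[bp1:bp1 + flank])
        left = "".join(reference[bp2 - flank:bp2])
    else:
        seg = "".join(reference[bp2 - flank:bp2])
        right = "".join(_COMP[b] for b in reversed(seg))
    return left + right


# ---------------------------------------------------------------------------
# depth machinery
# ---------------------------------------------------------------------------

def simulate_depth_profile(chrom: str, length: int, bin_size: int,
                           base_depth: float,
                           scaled_intervals: Sequence[tuple[int, int, float]],
                           gc: np.ndarray | None,
                           rng: np.random.Generator) -> DepthProfile:
    """Poisson depth around ``base_depth`` with multiplicative factors over
    the given (start, end, factor) intervals (package convention: affected
    bases ``start+1 .. end``)."""
    n_bins = length // bin_size
    mult = np.ones(n_bins)
    for start, end, factor in scaled_intervals:
        i0 = start // bin_size            # bin of base start+1
        i1 = (end - 1) // bin_size + 1
        mult[i0:i1] *= factor
    lam = base_depth * mult * bin_size
    depth = rng.poisson(lam).astype(float) / bin_size
    return DepthProfile(chrom=chrom, bin_size=bin_size, depth=depth, gc=gc)


def _depth_factor(svtype: SVType, genotype: Genotype, m: float) -> float:
    if svtype is SVType.DEL:
        return 1.0 - m / 4 if genotype is Genotype.het else 1.0 - m / 2
    if svtype is SVType.DUP:
        return 1.0 + m / 4 if genotype is Genotype.het else 1.0 + m / 2
    return 1.0


# ---------------------------------------------------------------------------
# internal planting plan
# ---------------------------------------------------------------------------

@dataclass
class _PlannedSV:
    sv_id: str
    planted_class: str
    svtype: SVType
    chrom: str = ""
    start: int = 0
    end: int = 0
    failure_mode: str | None = None
    origin: str = "none"
    homology_len: int = 0
    m: float = 1.0
    carrier_probands: list[str] = field(default_factory=list)
    af: float = 0.0
    with_gene: bool = False


def _place_intervals(plans: Sequence[_PlannedSV], config: SimConfig,
                     rng: np.random.Generator, pad: int = 3000) -> None:
    """Assign non-overlapping (chrom, start, end) to every plan in place."""
    chroms = list(config.chrom_lengths)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in chroms}
    total = sum(l for _, l in chroms)
    weights = [l / total for _, l in chroms]
    lo_sz, hi_sz = config.sv_size_range
    for plan in plans:
        size = int(rng.integers(lo_sz, hi_sz + 1))
        for _attempt in range(config.max_place_attempts):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom, clen = chroms[ci]
            start = int(rng.integers(3500, clen - size - 3500))
            end = start + size
            if all(e + pad < start or s - pad > end
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                plan.chrom, plan.start, plan.end = chrom, start, end
                break
        else:
            raise RuntimeError(
                "could not place SV without incompatible overlap; "
                "reduce counts or enlarge chromosomes")


def _hwe_genotype(q: float, rng: np.random.Generator) -> Genotype:
    u = rng.random()
    if u < (1 - q) ** 2:
        return Genotype.hom_ref
    if u < (1 - q) ** 2 + 2 * q * (1 - q):
        return Genotype.het
    return Genotype.hom_alt


def _transmit(gt: Genotype, rng: np.random.Generator) -> int:
    """Number of alt alleles (0/1) a parent passes on."""
    if gt is Genotype.hom_alt:
        return 1
    if gt is Genotype.het:
        return int(rng.random() < 0.5)
    return 0


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def build_pedigree(config: SimConfig) -> Pedigree:
    """Two-line trio pedigree with a few probands having sequenced
    third-generation offspring (line 1, mirroring the study design)."""
    ped = Pedigree()
    tissues = {"line1": ["ear"], "line2": ["ear", "hair", "semen"]}
    for li in range(config.n_lines):
        line = f"line{li + 1}"
        tlist = tissues.get(line, ["ear"])
        for ti in range(config.n_trios_per_line):
            tag = f"L{li + 1}T{ti + 1:02d}"
            sire, dam, prob = f"{tag}S", f"{tag}D", f"{tag}P"
            tissue = tlist[ti % len(tlist)]
            for sid in (sire, dam, prob):
                ped.samples[sid] = SampleMeta(line=line, tissue=tissue)
            ped.trios.append(Trio(sire=sire, dam=dam, proband=prob))
    line1_probands = [t.proband for t in ped.trios
                      if ped.samples[t.proband].line == "line1"]
    for prob in line1_probands[:config.n_offspring_probands]:
        kids = []
        for ki in range(config.offspring_per_proband):
            kid = f"{prob}O{ki + 1}"
            ped.samples[kid] = SampleMeta(line="line1", tissue="ear")
            kids.append(kid)
        ped.offspring_links[prob] = kids
    return ped


def _plan_cohort(config: SimConfig, ped: Pedigree,
                 rng: np.random.Generator) -> list[_PlannedSV]:
    plans: list[_PlannedSV] = []
    probands = [t.proband for t in ped.trios]
    dn_types = [SVType.DEL, SVType.DUP, SVType.INV]
    for i in range(config.n_denovo):
        svt = dn_types[i % 3]
        origin = ("none" if svt is SVType.INV
                  else ("paternal" if i % 2 == 0 else "maternal"))
        plans.append(_PlannedSV(
            sv_id=f"dn{i + 1:03d}", planted_class=DE_NOVO, svtype=svt,
            origin=origin,
            homology_len=config.homology_lengths[i % len(config.homology_lengths)],
            carrier_probands=[probands[(i * 7) % len(probands)]],
            with_gene=(i % 4 != 3)))
    # the first de novo SV goes to a proband with sequenced offspring when
    # available, so the transmission check has something to find
    offspring_probands = list(ped.offspring_links)
    if plans and offspring_probands:
        plans[0].carrier_probands = [offspring_probands[0]]
    for i in range(config.n_mosaic):
        plans.append(_PlannedSV(
            sv_id=f"mos{i + 1:02d}", planted_class=MOSAIC, svtype=SVType.DEL,
            m=config.mosaic_cell_fraction,
            carrier_probands=[probands[(i * 11 + 3) % len(probands)]]))
    lo_af, hi_af = config.inherited_af_range
    for i in range(config.n_inherited):
        plans.append(_PlannedSV(
            sv_id=f"inh{i + 1:04d}", planted_class=INHERITED,
            svtype=dn_types[i % 3],
            af=float(lo_af + (hi_af - lo_af) * rng.random())))
    fp_type_cycle = {NO_COVERAGE_SHIFT: [SVType.DEL, SVType.DUP],
                     PARENTAL_EVIDENCE: [SVType.DEL, SVType.DUP, SVType.INV]}
    for i in range(config.n_false_positive):
        mode = FAILURE_MODES[i % len(FAILURE_MODES)]
        cyc = fp_type_cycle.get(mode)
        svt = cyc[(i // len(FAILURE_MODES)) % len(cyc)] if cyc else SVType.INV
        carriers = [probands[(i * 13 + 5) % len(probands)]]
        if mode == RECURRENT:
            second = probands[(i * 13 + 5 + len(probands) // 2) % len(probands)]
            carriers.append(second)
        plans.append(_PlannedSV(
            sv_id=f"fp{i + 1:03d}", planted_class=FALSE_POSITIVE, svtype=svt,
            failure_mode=mode, carrier_probands=carriers))
    return plans


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate the full synthetic cohort; deterministic in ``config.seed``."""
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    ped = build_pedigree(config)
    sample_ids = list(ped.samples)
    trio_of = {t.proband: t for t in ped.trios}

    # reference
    reference_arr: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths:
        reference_arr[chrom] = _BASES[rng.integers(0, 4, size=length)]

    plans = _plan_cohort(config, ped, rng)
    _place_intervals(plans, config, rng)

    # junction homology for de novo and mosaic SVs
    read_support: dict[str, dict[str, list[tuple[int, int, str]]]] = {}
    for plan in plans:
        if plan.planted_class in (DE_NOVO, MOSAIC):
            shell = SVRecord(id=plan.sv_id, chrom=plan.chrom,
                             start=plan.start, end=plan.end, svtype=plan.svtype)
            plant_junction(reference_arr[plan.chrom], shell,
                           plan.homology_len, rng=rng)

    # repeats: around repeat-mode FP breakpoints, plus decoys in free space
    repeats: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in config.chrom_lengths}
    for plan in plans:
        if plan.failure_mode == REPEAT_BOTH:
            repeats[plan.chrom].append((plan.start - 60, plan.start + 60))
            repeats[plan.chrom].append((plan.end - 60, plan.end + 60))
    decoys = [_PlannedSV(sv_id=f"rep{i}", planted_class="repeat",
                         svtype=SVType.DEL)
              for i in range(config.n_decoy_repeats)]
    # decoys must not sit near real breakpoints: re-run placement for them
    # against the already-placed SVs
    occupied = {c: [(p.start, p.end) for p in plans if p.chrom == c]
                for c, _ in config.chrom_lengths}
    chroms = list(config.chrom_lengths)
    for d in decoys:
        size = int(rng.integers(200, 2000))
        for _ in range(config.max_place_attempts):
            ci = int(rng.integers(len(chroms)))
            chrom, clen = chroms[ci]
            start = int(rng.integers(3500, clen - size - 3500))
            end = start + size
            if all(e + 3000 < start or s - 3000 > end
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                repeats[chrom].append((start, end))
                break
    for c in repeats:
        repeats[c].sort()

    # genotypes
    genotypes: dict[str, dict[str, Genotype]] = {}
    truth: dict[str, TruthRecord] = {}
    for plan in plans:
        gts = {sid: Genotype.hom_ref for sid in sample_ids}
        if plan.planted_class == INHERITED:
            q = plan.af
            carriers: list[str] = []
            for trio in ped.trios:
                gts[trio.sire] = _hwe_genotype(q, rng)
                gts[trio.dam] = _hwe_genotype(q, rng)
                n_alt = (_transmit(gts[trio.sire], rng)
                         + _transmit(gts[trio.dam], rng))
                gts[trio.proband] = [Genotype.hom_ref, Genotype.het,
                                     Genotype.hom_alt][n_alt]
            for prob, kids in ped.offspring_links.items():
                for kid in kids:
                    n_alt = (_transmit(gts[prob], rng)
                             + _transmit(_hwe_genotype(q, rng), rng))
                    gts[kid] = [Genotype.hom_ref, Genotype.het,
                                Genotype.hom_alt][n_alt]
            carriers = [t.proband for t in ped.trios
                        if gts[t.proband] is not Genotype.hom_ref]
            plan.carrier_probands = carriers
        else:
            for prob in plan.carrier_probands:
                gts[prob] = Genotype.het
            if plan.planted_class == DE_NOVO:
                for kid in ped.offspring_links.get(
                        plan.carrier_probands[0], []):
                    if rng.random() < 0.5:
                        gts[kid] = Genotype.het
        genotypes[plan.sv_id] = gts
        truth[plan.sv_id] = TruthRecord(
            sv_id=plan.sv_id, planted_class=plan.planted_class,
            svtype=plan.svtype.value, chrom=plan.chrom, start=plan.start,
            end=plan.end, failure_mode=plan.failure_mode,
            parent_of_origin=plan.origin, homology_len=plan.homology_len,
            mosaic_cell_fraction=plan.m if plan.planted_class == MOSAIC else 1.0,
            carrier_probands=list(plan.carrier_probands))

    # depth profiles
    base_depth = {sid: float(np.clip(rng.normal(config.mean_depth,
                                                config.depth_jitter), 10, None))
                  for sid in sample_ids}
    gc_track: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths:
        arr = reference_arr[chrom]
        n_bins = length // config.depth_bin_size
        isgc = np.isin(arr[:n_bins * config.depth_bin_size], ["G", "C"])
        gc_track[chrom] = isgc.reshape(n_bins, config.depth_bin_size).mean(axis=1)

    shifted: dict[str, list[tuple[str, int, int, float]]] = {sid: [] for sid in sample_ids}
    for plan in plans:
        if plan.failure_mode == NO_COVERAGE_SHIFT:
            continue  # the defining feature: the depth profile is flat
        for sid, gt in genotypes[plan.sv_id].items():
            if gt is Genotype.hom_ref:
                continue
            f = _depth_factor(plan.svtype, gt, plan.m)
            if f != 1.0:
                shifted[sid].append((plan.chrom, plan.start, plan.end, f))

    depth_profiles: dict[str, dict[str, DepthProfile]] = {}
    for sid in sample_ids:
        per_chrom: dict[str, DepthProfile] = {}
        for chrom, length in config.chrom_lengths:
            ivs = [(s, e, f) for c, s, e, f in shifted[sid] if c == chrom]
            per_chrom[chrom] = simulate_depth_profile(
                chrom, length, config.depth_bin_size, base_depth[sid],
                ivs, gc_track[chrom], rng)
        depth_profiles[sid] = per_chrom
    mean_depths = {sid: float(np.mean(np.concatenate(
        [p.depth for p in depth_profiles[sid].values()])))
        for sid in sample_ids}
    stratum_cache = {sid: {chrom: gc_stratum_medians(prof)
                           for chrom, prof in per.items()}
                     for sid, per in depth_profiles.items()}

    # evidence fields and SVRecords
    records: list[SVRecord] = []
    for plan in plans:
        rec = SVRecord(id=plan.sv_id, chrom=plan.chrom, start=plan.start,
                       end=plan.end, svtype=plan.svtype)
        gts = genotypes[plan.sv_id]
        for sid in sample_ids:
            gt = gts[sid]
            ev = _draw_evidence(rng, gt, base_depth[sid], plan.m, config)
            prof = depth_profiles[sid][plan.chrom]
            ev.dhffc = compute_dhffc(prof, (plan.start, plan.end))
            ev.dhbfc, _ = compute_dhbfc(prof, (plan.start, plan.end),
                                        stratum_cache[sid][plan.chrom])
            rec.evidence[sid] = ev
        _apply_failure_mode(plan, rec, trio_of, rng)
        records.append(rec)

    # breakends (kept in the callset, excluded from analysis)
    for i in range(config.n_bnd):
        chrom, clen = config.chrom_lengths[i % len(config.chrom_lengths)]
        pos = int(rng.integers(10_000, clen - 10_000))
        rec = SVRecord(id=f"bnd{i + 1:02d}", chrom=chrom, start=pos,
                       end=None, svtype=SVType.BND)
        for sid in sample_ids:
            rec.evidence[sid] = _draw_evidence(
                rng, Genotype.hom_ref, base_depth[sid], 1.0, config)
        records.append(rec)

    # breakpoint-local read support for candidates that can reach review
    for plan in plans:
        if plan.planted_class == INHERITED:
            continue
        read_support[plan.sv_id] = _draw_read_support(
            plan, base_depth[plan.carrier_probands[0]], rng)

    # informative SNPs inside de novo and mosaic SVs
    snvs: list[SmallVariant] = []
    for plan in plans:
        if plan.planted_class == DE_NOVO and plan.svtype in (SVType.DEL, SVType.DUP):
            trio = trio_of[plan.carrier_probands[0]]
            snvs.extend(_informative_snps(
                plan, trio, reference_arr[plan.chrom], sample_ids,
                base_depth, config, rng))
        elif plan.planted_class == MOSAIC:
            trio = trio_of[plan.carrier_probands[0]]
            snvs.extend(_informative_snps(
                plan, trio, reference_arr[plan.chrom], sample_ids,
                base_depth, config, rng))
    snvs.sort(key=lambda v: (v.chrom, v.pos))

    gff_text = _build_gff(plans)
    reference = {chrom: "".join(arr) for chrom, arr in reference_arr.items()}
    records.sort(key=lambda r: (r.chrom, r.start, r.id))
    return SimulatedCohort(
        config=config, records=records, pedigree=ped,
        depth_profiles=depth_profiles, snvs=snvs, truth=truth,
        reference=reference, repeats=repeats, read_support=read_support,
        gff_text=gff_text, mean_depths=mean_depths)


def _draw_evidence(rng: np.random.Generator, gt: Genotype, depth: float,
                   m: float, config: SimConfig) -> SampleEvidence:
    n = max(1, int(rng.poisson(depth)))
    if gt is Genotype.het:
        p_alt = 0.5 * m
    elif gt is Genotype.hom_alt:
        p_alt = min(1.0, m)
    else:
        p_alt = config.base_error
    alt = int(rng.binomial(n, p_alt))
    ab = alt / n
    if gt in (Genotype.het, Genotype.hom_alt):
        su = int(rng.poisson(depth / 2 * m * (2 if gt is Genotype.hom_alt else 1)))
    else:
        su = alt
    sr = int(rng.binomial(su, 0.5)) if su else 0
    gq = float(np.clip(round(rng.normal(config.gq_mean, config.gq_sd)), 1, 99))
    return SampleEvidence(genotype=gt, gq=gq, ab=ab, su=su, pe=su - sr,
                          sr=sr, dhffc=None, dhbfc=None)


def _apply_failure_mode(plan: _PlannedSV, rec: SVRecord,
                        trio_of: Mapping[str, Trio],
                        rng: np.random.Generator) -> None:
    """Adjust VCF-level evidence so each failure mode passes every stage
    before the one meant to catch it."""
    mode = plan.failure_mode
    if mode is None:
        return
    if mode == NO_COVERAGE_SHIFT:
        # the genotyper reported a convincing fold-change that the actual
        # depth profile does not show
        for prob in plan.carrier_probands:
            ev = rec.evidence[prob]
            if plan.svtype is SVType.DEL:
                ev.dhffc = 0.55 + 0.1 * rng.random()
            else:
                ev.dhbfc = 1.25 + 0.1 * rng.random()
    elif mode == PARENTAL_EVIDENCE:
        # parents are called hom_ref but carry read evidence for the allele
        trio = trio_of[plan.carrier_probands[0]]
        for parent in (trio.sire, trio.dam):
            ev = rec.evidence[parent]
            ev.ab = 0.2 + 0.1 * rng.random()
            ev.su = int(5 + rng.integers(0, 4))
            ev.sr = ev.su // 2
            ev.pe = ev.su - ev.sr


def _draw_read_support(plan: _PlannedSV, depth: float,
                       rng: np.random.Generator,
                       ) -> dict[str, list[tuple[int, int, str]]]:
    """Supporting-read intervals at each breakpoint for the carrier proband."""
    mode = plan.failure_mode

    def good_side(bp: int, n_min: int = 3) -> list[tuple[int, int, str]]:
        n = max(n_min, int(rng.poisson(depth / 2 * plan.m)))
        out = []
        for j in range(n):
            s = bp - int(rng.integers(20, 131))
            out.append((s, s + 150, "SR" if j % 2 == 0 else "PE"))
        return out

    left = good_side(plan.start)
    if mode == ONE_SIDED:
        right: list[tuple[int, int, str]] = []
    elif mode == LOW_READ:
        s = plan.end - 100
        right = [(s, s + 150, "SR"), (s - 40, s + 110, "PE")]
    elif mode == NON_OVERLAPPING:
        right = [(plan.end - 400, plan.end - 260, "SR"),
                 (plan.end - 200, plan.end - 60, "PE"),
                 (plan.end + 20, plan.end + 160, "SR")]
    else:
        right = good_side(plan.end)
    return {"left": left, "right": right}


def _informative_snps(plan: _PlannedSV, trio: Trio, ref_arr: np.ndarray,
                      sample_ids: Sequence[str],
                      base_depth: Mapping[str, float], config: SimConfig,
                      rng: np.random.Generator) -> list[SmallVariant]:
    """Plant phase-informative SNPs inside an SV.

    Deletions: the origin parent is homozygous for one allele, the other
    parent homozygous for the other; the proband's reads show only the
    non-origin parent's allele (scaled by the cell fraction for mosaics).
    Duplications: one parent homozygous, the other heterozygous, proband
    heterozygous with the duplicated (origin-parent) allele over-represented
    at (1+m):1.
    """
    length = plan.end - plan.start
    n_snps = max(2, int(length * config.snp_density))
    margin = 25
    if length <= 2 * margin + n_snps:
        return []
    positions = np.linspace(plan.start + margin, plan.end - margin,
                            n_snps + 1, dtype=int)[:-1]
    positions = sorted(set(int(p) + int(rng.integers(0, 10)) for p in positions))
    origin_parent = trio.sire if plan.origin == "paternal" else trio.dam
    other_parent = trio.dam if origin_parent == trio.sire else trio.sire
    m = plan.m
    out: list[SmallVariant] = []
    for pi, pos in enumerate(positions):
        ref_base = str(ref_arr[pos - 1])
        alt_base = _pick_base(rng, {ref_base})
        snv = SmallVariant(chrom=plan.chrom, pos=pos, ref=ref_base,
                           alt=alt_base)
        for sid in sample_ids:
            snv.genotypes[sid] = Genotype.hom_ref
        origin_allele_is_alt = (pi % 2 == 0)
        if plan.svtype is SVType.DEL:
            og = Genotype.hom_alt if origin_allele_is_alt else Genotype.hom_ref
            ug = Genotype.hom_ref if origin_allele_is_alt else Genotype.hom_alt
            snv.genotypes[origin_parent] = og
            snv.genotypes[other_parent] = ug
            # proband copies: origin haplotype present in (1-m) of cells
            n = max(1, int(rng.poisson(base_depth[trio.proband] * (2 - m) / 2)))
            f_origin = (1 - m) / (2 - m)
            n_origin = int(rng.binomial(n, f_origin))
            n_other = n - n_origin
            alt_reads = n_origin if origin_allele_is_alt else n_other
            snv.allele_depths[trio.proband] = (n - alt_reads, alt_reads)
            minor = min(n_origin, n_other) / n
            if minor <= 0.05:
                called = (Genotype.hom_alt if alt_reads > n - alt_reads
                          else Genotype.hom_ref)
            else:
                called = Genotype.het
            snv.genotypes[trio.proband] = called
            _parent_ad(snv, origin_parent, og, base_depth, rng)
            _parent_ad(snv, other_parent, ug, base_depth, rng)
        else:  # DUP (origin parent donates the duplicated allele)
            og = Genotype.hom_alt if origin_allele_is_alt else Genotype.hom_ref
            snv.genotypes[origin_parent] = og
            snv.genotypes[other_parent] = Genotype.het
            snv.genotypes[trio.proband] = Genotype.het
            n = max(1, int(rng.poisson(base_depth[trio.proband] * (2 + m) / 2)))
            f_dup = (1 + m) / (2 + m)
            n_dup = int(rng.binomial(n, f_dup))
            alt_reads = n_dup if origin_allele_is_alt else n - n_dup
            snv.allele_depths[trio.proband] = (n - alt_reads, alt_reads)
            _parent_ad(snv, origin_parent, og, base_depth, rng)
            _parent_ad(snv, other_parent, Genotype.het, base_depth, rng)
        out.append(snv)
    return out


def _parent_ad(snv: SmallVariant, sample: str, gt: Genotype,
               base_depth: Mapping[str, float],
               rng: np.random.Generator) -> None:
    n = max(1, int(rng.poisson(base_depth[sample])))
    p = {Genotype.hom_ref: 0.0, Genotype.het: 0.5, Genotype.hom_alt: 1.0}[gt]
    alt = int(rng.binomial(n, min(1.0, max(0.0, p))))
    snv.allele_depths[sample] = (n - alt, alt)


def _build_gff(plans: Sequence[_PlannedSV]) -> str:
    """Gene models enclosing most de novo SVs: the SV falls in intron 1 of a
    4-exon gene; every fourth de novo SV is left intergenic."""
    lines = ["##gff-version 3"]
    gi = 0
    for plan in plans:
        if plan.planted_class != DE_NOVO or not plan.with_gene:
            continue
        gi += 1
        gid = f"gene{gi:03d}"
        gs, ge = plan.start - 2000, plan.end + 2000
        lines.append(f"{plan.chrom}\tsim\tgene\t{gs}\t{ge}\t.\t+\t.\tID={gid}")
        exons = [(gs, gs + 200),
                 (plan.end + 500, plan.end + 650),
                 (plan.end + 900, plan.end + 1050),
                 (ge - 150, ge)]
        for xi, (xs, xe) in enumerate(exons, 1):
            lines.append(f"{plan.chrom}\tsim\texon\t{xs}\t{xe}\t.\t+\t.\t"
                         f"ID={gid}.e{xi};Parent={gid}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# phasing benchmark
# ---------------------------------------------------------------------------

def simulate_phasing_benchmark(n_svs: int = 100, depth: float = 30.0,
                               noise: bool = True, seed: int = 0,
                               ) -> list[tuple[SVRecord, list[SmallVariant], Trio, str]]:
    """Stand-alone parent-of-origin benchmark: ``n_svs`` phased dnSVs (half
    deletions, half duplications) with informative SNPs, either with exact
    read counts (``noise=False``) or Binomial read noise at ``depth``."""
    rng = np.random.default_rng(seed)
    trio = Trio(sire="S", dam="D", proband="P")
    samples = ["S", "D", "P"]
    out = []
    for i in range(n_svs):
        svt = SVType.DEL if i % 2 == 0 else SVType.DUP
        origin = "paternal" if (i // 2) % 2 == 0 else "maternal"
        start = 10_000
        end = start + 1_500
        rec = SVRecord(id=f"bm{i:03d}", chrom=f"c{i}", start=start, end=end,
                       svtype=svt)
        origin_parent = "S" if origin == "paternal" else "D"
        other_parent = "D" if origin_parent == "S" else "S"
        snvs = []
        for si in range(4):
            pos = start + 200 + si * 250
            snv = SmallVariant(chrom=rec.chrom, pos=pos, ref="A", alt="G")
            origin_is_alt = si % 2 == 0
            if svt is SVType.DEL:
                og = Genotype.hom_alt if origin_is_alt else Genotype.hom_ref
                ug = Genotype.hom_ref if origin_is_alt else Genotype.hom_alt
                snv.genotypes = {origin_parent: og, other_parent: ug}
                if noise:
                    n = max(1, int(rng.poisson(depth / 2)))
                    err = int(rng.binomial(n, 0.005))
                else:
                    n, err = int(depth / 2), 0
                n_origin, n_other = err, n - err
                alt_reads = n_origin if origin_is_alt else n_other
                snv.allele_depths = {"P": (n - alt_reads, alt_reads)}
                minor = min(n_origin, n_other) / n
                snv.genotypes["P"] = (
                    Genotype.het if minor > 0.05 else
                    (Genotype.hom_alt if alt_reads > n - alt_reads
                     else Genotype.hom_ref))
            else:
                og = Genotype.hom_alt if origin_is_alt else Genotype.hom_ref
                snv.genotypes = {origin_parent: og, other_parent: Genotype.het,
                                 "P": Genotype.het}
                if noise:
                    n = max(1, int(rng.poisson(depth * 1.5)))
                    n_dup = int(rng.binomial(n, 2 / 3))
                else:
                    n, n_dup = 45, 30
                alt_reads = n_dup if origin_is_alt else n - n_dup
                snv.allele_depths = {"P": (n - alt_reads, alt_reads)}
            for sid in samples:
                snv.genotypes.setdefault(sid, Genotype.hom_ref)
            snvs.append(snv)
        out.append((rec, snvs, trio, origin))
    return out


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_simulated_cohort(cohort: SimulatedCohort,
                           out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    contigs = dict(cohort.config.chrom_lengths)
    write_cohort(cohort.records, cohort.pedigree, out / "sv.vcf",
                 out / "cohort.ped", contigs=contigs)
    paths["sv_vcf"] = out / "sv.vcf"
    paths["ped"] = out / "cohort.ped"
    write_snv_vcf(cohort.snvs, list(cohort.pedigree.samples),
                  out / "snv.vcf", contigs=contigs)
    paths["snv_vcf"] = out / "snv.vcf"
    with open(out / "reference.fa", "w") as fh:
        for chrom, seq in cohort.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    paths["reference"] = out / "reference.fa"
    write_bed(cohort.repeats, out / "repeats.bed")
    paths["repeats"] = out / "repeats.bed"
    (out / "genes.gff3").write_text(cohort.gff_text)
    paths["gff"] = out / "genes.gff3"
    rows = [{
        "sv_id": t.sv_id, "class": t.planted_class, "svtype": t.svtype,
        "chrom": t.chrom, "start": t.start, "end": t.end,
        "failure_mode": t.failure_mode or "",
        "parent_of_origin": t.parent_of_origin,
        "homology_len": t.homology_len, "m": t.mosaic_cell_fraction,
        "carrier_probands": ",".join(t.carrier_probands),
    } for t in cohort.truth.values()]
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    sup_rows = []
    for sv_id, sides in cohort.read_support.items():
        for side, reads in sides.items():
            for s, e, kind in reads:
                sup_rows.append({"sv_id": sv_id, "side": side,
                                 "start": s, "end": e, "kind": kind})
    pd.DataFrame(sup_rows, columns=["sv_id", "side", "start", "end", "kind"]
                 ).to_csv(out / "read_support.tsv", sep="\t", index=False)
    paths["read_support"] = out / "read_support.tsv"
    save_depth_profiles(cohort.depth_profiles, out / "depth")
    paths["depth_dir"] = out / "depth"
    import json
    from dataclasses import asdict
    (out / "config.json").write_text(
        json.dumps(asdict(cohort.config), indent=2) + "\n")
    paths["config"] = out / "config.json"
    return paths


def read_simulated_cohort(in_dir: str | Path) -> SimulatedCohort:
    """Reload a cohort written by :func:`write_simulated_cohort`."""
    import json

    from pyfaidx import Fasta

    from dnsv.svio import load_cohort, load_depth_profiles, read_bed, read_snv_vcf

    src = Path(in_dir)
    cfg_raw = json.loads((src / "config.json").read_text())
    cfg_raw["sv_size_range"] = tuple(cfg_raw["sv_size_range"])
    cfg_raw["homology_lengths"] = tuple(cfg_raw["homology_lengths"])
    cfg_raw["inherited_af_range"] = tuple(cfg_raw["inherited_af_range"])
    cfg_raw["chrom_lengths"] = tuple(
        (c, l) for c, l in cfg_raw["chrom_lengths"])
    config = SimConfig(**cfg_raw)
    records, ped = load_cohort(src / "sv.vcf", src / "cohort.ped")
    snvs = read_snv_vcf(src / "snv.vcf")
    fasta = Fasta(str(src / "reference.fa"))
    reference = {name: str(fasta[name][:]) for name in fasta.keys()}
    repeats = read_bed(src / "repeats.bed")
    gff_text = (src / "genes.gff3").read_text()
    truth = read_truth(src / "truth.tsv")
    read_support = read_read_support(src / "read_support.tsv")
    depth_profiles = load_depth_profiles(src / "depth")
    mean_depths = {sid: float(np.mean(np.concatenate(
        [p.depth for p in per.values()])))
        for sid, per in depth_profiles.items()}
    return SimulatedCohort(
        config=config, records=records, pedigree=ped,
        depth_profiles=depth_profiles, snvs=snvs, truth=truth,
        reference=reference, repeats=repeats, read_support=read_support,
        gff_text=gff_text, mean_depths=mean_depths)


def read_read_support(path: str | Path
                      ) -> dict[str, dict[str, list[tuple[int, int, str]]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, list[tuple[int, int, str]]]] = {}
    for row in df.itertuples():
        out.setdefault(row.sv_id, {}).setdefault(row.side, []).append(
            (int(row.start), int(row.end), str(row.kind)))
    return out


def read_truth(path: str | Path) -> dict[str, TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = {}
    for row in df.to_dict("records"):
        out[row["sv_id"]] = TruthRecord(
            sv_id=row["sv_id"], planted_class=row["class"],
            svtype=row["svtype"], chrom=str(row["chrom"]),
            start=int(row["start"]), end=int(row["end"]),
            failure_mode=row["failure_mode"] or None,
            parent_of_origin=row["parent_of_origin"],
            homology_len=int(row["homology_len"]),
            mosaic_cell_fraction=float(row["m"]),
            carrier_probands=[c for c in str(row["carrier_probands"]).split(",")
                              if c])
    return out
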