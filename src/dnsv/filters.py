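"""Candidate dnSV filter cascade.

A de novo SV candidate is a (site, trio) pair where the proband is
heterozygous and no other cohort sample carries the allele.  Candidates then
pass a trio genotype-quality sum filter, a cohort allele-frequency cap, and a
per-type evidence filter over allelic balance, supporting reads and depth
fold-changes, with a final uniqueness screen across probands.  Every
inequality is strict exactly as declared in the thresholds; all filters are
pure predicates, so the survivor set is independent of the order in which
they are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from dnsv.svio import (
    DepthProfile,
    Genotype,
    Pedigree,
    SVRecord,
    SVType,
    Trio,
)


@dataclass(frozen=True)
class Thresholds:
    """Filter thresholds; defaults are the published values of the cascade.

    ``gq_sum`` — trio GQ sum must exceed this; ``af_max`` — cohort allele
    frequency above this excludes (equality retained); DEL needs proband
    DHFFC below ``del_dhffc`` and parents' mean DHFFC above
    ``del_parent_dhffc``; DUP needs proband DHBFC above ``dup_dhbfc`` and
    parents' mean DHBFC below ``dup_parent_dhbfc``; per-type proband AB
    minima and SU minima; each parent individually must stay below
    ``parent_ab_max`` and at or below ``parent_su_max``.
    """

    gq_sum: float = 120.0
    af_max: float = 0.1
    del_dhffc: float = 0.8
    del_parent_dhffc: float = 0.8
    del_ab: float = 0.05
    del_su: int = 3
    dup_dhbfc: float = 1.1
    dup_parent_dhbfc: float = 1.2
    dup_ab: float = 0.1
    dup_su: int = 3
    inv_ab: float = 0.2
    inv_su: int = 5
    parent_ab_max: float = 0.1
    parent_su_max: int = 3


@dataclass
class FilterCheck:
    name: str
    observed: float | None
    threshold: float | None
    passed: bool

    def compact(self) -> str:
        obs = "NA" if self.observed is None else f"{self.observed:g}"
        thr = "NA" if self.threshold is None else f"{self.threshold:g}"
        return f"{self.name}={obs}/{thr}:{'P' if self.passed else 'F'}"


@dataclass
class FilterTrace:
    """Ordered record of every filter applied to one candidate."""

    checks: list[FilterCheck] = field(default_factory=list)

    def add(self, name: str, observed, threshold, passed: bool) -> bool:
        self.checks.append(FilterCheck(name, observed, threshold, bool(passed)))
        return bool(passed)

    @property
    def status(self) -> str:
        return "candidate" if all(c.passed for c in self.checks) else "rejected"

    @property
    def failed_names(self) -> list[str]:
        return [c.name for c in self.checks if not c.passed]

    def compact(self) -> str:
        return ";".join(c.compact() for c in self.checks)


@dataclass
class CandidateDnSV:
    """An SV site bound to one trio, with its filter trace and review verdict."""

    record: SVRecord
    trio: Trio
    trace: FilterTrace = field(default_factory=FilterTrace)
    verdict: str | None = None
    violated_rules: list[int] = field(default_factory=list)

    @property
    def status(self) -> str:
        return self.trace.status


# ---------------------------------------------------------------------------
# Mendelian screening
# ---------------------------------------------------------------------------

def mendelian_candidates(records: Iterable[SVRecord],
                         pedigree: Pedigree) -> list[CandidateDnSV]:
    """Screen for de novo candidates: proband het, everyone else allele-free.

    The proband must be heterozygous and both parents plus every unrelated
    cohort sample homozygous reference.  A missing parent genotype
    disqualifies (conservative); a missing genotype in an unrelated sample
    counts as non-carrier (missingness is common and the allele-frequency
    filter backstops).  The proband's own sequenced offspring are exempt
    from the non-carrier requirement, since a genuine dnSV is transmitted to
    them half the time.  Breakend records are dropped before screening.
    """
    out: list[CandidateDnSV] = []
    all_samples = set(pedigree.samples)
    for rec in records:
        if rec.excluded_from_analysis:
            continue
        carriers = {sid for sid, ev in rec.evidence.items()
                    if ev.genotype in (Genotype.het, Genotype.hom_alt)}
        for trio in pedigree.trios:
            ev_p = rec.evidence.get(trio.proband)
            if ev_p is None or ev_p.genotype is not Genotype.het:
                continue
            ev_s = rec.evidence.get(trio.sire)
            ev_d = rec.evidence.get(trio.dam)
            if (ev_s is None or ev_s.genotype is not Genotype.hom_ref or
                    ev_d is None or ev_d.genotype is not Genotype.hom_ref):
                continue
            exempt = set(trio.members()) | set(
                pedigree.offspring_links.get(trio.proband, []))
            unrelated = (all_samples & set(rec.evidence)) - exempt
            if carriers & unrelated:
                continue
            cand = CandidateDnSV(record=rec, trio=trio)
            cand.trace.add("mendelian", None, None, True)
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Pure per-candidate predicates
# ---------------------------------------------------------------------------

def trio_gq_filter(candidate: CandidateDnSV,
                   thresholds: Thresholds = Thresholds()) -> bool:
    """Pass iff the trio's GQ sum is strictly greater than the threshold."""
    rec, trio = candidate.record, candidate.trio
    gqs = [rec.evidence.get(m, None) for m in trio.members()]
    vals = [e.gq for e in gqs if e is not None]
    if len(vals) != 3 or any(v is None for v in vals):
        return candidate.trace.add("gq_sum", None, thresholds.gq_sum, False)
    total = float(sum(vals))
    return candidate.trace.add("gq_sum", total, thresholds.gq_sum,
                               total > thresholds.gq_sum)


def cohort_af(record: SVRecord, samples: Sequence[str] | None = None) -> float:
    """Cohort allele frequency: alt alleles over 2x non-missing genotypes."""
    ids = samples if samples is not None else list(record.evidence)
    alt = 0
    genotyped = 0
    for sid in ids:
        ev = record.evidence.get(sid)
        if ev is None or ev.genotype is Genotype.missing:
            continue
        genotyped += 1
        if ev.genotype is Genotype.het:
            alt += 1
        elif ev.genotype is Genotype.hom_alt:
            alt += 2
    if genotyped == 0:
        raise ValueError(f"no genotyped samples at {record.id}")
    return alt / (2 * genotyped)


def af_filter(candidate: CandidateDnSV, samples: Sequence[str] | None = None,
              thresholds: Thresholds = Thresholds()) -> bool:
    """Exclude candidates with cohort AF strictly above the cap.

    Equality is retained: the cap is deliberately permissive so that a dnSV
    transmitted from the proband to sequenced third-generation offspring is
    not discarded.
    """
    af = cohort_af(candidate.record, samples)
    return candidate.trace.add("af", af, thresholds.af_max,
                               af <= thresholds.af_max)


def type_specific_filter(candidate: CandidateDnSV,
                         thresholds: Thresholds = Thresholds()) -> FilterTrace:
    """Apply the per-type evidence filter; all inequalities strict.

    DEL: proband DHFFC < del_dhffc, parents' mean DHFFC > del_parent_dhffc,
    proband AB > del_ab, proband SU >= del_su.  DUP: proband DHBFC >
    dup_dhbfc, parents' mean DHBFC < dup_parent_dhbfc, proband AB > dup_ab,
    proband SU >= dup_su.  INV: proband AB > inv_ab, proband SU >= inv_su.
    All types: each parent AB < parent_ab_max and SU <= parent_su_max.
    Missing required evidence fails the corresponding check.
    """
    rec, trio = candidate.record, candidate.trio
    if rec.svtype is SVType.BND:
        raise ValueError("breakend records are excluded before type filtering")
    t = thresholds
    trace = candidate.trace
    ev_p = rec.evidence.get(trio.proband)
    ev_s = rec.evidence.get(trio.sire)
    ev_d = rec.evidence.get(trio.dam)

    def _gt(name, val, thr):
        trace.add(name, val, thr, val is not None and val > thr)

    def _lt(name, val, thr):
        trace.add(name, val, thr, val is not None and val < thr)

    def _ge(name, val, thr):
        trace.add(name, val, thr, val is not None and val >= thr)

    def _le(name, val, thr):
        trace.add(name, val, thr, val is not None and val <= thr)

    def _parent_mean(attr):
        vals = [getattr(e, attr) for e in (ev_s, ev_d)
                if e is not None and getattr(e, attr) is not None]
        return sum(vals) / len(vals) if len(vals) == 2 else None

    p = ev_p or None
    if rec.svtype is SVType.DEL:
        _lt("proband_dhffc", p.dhffc if p else None, t.del_dhffc)
        _gt("parent_mean_dhffc", _parent_mean("dhffc"), t.del_parent_dhffc)
        _gt("proband_ab", p.ab if p else None, t.del_ab)
        _ge("proband_su", p.su if p else None, t.del_su)
    elif rec.svtype is SVType.DUP:
        _gt("proband_dhbfc", p.dhbfc if p else None, t.dup_dhbfc)
        _lt("parent_mean_dhbfc", _parent_mean("dhbfc"), t.dup_parent_dhbfc)
        _gt("proband_ab", p.ab if p else None, t.dup_ab)
        _ge("proband_su", p.su if p else None, t.dup_su)
    elif rec.svtype is SVType.INV:
        _gt("proband_ab", p.ab if p else None, t.inv_ab)
        _ge("proband_su", p.su if p else None, t.inv_su)
    for label, ev in (("sire", ev_s), ("dam", ev_d)):
        _lt(f"{label}_ab", ev.ab if ev else None, t.parent_ab_max)
        _le(f"{label}_su", ev.su if ev else None, t.parent_su_max)
    return trace


def uniqueness_filter(candidates: Sequence[CandidateDnSV]
                      ) -> list[CandidateDnSV]:
    """Drop every candidate whose identical site (chrom/start/end/svtype) is
    a candidate in more than one proband; a dnSV is a one-time event."""
    by_site: dict[tuple, set[str]] = {}
    for cand in candidates:
        by_site.setdefault(cand.record.site_key, set()).add(cand.trio.proband)
    kept = []
    for cand in candidates:
        recurrent = len(by_site[cand.record.site_key]) > 1
        cand.trace.add("unique_in_cohort",
                       float(len(by_site[cand.record.site_key])), 1.0,
                       not recurrent)
        if not recurrent:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Depth fold-changes
# ---------------------------------------------------------------------------

def _median(values: np.ndarray) -> float:
    return float(np.median(values))


def compute_dhffc(profile: DepthProfile, interval: tuple[int, int],
                  flank_bp: int = 1000) -> float:
    """Flank fold-change: median depth inside the SV over the median depth of
    the concatenated 1 kb left and right flanks.

    ``interval`` is (start, end) in the package convention: affected bases
    are ``start+1 .. end``.  Returns ``inf`` when the flank median is zero.
    The interval plus flanks must lie inside the profile.
    """
    start, end = interval
    if end <= start:
        raise ValueError("interval end must exceed start")
    bs = profile.bin_size
    lo = start + 1 - flank_bp
    hi = end + flank_bp
    if lo < 1 or hi > profile.seq_length:
        raise ValueError(
            f"interval {interval} with {flank_bp} bp flanks is outside the "
            f"depth profile for {profile.chrom}")
    inside = profile.depth[profile.bin_index(start + 1):
                           profile.bin_index(end) + 1]
    left = profile.depth[profile.bin_index(lo):profile.bin_index(start) + 1]
    right = profile.depth[profile.bin_index(end + 1):
                          profile.bin_index(hi) + 1]
    flank = np.concatenate([left, right])
    fm = _median(flank)
    if fm == 0:
        return math.inf
    return _median(inside) / fm


GC_STRATUM_WIDTH = 0.05


def compute_dhbfc(profile: DepthProfile, interval: tuple[int, int],
                  stratum_medians: Mapping[int, float] | None = None,
                  ) -> tuple[float, bool]:
    """GC-matched fold-change: median depth inside the SV over the median
    depth of all genome bins in the same GC stratum (width-0.05 bins of GC
    fraction).

    Returns ``(value, gc_fallback)`` where ``gc_fallback`` flags that the
    matching stratum was empty and the genome-wide median was used instead.
    ``stratum_medians`` may carry precomputed per-stratum medians (key
    ``floor(gc / 0.05)``) to avoid rescanning the profile per call.
    """
    if profile.gc is None:
        raise ValueError("DHBFC requires a profile with per-bin GC")
    start, end = interval
    if end <= start:
        raise ValueError("interval end must exceed start")
    if start + 1 < 1 or end > profile.seq_length:
        raise ValueError(f"interval {interval} outside profile")
    i0 = profile.bin_index(start + 1)
    i1 = profile.bin_index(end) + 1
    inside = profile.depth[i0:i1]
    interval_gc = float(np.mean(profile.gc[i0:i1]))
    stratum = int(interval_gc / GC_STRATUM_WIDTH)
    if stratum_medians is not None:
        med = stratum_medians.get(stratum)
        fallback = med is None
        if fallback:
            med = _median(profile.depth)
    else:
        strata = (profile.gc / GC_STRATUM_WIDTH).astype(int)
        mask = strata == stratum
        fallback = not mask.any()
        med = _median(profile.depth[mask]) if not fallback else _median(profile.depth)
    if med == 0:
        return math.inf, fallback
    return _median(inside) / med, fallback


def gc_stratum_medians(profile: DepthProfile) -> dict[int, float]:
    """Precompute per-GC-stratum depth medians for :func:`compute_dhbfc`."""
    if profile.gc is None:
        raise ValueError("profile carries no GC track")
    strata = (profile.gc / GC_STRATUM_WIDTH).astype(int)
    return {int(s): _median(profile.depth[strata == s])
            for s in np.unique(strata)}


# ---------------------------------------------------------------------------
# Depth-correlation QC
# ---------------------------------------------------------------------------

def depth_qc_correlation(records: Sequence[SVRecord], pedigree: Pedigree,
                         mean_depths: Mapping[str, float],
                         mad_factor: float = 3.0):
    """Per line and SV type: Pearson r between per-sample mean depth and
    per-sample carrier call count, plus outlier flags.

    A sample is flagged when its per-type call count exceeds
    ``median + mad_factor * MAD`` within its line (an excess of candidate
    calls of one type is a known failure signature of poor libraries).
    Returns ``(correlations, flags)`` as DataFrames; lines with fewer than
    3 samples are skipped and zero-variance inputs are reported with r NaN.
    """
    import pandas as pd

    svtypes = [SVType.DEL, SVType.DUP, SVType.INV, SVType.BND]
    counts: dict[str, dict[SVType, int]] = {
        sid: {t: 0 for t in svtypes} for sid in pedigree.samples}
    for rec in records:
        for sid, ev in rec.evidence.items():
            if sid in counts and ev.genotype in (Genotype.het, Genotype.hom_alt):
                counts[sid][rec.svtype] += 1

    lines: dict[str, list[str]] = {}
    for sid in pedigree.samples:
        lines.setdefault(pedigree.line_of(sid), []).append(sid)

    corr_rows, flag_rows = [], []
    for line, sids in sorted(lines.items()):
        sids = [s for s in sids if s in mean_depths]
        if len(sids) < 3:
            continue
        depths = np.array([mean_depths[s] for s in sids], dtype=float)
        for svt in svtypes:
            c = np.array([counts[s][svt] for s in sids], dtype=float)
            if np.std(depths) == 0 or np.std(c) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(depths, c)
            corr_rows.append({"line": line, "svtype": svt.value,
                              "n": len(sids), "r": r, "p": p})
            med = float(np.median(c))
            mad = float(np.median(np.abs(c - med)))
            cut = med + mad_factor * mad
            for s, cc in zip(sids, c):
                if mad > 0 and cc > cut:
                    flag_rows.append({"line": line, "svtype": svt.value,
                                      "sample": s, "count": int(cc),
                                      "cutoff": cut})
    return (pd.DataFrame(corr_rows, columns=["line", "svtype", "n", "r", "p"]),
            pd.DataFrame(flag_rows,
                         columns=["line", "svtype", "sample", "count", "cutoff"]))


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(records: Sequence[SVRecord], pedigree: Pedigree,
                thresholds: Thresholds = Thresholds(),
                ) -> tuple[list[CandidateDnSV], list[CandidateDnSV]]:
    """Run Mendelian screen -> GQ sum -> AF cap -> type filter -> uniqueness.

    Returns ``(survivors, rejected)``; every rejected candidate carries the
    trace naming the failed checks.  Because each stage is a pure predicate
    of the candidate, the survivor set is order-independent; this order is
    chosen for trace readability.
    """
    sample_ids = list(pedigree.samples)
    candidates = mendelian_candidates(records, pedigree)
    for cand in candidates:
        trio_gq_filter(cand, thresholds)
        af_filter(cand, sample_ids, thresholds)
        type_specific_filter(cand, thresholds)
    passing = [c for c in candidates if c.status == "candidate"]
    survivors = uniqueness_filter(passing)
    surviving_ids = {id(c) for c in survivors}
    rejected = [c for c in candidates if id(c) not in surviving_ids]
    return survivors, rejected
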