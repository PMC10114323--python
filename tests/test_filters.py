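"""Filter cascade: per-filter contracts, fold-change computation, QC, and
order-independence of the pure predicates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnsv.filters import (
    CandidateDnSV,
    Thresholds,
    af_filter,
    cohort_af,
    compute_dhbfc,
    compute_dhffc,
    depth_qc_correlation,
    gc_stratum_medians,
    mendelian_candidates,
    run_cascade,
    trio_gq_filter,
    type_specific_filter,
    uniqueness_filter,
)
from dnsv.svio import (
    DepthProfile,
    Genotype,
    Pedigree,
    SampleEvidence,
    SampleMeta,
    SVRecord,
    SVType,
    Trio,
)
from conftest import naive_cascade, random_filter_cohort

TRIO = Trio(sire="S", dam="D", proband="P")


def _cand(svtype=SVType.DEL, proband=None, sire=None, dam=None, **rec_kw):
    rec = SVRecord(id="x", chrom="chr1", start=1000,
                   end=None if svtype is SVType.BND else 2000,
                   svtype=svtype, **rec_kw)
    rec.evidence = {
        "P": proband or SampleEvidence(Genotype.het),
        "S": sire or SampleEvidence(Genotype.hom_ref),
        "D": dam or SampleEvidence(Genotype.hom_ref),
    }
    return CandidateDnSV(record=rec, trio=TRIO)


# -- trio GQ ---------------------------------------------------------------

@pytest.mark.parametrize("gqs,expected", [
    ((50, 40, 35), True),     # 125 > 120
    ((40, 40, 40), False),    # 120 is not strictly greater
    ((100, 15, 10), True),    # 125
])
def test_trio_gq_strictly_greater(gqs, expected):
    cand = _cand(proband=SampleEvidence(Genotype.het, gq=gqs[2]),
                 sire=SampleEvidence(Genotype.hom_ref, gq=gqs[0]),
                 dam=SampleEvidence(Genotype.hom_ref, gq=gqs[1]))
    assert trio_gq_filter(cand) is expected


def test_trio_gq_missing_fails():
    cand = _cand(proband=SampleEvidence(Genotype.het, gq=None))
    assert trio_gq_filter(cand) is False
    assert "gq_sum" in cand.trace.failed_names


@given(st.tuples(st.integers(0, 99), st.integers(0, 99), st.integers(0, 99)))
@settings(max_examples=200, derandomize=True)
def test_trio_gq_matches_sum_oracle(gqs):
    cand = _cand(proband=SampleEvidence(Genotype.het, gq=gqs[2]),
                 sire=SampleEvidence(Genotype.hom_ref, gq=gqs[0]),
                 dam=SampleEvidence(Genotype.hom_ref, gq=gqs[1]))
    assert trio_gq_filter(cand) is (gqs[0] + gqs[1] + gqs[2] > 120)


# -- allele frequency ------------------------------------------------------

def test_cohort_af_single_het_among_111():
    rec = SVRecord(id="x", chrom="1", start=1, end=2, svtype=SVType.DEL)
    rec.evidence = {f"s{i}": SampleEvidence(Genotype.hom_ref)
                    for i in range(110)}
    rec.evidence["carrier"] = SampleEvidence(Genotype.het)
    assert cohort_af(rec) == pytest.approx(1 / 222)


@pytest.mark.parametrize("n_het,n_total,kept", [
    (12, 50, False),   # AF 0.12 > 0.1 -> excluded
    (10, 50, True),    # AF exactly 0.1 -> retained (strict inequality)
    (1, 50, True),
])
def test_af_boundary(n_het, n_total, kept):
    rec = SVRecord(id="x", chrom="1", start=1, end=2, svtype=SVType.DEL)
    rec.evidence = {"P": SampleEvidence(Genotype.het),
                    "S": SampleEvidence(Genotype.hom_ref),
                    "D": SampleEvidence(Genotype.hom_ref)}
    for i in range(n_het - 1):
        rec.evidence[f"c{i}"] = SampleEvidence(Genotype.het)
    while len(rec.evidence) < n_total:
        rec.evidence[f"r{len(rec.evidence)}"] = SampleEvidence(Genotype.hom_ref)
    cand = CandidateDnSV(record=rec, trio=TRIO)
    assert af_filter(cand) is kept


def test_cohort_af_no_genotypes_is_error():
    rec = SVRecord(id="x", chrom="1", start=1, end=2, svtype=SVType.DEL)
    rec.evidence = {"a": SampleEvidence(Genotype.missing)}
    with pytest.raises(ValueError):
        cohort_af(rec)


# -- Mendelian screen ------------------------------------------------------

def _screen_cohort(unrelated_gt=Genotype.hom_ref, proband_gt=Genotype.het,
                   parent_gt=Genotype.hom_ref):
    ped = Pedigree()
    for sid in ("S", "D", "P", "US", "UD", "UP"):
        ped.samples[sid] = SampleMeta()
    ped.trios = [Trio("S", "D", "P"), Trio("US", "UD", "UP")]
    rec = SVRecord(id="x", chrom="1", start=100, end=300, svtype=SVType.DEL)
    rec.evidence = {
        "P": SampleEvidence(proband_gt), "S": SampleEvidence(parent_gt),
        "D": SampleEvidence(parent_gt),
        "US": SampleEvidence(Genotype.hom_ref),
        "UD": SampleEvidence(Genotype.hom_ref),
        "UP": SampleEvidence(unrelated_gt),
    }
    return [rec], ped


def test_mendelian_candidate_found():
    cands = mendelian_candidates(*_screen_cohort())
    assert [(c.record.id, c.trio.proband) for c in cands] == [("x", "P")]


def test_mendelian_proband_hom_ref_not_candidate():
    assert mendelian_candidates(
        *_screen_cohort(proband_gt=Genotype.hom_ref)) == []


def test_mendelian_unrelated_carrier_disqualifies():
    assert mendelian_candidates(
        *_screen_cohort(unrelated_gt=Genotype.het)) == []


def test_mendelian_missing_parent_disqualifies():
    assert mendelian_candidates(
        *_screen_cohort(parent_gt=Genotype.missing)) == []


def test_mendelian_missing_unrelated_is_noncarrier():
    cands = mendelian_candidates(
        *_screen_cohort(unrelated_gt=Genotype.missing))
    assert len(cands) == 1


# -- type-specific filter --------------------------------------------------

def _passes(cand):
    type_specific_filter(cand)
    return cand.status == "candidate"


def test_del_filter_pass_case():
    cand = _cand(SVType.DEL,
                 proband=SampleEvidence(Genotype.het, ab=0.4, su=10, dhffc=0.6),
                 sire=SampleEvidence(Genotype.hom_ref, ab=0.0, su=0, dhffc=0.95),
                 dam=SampleEvidence(Genotype.hom_ref, ab=0.0, su=0, dhffc=0.93))
    assert _passes(cand)


def test_dup_dhbfc_boundary_fails():
    cand = _cand(SVType.DUP,
                 proband=SampleEvidence(Genotype.het, ab=0.3, su=8, dhbfc=1.1),
                 sire=SampleEvidence(Genotype.hom_ref, ab=0.0, su=0, dhbfc=1.0),
                 dam=SampleEvidence(Genotype.hom_ref, ab=0.0, su=0, dhbfc=1.0))
    assert not _passes(cand)
    assert "proband_dhbfc" in cand.trace.failed_names


@pytest.mark.parametrize("su,expected", [(5, True), (4, False)])
def test_inv_read_minimum(su, expected):
    cand = _cand(SVType.INV,
                 proband=SampleEvidence(Genotype.het, ab=0.25, su=su),
                 sire=SampleEvidence(Genotype.hom_ref, ab=0.05, su=1),
                 dam=SampleEvidence(Genotype.hom_ref, ab=0.05, su=1))
    assert _passes(cand) is expected


def test_parent_su_each_parent_individually():
    cand = _cand(SVType.INV,
                 proband=SampleEvidence(Genotype.het, ab=0.3, su=9),
                 sire=SampleEvidence(Genotype.hom_ref, ab=0.0, su=4),
                 dam=SampleEvidence(Genotype.hom_ref, ab=0.0, su=0))
    assert not _passes(cand)
    assert "sire_su" in cand.trace.failed_names


def test_bnd_rejected_by_type_filter():
    with pytest.raises(ValueError):
        type_specific_filter(_cand(SVType.BND))


def test_missing_evidence_fails_conservatively():
    cand = _cand(SVType.DEL, proband=SampleEvidence(Genotype.het))
    assert not _passes(cand)


# -- uniqueness ------------------------------------------------------------

def _site_candidate(proband, start=500):
    rec = SVRecord(id=f"sv_{start}_{proband}", chrom="chr2", start=start,
                   end=start + 800, svtype=SVType.INV)
    rec.evidence = {proband: SampleEvidence(Genotype.het)}
    return CandidateDnSV(record=rec, trio=Trio(sire=f"{proband}s",
                                               dam=f"{proband}d",
                                               proband=proband))


def test_uniqueness_removes_recurrent_site():
    cands = [_site_candidate(f"P{i}") for i in range(6)]
    assert uniqueness_filter(cands) == []


def test_uniqueness_keeps_singleton():
    cands = [_site_candidate("P1"), _site_candidate("P2", start=9000)]
    assert len(uniqueness_filter(cands)) == 2


def test_uniqueness_matches_count_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        starts = rng.integers(0, 5, size=30) * 1000 + 100
        probands = [f"P{i}" for i in rng.integers(0, 8, size=30)]
        seen = set()
        cands = []
        for s, p in zip(starts, probands):
            if (s, p) in seen:
                continue
            seen.add((s, p))
            cands.append(_site_candidate(p, start=int(s)))
        kept = {(c.record.site_key, c.trio.proband)
                for c in uniqueness_filter(cands)}
        counts = {}
        for c in cands:
            counts.setdefault(c.record.site_key, set()).add(c.trio.proband)
        expected = {(c.record.site_key, c.trio.proband) for c in cands
                    if len(counts[c.record.site_key]) == 1}
        assert kept == expected


# -- depth fold-changes ----------------------------------------------------

def _flat_profile(depth=30.0, n_bins=500, bin_size=100, gc=None):
    return DepthProfile(chrom="chr1", bin_size=bin_size,
                        depth=np.full(n_bins, depth), gc=gc)


def test_dhffc_identity_and_halving():
    prof = _flat_profile()
    assert compute_dhffc(prof, (20_000, 22_000)) == pytest.approx(1.0)
    prof2 = _flat_profile()
    prof2.depth[200:220] = 15.0   # bases 20001..22000
    assert compute_dhffc(prof2, (20_000, 22_000)) == pytest.approx(0.5)


def test_dhffc_zero_flank_is_inf():
    prof = _flat_profile(depth=0.0)
    prof.depth[200:220] = 10.0
    assert math.isinf(compute_dhffc(prof, (20_000, 22_000)))


def test_dhffc_outside_profile_errors():
    prof = _flat_profile(n_bins=50)
    with pytest.raises(ValueError):
        compute_dhffc(prof, (100, 600))     # left flank would be < position 1


def test_dhffc_matches_sorted_median_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        prof = DepthProfile(chrom="c", bin_size=100,
                            depth=rng.integers(5, 60, size=400).astype(float))
        start = int(rng.integers(3_000, 25_000))
        end = start + int(rng.integers(500, 4_000))

        def med(vals):
            vals = sorted(vals)
            n = len(vals)
            return (vals[n // 2] if n % 2 else
                    (vals[n // 2 - 1] + vals[n // 2]) / 2)

        i0, i1 = start // 100, (end - 1) // 100
        inside = list(prof.depth[i0:i1 + 1])
        lo, hi = start + 1 - 1000, end + 1000
        left = list(prof.depth[(lo - 1) // 100:(start - 1) // 100 + 1])
        right = list(prof.depth[end // 100:(hi - 1) // 100 + 1])
        expected = med(inside) / med(left + right)
        assert compute_dhffc(prof, (start, end)) == pytest.approx(
            expected, abs=1e-12)


def test_dhbfc_uniform_and_ratio():
    gc = np.full(500, 0.5)
    prof = _flat_profile(gc=gc)
    val, fb = compute_dhbfc(prof, (20_000, 22_000))
    assert val == pytest.approx(1.0) and not fb
    prof2 = _flat_profile(gc=gc)
    prof2.depth[200:220] = 45.0
    val2, _ = compute_dhbfc(prof2, (20_000, 22_000))
    assert val2 == pytest.approx(1.5)


def test_dhbfc_matches_stratified_oracle():
    rng = np.random.default_rng(9)
    for _ in range(15):
        gc = rng.uniform(0.2, 0.8, size=300)
        depth = rng.integers(10, 50, size=300).astype(float)
        prof = DepthProfile(chrom="c", bin_size=100, depth=depth, gc=gc)
        start = int(rng.integers(2_000, 20_000))
        end = start + 1_500
        i0, i1 = start // 100, (end - 1) // 100
        stratum = int(np.mean(gc[i0:i1 + 1]) / 0.05)
        mask = (gc / 0.05).astype(int) == stratum
        expected = np.median(depth[i0:i1 + 1]) / np.median(depth[mask])
        got, fb = compute_dhbfc(prof, (start, end))
        assert not fb
        assert got == pytest.approx(expected, abs=1e-12)
        cache = gc_stratum_medians(prof)
        got2, _ = compute_dhbfc(prof, (start, end), cache)
        assert got2 == pytest.approx(expected, abs=1e-12)


def test_dhbfc_empty_stratum_falls_back():
    gc = np.full(300, 0.5)
    gc[100:120] = 0.95
    depth = np.full(300, 30.0)
    depth[100:120] = 60.0
    prof = DepthProfile(chrom="c", bin_size=100, depth=depth, gc=gc)
    # drop the interval's own stratum from the cache to force the
    # genome-wide fallback
    stratum = int(np.mean(gc[100:120]) / 0.05)
    cache = {s: m for s, m in gc_stratum_medians(prof).items() if s != stratum}
    val, fb = compute_dhbfc(prof, (10_000, 12_000), cache)
    assert fb
    assert val == pytest.approx(60.0 / np.median(depth))


# -- QC --------------------------------------------------------------------

def _qc_cohort(counts, depths):
    ped = Pedigree()
    for i in range(len(counts)):
        ped.samples[f"s{i}"] = SampleMeta(line="line1")
    records = []
    for i, c in enumerate(counts):
        for j in range(c):
            rid = f"r{i}_{j}"
            rec = SVRecord(id=rid, chrom="1", start=100 + j, end=200 + j,
                           svtype=SVType.DUP)
            rec.evidence = {f"s{i}": SampleEvidence(Genotype.het)}
            records.append(rec)
    mean_depths = {f"s{i}": d for i, d in enumerate(depths)}
    return records, ped, mean_depths


def test_qc_proportional_counts_give_r_one():
    depths = [20, 25, 30, 35, 40]
    counts = [2 * d for d in depths]
    corr, _ = depth_qc_correlation(*_qc_cohort(counts, depths))
    row = corr[corr.svtype == "DUP"].iloc[0]
    assert row.r == pytest.approx(1.0)


def test_qc_outlier_flagged():
    counts = [5, 6, 5, 6, 60]
    corr, flags = depth_qc_correlation(*_qc_cohort(counts, [30] * 5))
    assert "s4" in set(flags["sample"])
    row = corr[corr.svtype == "DUP"].iloc[0]
    assert math.isnan(row.r)      # zero depth variance -> undefined


# -- cascade properties ----------------------------------------------------

def test_cascade_order_independent():
    """Applying the pure per-candidate predicates in any order yields the
    same survivor set."""
    import itertools
    rng = np.random.default_rng(21)
    records, ped = random_filter_cohort(rng, 60)
    samples = list(ped.samples)
    base = {(c.record.id, c.trio.proband)
            for c in _apply(records, ped, ("gq", "af", "type"))}
    for order in itertools.permutations(("gq", "af", "type")):
        got = {(c.record.id, c.trio.proband)
               for c in _apply(records, ped, order)}
        assert got == base


def _apply(records, ped, order):
    thr = Thresholds()
    samples = list(ped.samples)
    cands = mendelian_candidates(records, ped)
    for cand in cands:
        for step in order:
            if step == "gq":
                trio_gq_filter(cand, thr)
            elif step == "af":
                af_filter(cand, samples, thr)
            else:
                type_specific_filter(cand, thr)
    return uniqueness_filter([c for c in cands if c.status == "candidate"])


def test_cascade_monotone_in_thresholds():
    """Tightening any threshold never enlarges the survivor set."""
    rng = np.random.default_rng(31)
    records, ped = random_filter_cohort(rng, 200)
    base = {(c.record.id, c.trio.proband)
            for c in run_cascade(records, ped)[0]}
    tighter = [
        Thresholds(gq_sum=150), Thresholds(af_max=0.05),
        Thresholds(del_dhffc=0.7), Thresholds(dup_dhbfc=1.2),
        Thresholds(inv_ab=0.3), Thresholds(parent_su_max=1),
        Thresholds(del_su=5, dup_su=5, inv_su=7),
    ]
    for thr in tighter:
        got = {(c.record.id, c.trio.proband)
               for c in run_cascade(records, ped, thr)[0]}
        assert got <= base, thr


def test_cascade_matches_naive_oracle_small():
    rng = np.random.default_rng(41)
    records, ped = random_filter_cohort(rng, 50)
    got = {(c.record.id, c.trio.proband)
           for c in run_cascade(records, ped)[0]}
    assert got == naive_cascade(records, ped)
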