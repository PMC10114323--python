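"""Characterisation: phasing rules, homology classes, clustering geometry,
mosaic arithmetic, Wilson interval, transmission."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnsv.characterise import (
    MATERNAL,
    MICRO_HOM,
    NON_HOM,
    PATERNAL,
    UNKNOWN,
    UNRESOLVED,
    assign_parent_of_origin,
    check_transmission,
    classify_mechanism,
    cluster_dnms,
    estimate_rate,
    genic_context,
    junction_homology,
    mosaic_fraction,
    transmission_probability,
)
from dnsv.svio import (
    Genotype,
    Pedigree,
    SampleEvidence,
    SampleMeta,
    SmallVariant,
    SVRecord,
    SVType,
    Trio,
)

TRIO = Trio(sire="S", dam="D", proband="P")


def _sv(svtype=SVType.DEL, chrom="chr1", start=1_000, end=3_000, id="sv"):
    return SVRecord(id=id, chrom=chrom, start=start, end=end, svtype=svtype)


def _snv(pos, gts, ads=None, chrom="chr1"):
    snv = SmallVariant(chrom=chrom, pos=pos, ref="A", alt="G")
    snv.genotypes = {k: v for k, v in gts.items()}
    snv.allele_depths = dict(ads or {})
    return snv


# -- parent of origin ------------------------------------------------------

def test_dup_two_to_one_excess_from_sire_is_paternal():
    """A het SNP at a 2:1 read ratio whose over-represented allele must come
    from the father phases the duplication paternally."""
    dup = _sv(SVType.DUP)
    snv = _snv(2_000,
               {"P": Genotype.het, "S": Genotype.hom_alt, "D": Genotype.het},
               {"P": (15, 30)})   # alt over-represented; sire is hom alt
    assert assign_parent_of_origin(dup, [snv], TRIO) == PATERNAL


def test_dup_excess_allele_from_het_parent():
    dup = _sv(SVType.DUP)
    snv = _snv(2_000,
               {"P": Genotype.het, "S": Genotype.hom_ref, "D": Genotype.het},
               {"P": (15, 30)})   # alt over-represented; sire cannot donate it
    assert assign_parent_of_origin(dup, [snv], TRIO) == MATERNAL


def test_del_absent_allele_names_the_origin_parent():
    """Proband looks homozygous reference although the dam is homozygous
    alternate: the maternal haplotype is the deleted one."""
    dele = _sv(SVType.DEL)
    snv = _snv(1_500,
               {"P": Genotype.hom_ref, "S": Genotype.hom_ref,
                "D": Genotype.hom_alt},
               {"P": (22, 0)})
    assert assign_parent_of_origin(dele, [snv], TRIO) == MATERNAL


def test_no_informative_snps_is_unknown():
    assert assign_parent_of_origin(_sv(), [], TRIO) == UNKNOWN
    outside = _snv(9_999, {"P": Genotype.hom_ref, "D": Genotype.hom_alt},
                   {"P": (22, 0)})
    assert assign_parent_of_origin(_sv(), [outside], TRIO) == UNKNOWN


def test_conflicting_snps_are_unknown():
    dele = _sv(SVType.DEL)
    a = _snv(1_200, {"P": Genotype.hom_ref, "S": Genotype.hom_ref,
                     "D": Genotype.hom_alt}, {"P": (20, 0)})
    b = _snv(1_900, {"P": Genotype.hom_ref, "S": Genotype.hom_alt,
                     "D": Genotype.hom_ref}, {"P": (20, 0)})
    assert assign_parent_of_origin(dele, [a, b], TRIO) == UNKNOWN


def test_out_of_tolerance_ratio_is_not_informative():
    dup = _sv(SVType.DUP)
    snv = _snv(2_000,
               {"P": Genotype.het, "S": Genotype.hom_alt, "D": Genotype.het},
               {"P": (22, 23)})   # balanced het, no duplication signal
    assert assign_parent_of_origin(dup, [snv], TRIO) == UNKNOWN


# -- junction homology -----------------------------------------------------

def test_planted_five_base_homology_recovered():
    rng = np.random.default_rng(12)
    from dnsv.simulate import plant_junction
    ref = np.array(list("ACGT"))[rng.integers(0, 4, size=10_000)].copy()
    sv = _sv(SVType.DEL, start=4_000, end=7_000)
    plant_junction(ref, sv, 5, rng=rng)
    assert junction_homology({"chr1": "".join(ref)}, sv) == 5


def test_engineered_mismatch_flanks_have_zero_homology():
    seq = "A" * 4_000 + "C" + "A" * 2_998 + "G" + "T" * 3_001
    # breakpoints at 4000 (preceded by A, followed by C) and 7000
    # (preceded by G, followed by T): no shared suffix or prefix
    sv = _sv(SVType.DEL, start=4_000, end=7_000)
    assert junction_homology({"chr1": seq}, sv) == 0


def test_short_junction_is_unresolved():
    sv = _sv(SVType.DEL, start=4_000, end=7_000)
    seq = "A" * 12_000
    assert junction_homology({"chr1": seq}, sv, junction="ACGT" * 5) is None


@pytest.mark.parametrize("h,expected", [
    (0, NON_HOM), (1, NON_HOM), (2, MICRO_HOM), (4, MICRO_HOM),
    (15, MICRO_HOM), (16, UNRESOLVED), (None, UNRESOLVED),
])
def test_mechanism_classes(h, expected):
    assert classify_mechanism(h) == expected


def test_mechanism_negative_is_error():
    with pytest.raises(ValueError):
        classify_mechanism(-1)


@given(st.integers(0, 200))
@settings(max_examples=60, derandomize=True)
def test_mechanism_partitions_all_lengths(h):
    assert classify_mechanism(h) in {NON_HOM, MICRO_HOM, UNRESOLVED}


# -- clustering ------------------------------------------------------------

def _cluster_members():
    return [
        _sv(SVType.DUP, "1", 2_940_197, 2_940_384, id="dup187"),
        _sv(SVType.DEL, "1", 2_940_383, 2_940_394, id="del11"),
    ]


def test_cluster_span_of_adjacent_pair():
    clusters = cluster_dnms(_cluster_members(), window_bp=50_000)
    assert len(clusters) == 1
    assert clusters[0].span == 197
    assert clusters[0].count == 2


def test_cluster_component_size_sum():
    members = [
        _sv(SVType.DEL, "1", 95_207_720, 95_210_792, id="a"),
        _sv(SVType.DUP, "1", 95_210_182, 95_213_638, id="b"),
        _sv(SVType.DUP, "1", 95_213_834, 95_214_842, id="c"),
        _sv(SVType.DUP, "1", 95_214_800, 95_232_460, id="d"),
    ]
    clusters = cluster_dnms(members, window_bp=50_000)
    assert len(clusters) == 1
    assert clusters[0].size_sum == 25_196
    assert clusters[0].span < clusters[0].size_sum  # members overlap


def test_different_chromosomes_never_cluster():
    a = _sv(SVType.DEL, "1", 100, 300, id="a")
    b = _sv(SVType.DEL, "2", 100, 300, id="b")
    clusters = cluster_dnms([a, b], window_bp=10_000)
    assert len(clusters) == 2 and all(c.count == 1 for c in clusters)


def test_clustering_invariant_to_input_order():
    rng = np.random.default_rng(5)
    members = [_sv(SVType.DEL, "3", int(s), int(s) + 200, id=f"m{i}")
               for i, s in enumerate(rng.integers(1_000, 500_000, size=25))]
    base = cluster_dnms(members, window_bp=20_000)
    for _ in range(5):
        perm = list(members)
        rng.shuffle(perm)
        got = cluster_dnms(perm, window_bp=20_000)
        assert [[m.id for m in c.members] for c in got] == \
            [[m.id for m in c.members] for c in base]


# -- mosaic ----------------------------------------------------------------

def test_mosaic_two_to_one_ratio():
    d, zyg = mosaic_fraction([20], [10])
    assert d == pytest.approx(0.25)
    assert zyg == "mosaic"


def test_hemizygous_signal_is_germline():
    d, zyg = mosaic_fraction([30], [0])
    assert d == pytest.approx(0.5)
    assert zyg == "germline"


def test_balanced_ratio_no_deletion_signal():
    d, _ = mosaic_fraction([15], [15])
    assert d == pytest.approx(0.0)


def test_three_to_one_ratio():
    d, _ = mosaic_fraction([30], [10])
    assert d == pytest.approx((1 - 1 / 3) / 2)


@given(st.integers(0, 100), st.integers(1, 100))
@settings(max_examples=80, derandomize=True)
def test_mosaic_fraction_monotone_decreasing_in_ratio(minor, major):
    if minor > major:
        minor, major = major, minor
    d, _ = mosaic_fraction([major], [minor])
    r = minor / major
    assert d == pytest.approx((1 - r) / 2)
    assert 0.0 <= d <= 0.5


# -- rate ------------------------------------------------------------------

def test_rate_worked_example():
    est = estimate_rate(4, 37)
    assert round(est.rate, 3) == 0.108
    assert est.ci_low <= est.rate <= est.ci_high


def test_rate_zero_count():
    est = estimate_rate(0, 37)
    assert est.rate == 0.0 and est.ci_low == 0.0


def test_rate_invalid_inputs():
    with pytest.raises(ValueError):
        estimate_rate(1, 0)
    with pytest.raises(ValueError):
        estimate_rate(5, 4)


def test_wilson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint
    for k, n in [(4, 37), (0, 37), (37, 37), (10, 100), (1, 9)]:
        est = estimate_rate(k, n)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert est.ci_low == pytest.approx(lo, abs=1e-9)
        assert est.ci_high == pytest.approx(hi, abs=1e-9)


@given(st.integers(0, 50), st.integers(1, 50))
@settings(max_examples=100, derandomize=True)
def test_wilson_contains_point_estimate(k, n):
    if k > n:
        k = n
    est = estimate_rate(k, n)
    assert est.ci_low <= est.rate <= est.ci_high
    assert est.ci_low >= 0.0


# -- transmission ----------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(0, 0.0), (4, 0.9375),
                                        (10, 0.9990234375)])
def test_transmission_probability(n, expected):
    assert transmission_probability(n) == pytest.approx(expected)


def _transmission_cohort(offspring_gt):
    ped = Pedigree()
    for sid in ("S", "D", "P", "K1"):
        ped.samples[sid] = SampleMeta()
    ped.trios = [TRIO]
    ped.offspring_links = {"P": ["K1"]}
    rec = _sv()
    rec.evidence = {"P": SampleEvidence(Genotype.het),
                    "K1": SampleEvidence(offspring_gt)}
    return rec, ped


def test_transmission_validated():
    rec, ped = _transmission_cohort(Genotype.het)
    assert check_transmission(rec, ped) == "validated"


def test_transmission_not_observed():
    rec, ped = _transmission_cohort(Genotype.hom_ref)
    assert check_transmission(rec, ped) == "not_observed"


def test_transmission_no_offspring():
    rec, ped = _transmission_cohort(Genotype.het)
    ped.offspring_links = {}
    assert check_transmission(rec, ped) == "no_offspring"


# -- genic context ---------------------------------------------------------

def _write_gff(tmp_path, n_exons=20):
    lines = ["##gff-version 3", "chrG\tt\tgene\t1000\t100000\t.\t+\t.\tID=g1"]
    # exon i occupies [1000 + 5000*i, 1000 + 5000*i + 500]
    for i in range(n_exons):
        s = 1_000 + 5_000 * i
        lines.append(f"chrG\tt\texon\t{s}\t{s + 500}\t.\t+\t.\t"
                     f"ID=g1.e{i};Parent=g1")
    path = tmp_path / "genes.gff3"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_intronic_with_ordinal(tmp_path):
    gff = _write_gff(tmp_path)  # 20 exons -> 19 introns
    sv = _sv(SVType.DEL, "chrG", 2_000, 5_500)   # between exon 1 and exon 2
    context, genes, intron = genic_context(sv, gff)
    assert context == "intronic"
    assert genes == ["g1"]
    assert intron == "intron 1/19"


def test_exon_overlap_is_exonic(tmp_path):
    gff = _write_gff(tmp_path)
    sv = _sv(SVType.DUP, "chrG", 1_400, 2_200)   # crosses exon 1's end
    context, genes, intron = genic_context(sv, gff)
    assert context == "exonic" and intron is None


def test_outside_genes_is_intergenic(tmp_path):
    gff = _write_gff(tmp_path)
    sv = _sv(SVType.DEL, "chrG", 200_000, 201_000)
    context, genes, _ = genic_context(sv, gff)
    assert context == "intergenic" and genes == []
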