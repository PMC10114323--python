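"""Shared fixtures: the default synthetic cohort, a pipeline run over it,
and a naive single-function re-implementation of the filter cascade used as
an independent oracle."""

from __future__ import annotations

import numpy as np
import pytest

from dnsv.filters import Thresholds
from dnsv.pipeline import run_pipeline
from dnsv.simulate import SimConfig, simulate_cohort
from dnsv.svio import Genotype, Pedigree, SampleEvidence, SampleMeta, SVRecord, SVType, Trio


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimConfig())


@pytest.fixture(scope="session")
def pipeline_result(default_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    return run_pipeline(default_cohort, out_dir=out)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_trios_per_line=2, n_denovo=3, n_inherited=12,
                    n_false_positive=7, n_decoy_repeats=5,
                    chrom_lengths=(("chr1", 400_000), ("chr2", 400_000)),
                    seed=99)
    return simulate_cohort(cfg)


# ---------------------------------------------------------------------------
# independent cascade oracle
# ---------------------------------------------------------------------------

def naive_cascade(records, pedigree: Pedigree,
                  thr: Thresholds = Thresholds()) -> set[tuple[str, str]]:
    """Single-function re-statement of the whole cascade, written without
    the package's predicate machinery; returns {(sv_id, proband)}."""
    all_samples = set(pedigree.samples)
    passing: list[tuple] = []
    for rec in records:
        if rec.svtype is SVType.BND:
            continue
        for trio in pedigree.trios:
            p = rec.evidence.get(trio.proband)
            s = rec.evidence.get(trio.sire)
            d = rec.evidence.get(trio.dam)
            if p is None or p.genotype is not Genotype.het:
                continue
            if s is None or d is None or \
                    s.genotype is not Genotype.hom_ref or \
                    d.genotype is not Genotype.hom_ref:
                continue
            exempt = set(trio.members()) | set(
                pedigree.offspring_links.get(trio.proband, []))
            carrier_elsewhere = False
            for sid in (all_samples & set(rec.evidence)) - exempt:
                gt = rec.evidence[sid].genotype
                if gt in (Genotype.het, Genotype.hom_alt):
                    carrier_elsewhere = True
            if carrier_elsewhere:
                continue
            if any(e.gq is None for e in (p, s, d)) or \
                    not (p.gq + s.gq + d.gq > thr.gq_sum):
                continue
            alt = genotyped = 0
            for sid in pedigree.samples:
                ev = rec.evidence.get(sid)
                if ev is None or ev.genotype is Genotype.missing:
                    continue
                genotyped += 1
                alt += {Genotype.hom_ref: 0, Genotype.het: 1,
                        Genotype.hom_alt: 2}[ev.genotype]
            if genotyped == 0 or alt / (2 * genotyped) > thr.af_max:
                continue
            ok = True
            if rec.svtype is SVType.DEL:
                ok &= p.dhffc is not None and p.dhffc < thr.del_dhffc
                ok &= (s.dhffc is not None and d.dhffc is not None
                       and (s.dhffc + d.dhffc) / 2 > thr.del_parent_dhffc)
                ok &= p.ab is not None and p.ab > thr.del_ab
                ok &= p.su is not None and p.su >= thr.del_su
            elif rec.svtype is SVType.DUP:
                ok &= p.dhbfc is not None and p.dhbfc > thr.dup_dhbfc
                ok &= (s.dhbfc is not None and d.dhbfc is not None
                       and (s.dhbfc + d.dhbfc) / 2 < thr.dup_parent_dhbfc)
                ok &= p.ab is not None and p.ab > thr.dup_ab
                ok &= p.su is not None and p.su >= thr.dup_su
            else:
                ok &= p.ab is not None and p.ab > thr.inv_ab
                ok &= p.su is not None and p.su >= thr.inv_su
            for parent in (s, d):
                ok &= parent.ab is not None and parent.ab < thr.parent_ab_max
                ok &= parent.su is not None and parent.su <= thr.parent_su_max
            if ok:
                passing.append((rec, trio))
    site_probands: dict[tuple, set[str]] = {}
    for rec, trio in passing:
        site_probands.setdefault(rec.site_key, set()).add(trio.proband)
    return {(rec.id, trio.proband) for rec, trio in passing
            if len(site_probands[rec.site_key]) == 1}


def random_filter_cohort(rng: np.random.Generator, n_records: int,
                         n_trios: int = 6):
    """Random records with evidence values clustered around the cascade
    thresholds, for oracle-equivalence testing."""
    ped = Pedigree()
    for ti in range(n_trios):
        for role in "SDP":
            ped.samples[f"T{ti}{role}"] = SampleMeta(line="line1")
        ped.trios.append(Trio(sire=f"T{ti}S", dam=f"T{ti}D",
                              proband=f"T{ti}P"))
    ped.offspring_links[ped.trios[0].proband] = []
    samples = list(ped.samples)
    svtypes = [SVType.DEL, SVType.DUP, SVType.INV, SVType.BND]
    gts = [Genotype.hom_ref, Genotype.het, Genotype.hom_alt, Genotype.missing]
    records = []
    for i in range(n_records):
        svt = svtypes[int(rng.integers(0, 4))] if rng.random() < 0.1 \
            else svtypes[int(rng.integers(0, 3))]
        start = int(rng.integers(1000, 100_000))
        rec = SVRecord(id=f"r{i}", chrom=f"chr{int(rng.integers(1, 3))}",
                       start=start,
                       end=None if svt is SVType.BND else start + int(rng.integers(60, 5000)),
                       svtype=svt)
        focus = int(rng.integers(0, n_trios))
        for si, sid in enumerate(samples):
            in_focus = sid.startswith(f"T{focus}")
            if in_focus and sid.endswith("P"):
                gt = Genotype.het if rng.random() < 0.8 else gts[int(rng.integers(0, 4))]
            elif in_focus:
                gt = Genotype.hom_ref if rng.random() < 0.8 else gts[int(rng.integers(0, 4))]
            else:
                gt = Genotype.hom_ref if rng.random() < 0.9 else gts[int(rng.integers(0, 4))]
            ev = SampleEvidence(
                genotype=gt,
                gq=None if rng.random() < 0.05 else float(rng.integers(20, 70)),
                ab=None if rng.random() < 0.05 else round(float(rng.uniform(0, 0.6)), 3),
                su=None if rng.random() < 0.05 else int(rng.integers(0, 8)),
                dhffc=None if rng.random() < 0.05 else round(float(rng.uniform(0.5, 1.1)), 3),
                dhbfc=None if rng.random() < 0.05 else round(float(rng.uniform(0.9, 1.5)), 3),
            )
            if ev.su is not None:
                ev.sr = ev.su // 2
                ev.pe = ev.su - ev.sr
            rec.evidence[sid] = ev
        records.append(rec)
    return records, ped
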