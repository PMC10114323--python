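"""End-to-end orchestration: cohort -> cascade -> review -> characterisation.

The pipeline binds the stages together and enforces the bookkeeping
invariants: every Mendelian candidate ends up exactly once in either the
confirmed set or the rejection log, and the whole run is deterministic given
the inputs (and, for simulated cohorts, the seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from dnsv.svio import Genotype, SVType, write_results
from dnsv.filters import (
    CandidateDnSV,
    Thresholds,
    depth_qc_correlation,
    run_cascade,
)
from dnsv.review import (
    HIGH_EVIDENCE,
    ReviewConfig,
    extract_breakpoint_evidence,
    review_candidate,
)
from dnsv.characterise import (
    DnSVCharacterisation,
    PhasingConfig,
    assign_parent_of_origin,
    check_transmission,
    classify_mechanism,
    cluster_dnms,
    estimate_rate,
    genic_context,
    junction_homology,
    mosaic_fraction,
)
from dnsv.simulate import SimulatedCohort


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    review: ReviewConfig = field(default_factory=ReviewConfig)
    phasing: PhasingConfig = field(default_factory=PhasingConfig)
    cluster_window_bp: int = 50_000
    confidence: float = 0.95
    germline_delta: float = 0.1


@dataclass
class PipelineResult:
    candidates: list[CandidateDnSV]
    confirmed: list[CandidateDnSV]
    rejected: list[CandidateDnSV]
    characterisations: dict[str, DnSVCharacterisation]
    clusters: list
    rate: object
    qc_correlations: pd.DataFrame
    qc_flags: pd.DataFrame

    @property
    def conserved(self) -> bool:
        """|candidates| == |confirmed| + |rejected| at the stage boundary."""
        return len(self.candidates) == len(self.confirmed) + len(self.rejected)


def run_pipeline(cohort: SimulatedCohort,
                 config: PipelineConfig | None = None,
                 gff_path: str | Path | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run cascade, review and characterisation over a (simulated) cohort.

    ``gff_path`` may point at a gene annotation; when absent the cohort's
    own annotation text is materialised next to the outputs (or skipped
    when there is nowhere to write it).
    """
    if config is None:
        config = PipelineConfig()
    records = [r for r in cohort.records if not r.excluded_from_analysis]

    survivors, cascade_rejected = run_cascade(records, cohort.pedigree,
                                              config.thresholds)

    confirmed: list[CandidateDnSV] = []
    review_rejected: list[CandidateDnSV] = []
    for cand in survivors:
        proband = cand.trio.proband
        profile = cohort.depth_profiles.get(proband, {}).get(cand.record.chrom)
        evidence = extract_breakpoint_evidence(
            cand, cohort.read_support, profile, config.review)
        verdict, _rules = review_candidate(cand, evidence, cohort.repeats,
                                           config.review)
        (confirmed if verdict == HIGH_EVIDENCE else review_rejected).append(cand)

    # characterisation of confirmed dnSVs
    if gff_path is None and out_dir is not None and cohort.gff_text:
        gff_path = Path(out_dir) / "genes.gff3"
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        Path(gff_path).write_text(cohort.gff_text)

    characterisations: dict[str, DnSVCharacterisation] = {}
    for cand in confirmed:
        rec, trio = cand.record, cand.trio
        ch = DnSVCharacterisation(sv_id=rec.id)
        ch.parent_of_origin = assign_parent_of_origin(
            rec, cohort.snvs, trio, config.phasing)
        hlen = junction_homology(cohort.reference, rec)
        ch.homology_len = hlen
        ch.mechanism = classify_mechanism(hlen)
        if gff_path is not None:
            ch.genic_context, ch.gene_ids, ch.intron = genic_context(
                rec, str(gff_path))
        if rec.svtype is SVType.DEL:
            het_snps = [v for v in cohort.snvs
                        if v.chrom == rec.chrom
                        and rec.start < v.pos <= (rec.end or 0)
                        and v.genotypes.get(trio.proband) is Genotype.het
                        and trio.proband in v.allele_depths]
            if het_snps:
                refs = [v.allele_depths[trio.proband][0] for v in het_snps]
                alts = [v.allele_depths[trio.proband][1] for v in het_snps]
                ch.deleted_fraction, ch.zygosity = mosaic_fraction(
                    refs, alts, config.germline_delta)
        ch.transmission = check_transmission(rec, cohort.pedigree,
                                             proband=trio.proband)
        characterisations[rec.id] = ch

    germline = [c for c in confirmed
                if characterisations[c.record.id].zygosity == "germline"]
    clusters = cluster_dnms([c.record for c in germline],
                            config.cluster_window_bp)
    for cl in clusters:
        if cl.count > 1:
            for member in cl.members:
                characterisations[member.id].cluster_id = cl.cluster_id
    n_trios = len(cohort.pedigree.trios)
    k_events = len(clusters)  # a mutation cluster counts as one event
    rate = estimate_rate(k_events, n_trios) if n_trios else None

    qc_corr, qc_flags = depth_qc_correlation(
        cohort.records, cohort.pedigree, cohort.mean_depths)

    result = PipelineResult(
        candidates=survivors + cascade_rejected,
        confirmed=confirmed,
        rejected=cascade_rejected + review_rejected,
        characterisations=characterisations,
        clusters=clusters, rate=rate,
        qc_correlations=qc_corr, qc_flags=qc_flags)

    if out_dir is not None:
        write_run_outputs(result, out_dir)
    return result


def write_run_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(result.confirmed + result.rejected,
                  result.characterisations, out, rate=result.rate)
    with open(out / "rejections.log", "w") as fh:
        for cand in result.rejected:
            reason = (";".join(cand.trace.failed_names)
                      or f"review:{','.join(map(str, cand.violated_rules))}")
            fh.write(f"{cand.record.id}\t{cand.trio.proband}\t{reason}\t"
                     f"{cand.trace.compact()}\n")
    result.qc_correlations.to_csv(out / "qc.tsv", sep="\t", index=False)
    result.qc_flags.to_csv(out / "qc_flags.tsv", sep="\t", index=False)
    summary = {
        "n_candidates": len(result.candidates),
        "n_confirmed": len(result.confirmed),
        "n_rejected": len(result.rejected),
        "n_clusters": len(result.clusters),
        "rate": None if result.rate is None else {
            "count": result.rate.count, "trios": result.rate.trios,
            "rate": result.rate.rate, "ci_low": result.rate.ci_low,
            "ci_high": result.rate.ci_high},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
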