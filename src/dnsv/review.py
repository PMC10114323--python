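"""Rule-based review of breakpoint-local evidence.

Manual inspection of candidate dnSVs in a genome browser follows a small set
of reproducible rejection criteria.  This module encodes them as pure
predicates over breakpoint-local evidence so that the review step is
automated, testable and order-free.  A candidate is called spurious when any
of the five rules fires:

1. both breakpoints overlap repeat intervals,
2. only one breakpoint has split-read or discordant-pair support,
3. fewer than three supporting reads (split + pairs) at either breakpoint,
4. the supporting-read intervals at a breakpoint are pairwise disjoint
   (mutually non-overlapping reads cannot support a single junction),
5. no coverage decrease (deletions) or increase (duplications) at both
   breakpoints.

Inversions are copy-neutral, so rule 5 is skipped for them.  The coverage
step of rule 5 is the ratio of median depth inside the SV to median depth
outside, each over a configurable window on either side of the breakpoint;
the default cutoffs reuse the cascade's fold-change thresholds as a proxy
for "clear visual" change, which has no published numeric value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from dnsv.svio import DepthProfile, SVType
from dnsv.filters import CandidateDnSV

HIGH_EVIDENCE = "high_evidence"
SPURIOUS = "spurious"


@dataclass
class BreakpointEvidence:
    """Read evidence local to one breakpoint.

    ``read_intervals`` are the 1-based inclusive spans of the supporting
    reads (split or discordant); ``coverage_step`` is the ratio of median
    depth on the SV-interior side of the breakpoint to the exterior side,
    or ``None`` when no depth profile is available.
    """

    split_reads: int = 0
    paired_reads: int = 0
    read_intervals: list[tuple[int, int]] = field(default_factory=list)
    coverage_step: float | None = None
    repeat_overlap: bool | None = None

    @property
    def support(self) -> int:
        return self.split_reads + self.paired_reads


@dataclass(frozen=True)
class ReviewConfig:
    repeat_window: int = 50       # bp around a breakpoint checked for repeats
    step_window: int = 500        # bp per side for the coverage step
    min_support: int = 3
    del_step_max: float = 0.8     # interior/exterior depth must fall below
    dup_step_min: float = 1.1     # ... or rise above, for DEL / DUP


def _overlaps_repeats(chrom: str, pos: int,
                      repeats: Mapping[str, Sequence[tuple[int, int]]] | Mapping[str, IntervalTree],
                      window: int) -> bool:
    iv = repeats.get(chrom)
    if iv is None:
        return False
    lo, hi = pos - window, pos + window
    if isinstance(iv, IntervalTree):
        return bool(iv.overlap(lo, hi + 1))
    return any(s <= hi and e >= lo for s, e in iv)


def _max_read_pileup(intervals: Sequence[tuple[int, int]]) -> int:
    """Deepest point of the supporting-read pileup at a breakpoint."""
    if not intervals:
        return 0
    events = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e + 1, -1))
    depth = best = 0
    for _, delta in sorted(events):
        depth += delta
        best = max(best, depth)
    return best


def coverage_step(profile: DepthProfile, breakpoint: int, interior: str,
                  window: int = 500,
                  interior_window: int | None = None) -> float:
    """Median depth on the SV-interior side over the exterior side of a
    breakpoint, each taken over ``window`` bp.  ``interior`` is "right" for
    a left breakpoint and "left" for a right breakpoint; ``interior_window``
    caps the interior side so short SVs are not diluted by sequence beyond
    their other breakpoint."""
    in_win = min(window, interior_window or window)
    lw = in_win if interior == "left" else window
    rw = in_win if interior == "right" else window
    left_lo = max(1, breakpoint - lw + 1)
    right_hi = min(profile.seq_length, breakpoint + rw)
    left = profile.depth[profile.bin_index(left_lo):
                         profile.bin_index(breakpoint) + 1]
    right = profile.depth[profile.bin_index(min(breakpoint + 1, right_hi)):
                          profile.bin_index(right_hi) + 1]
    inside, outside = (right, left) if interior == "right" else (left, right)
    om = float(np.median(outside)) if outside.size else 0.0
    im = float(np.median(inside)) if inside.size else 0.0
    return float("inf") if om == 0 else im / om


def extract_breakpoint_evidence(candidate: CandidateDnSV,
                                read_support: Mapping[str, dict] | None,
                                profile: DepthProfile | None,
                                config: ReviewConfig = ReviewConfig(),
                                ) -> tuple[BreakpointEvidence, BreakpointEvidence]:
    """Assemble per-breakpoint evidence from a read-support table and a
    proband depth profile.

    ``read_support`` maps sv-id to ``{"left": [(start, end, kind), ...],
    "right": [...]}`` with kind "SR" or "PE"; missing entries yield empty
    evidence (which review rule 2 then rejects, logged via the verdict).
    """
    rec = candidate.record
    entry = (read_support or {}).get(rec.id, {})

    def build(side: str, bp: int, interior: str) -> BreakpointEvidence:
        reads = entry.get(side, [])
        ev = BreakpointEvidence(
            split_reads=sum(1 for r in reads if len(r) > 2 and r[2] == "SR"),
            paired_reads=sum(1 for r in reads if len(r) > 2 and r[2] == "PE"),
            read_intervals=[(int(r[0]), int(r[1])) for r in reads],
        )
        if not reads:
            ev.split_reads = ev.paired_reads = 0
        if profile is not None and rec.svtype in (SVType.DEL, SVType.DUP):
            ev.coverage_step = coverage_step(profile, bp, interior,
                                             config.step_window,
                                             interior_window=rec.length)
        return ev

    left = build("left", rec.start, "right")
    right = build("right", rec.end or rec.start, "left")
    return left, right


def review_candidate(candidate: CandidateDnSV,
                     evidence: tuple[BreakpointEvidence, BreakpointEvidence],
                     repeats: Mapping[str, Sequence[tuple[int, int]]] | None = None,
                     config: ReviewConfig = ReviewConfig(),
                     ) -> tuple[str, list[int]]:
    """Apply the five rejection rules; returns (verdict, violated rule ids).

    The verdict is a pure function of its inputs.  The candidate's
    ``verdict`` and ``violated_rules`` fields are filled in as a convenience.
    """
    rec = candidate.record
    left, right = evidence
    violated: list[int] = []

    # rule 1: both breakpoints in repeats
    if repeats is not None:
        hits = [
            _overlaps_repeats(rec.chrom, rec.start, repeats, config.repeat_window),
            _overlaps_repeats(rec.chrom, rec.end or rec.start, repeats,
                              config.repeat_window),
        ]
        if all(hits):
            violated.append(1)

    # rule 2: support on one side only (or evidence missing for a side)
    supported = [left.support > 0, right.support > 0]
    if sum(supported) == 1:
        violated.append(2)

    # rule 3: fewer than min_support reads at either breakpoint
    if left.support < config.min_support or right.support < config.min_support:
        violated.append(3)

    # rule 4: supporting reads at a breakpoint mutually non-overlapping
    for bp_ev in (left, right):
        if len(bp_ev.read_intervals) >= 2 and _max_read_pileup(
                bp_ev.read_intervals) < 2:
            violated.append(4)
            break

    # rule 5: no coverage change in the expected direction at both breakpoints
    if rec.svtype in (SVType.DEL, SVType.DUP):
        steps = [left.coverage_step, right.coverage_step]
        if rec.svtype is SVType.DEL:
            ok = [s is not None and s <= config.del_step_max for s in steps]
        else:
            ok = [s is not None and s >= config.dup_step_min for s in steps]
        if not all(ok):
            violated.append(5)

    verdict = SPURIOUS if violated else HIGH_EVIDENCE
    candidate.verdict = verdict
    candidate.violated_rules = violated
    return verdict, violated
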