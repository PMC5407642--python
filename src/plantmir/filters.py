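"""The precursor filter cascade and family assignment.

Candidates that emerge from the inverted-repeat scan are screened on
length, base composition (GC 20-65% inclusive), energy sign, MFEI,
mature-arm placement, mature homology, and overlap with masked intervals
(repeats / other ncRNAs). Every failed filter is reported, not just the
first, so rejection reasons are auditable per candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import GenomicInterval, PrecursorRecord, ReferenceMature

#: Closed vocabulary of rejection reason codes, in cascade order.
REASON_CODES = (
    "LENGTH",
    "GC_RANGE",
    "MFE_SIGN",
    "MFEI_MIN",
    "MATURE_PLACEMENT",
    "MATURE_HOMOLOGY",
    "BLOCKLIST",
)


@dataclass(frozen=True)
class FilterThresholds:
    """Acceptance windows for the cascade; all boundaries inclusive.

    The GC window (20-65%) follows the published screen; the MFEI minimum
    defaults to 0.7, the lower edge of the range plant precursors occupy;
    the length window [60, 338] brackets the observed 68-338 nt with slack
    at the low end. Any blocklist overlap (>=1 nt) rejects.
    """

    gc_min: float = 20.0
    gc_max: float = 65.0
    mfei_min: float = 0.7
    mfe_max: float = 0.0  # MFE must be strictly below this
    max_mature_mismatches: int = 3
    length_min: int = 60
    length_max: int = 338

    def __post_init__(self) -> None:
        if self.gc_min > self.gc_max or self.length_min > self.length_max:
            raise ValueError("empty threshold window")


@dataclass
class FilterDecision:
    candidate_id: str
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.accepted == (not self.reasons)


def apply_cascade(
    candidate: PrecursorRecord,
    thresholds: FilterThresholds = FilterThresholds(),
    blocklist: list[GenomicInterval] | None = None,
) -> FilterDecision:
    """Evaluate every filter in fixed order; report all failures."""
    for attr in ("thermo", "composition"):
        if getattr(candidate, attr) is None:
            raise ValueError(f"candidate {candidate.candidate_id}: missing {attr}")
    reasons: list[str] = []
    t, comp = candidate.thermo, candidate.composition
    if not (thresholds.length_min <= candidate.length <= thresholds.length_max):
        reasons.append("LENGTH")
    if not (thresholds.gc_min <= comp.gc <= thresholds.gc_max):
        reasons.append("GC_RANGE")
    if not (t.mfe < thresholds.mfe_max):
        reasons.append("MFE_SIGN")
    if math.isnan(t.mfei) or t.mfei < thresholds.mfei_min:
        reasons.append("MFEI_MIN")
    if candidate.mature is None:
        reasons.append("MATURE_PLACEMENT")
    if (
        candidate.mature_mismatches is None
        or candidate.mature_mismatches > thresholds.max_mature_mismatches
    ):
        reasons.append("MATURE_HOMOLOGY")
    if blocklist:
        if any(candidate.interval.overlaps(b) for b in blocklist):
            reasons.append("BLOCKLIST")
    return FilterDecision(candidate.candidate_id, not reasons, reasons)


def resolve_overlaps(records: list[PrecursorRecord]) -> list[PrecursorRecord]:
    """One precursor per locus: among same-strand overlapping candidates
    keep the lowest MFE, then the longest, then the leftmost."""
    groups: dict[tuple[str, str], list[PrecursorRecord]] = {}
    for r in records:
        groups.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
    kept: list[PrecursorRecord] = []
    for key in sorted(groups):
        items = sorted(groups[key], key=lambda r: r.interval.start)
        cluster: list[PrecursorRecord] = []
        cluster_end = -1
        for r in items:
            if cluster and r.interval.start < cluster_end:
                cluster.append(r)
                cluster_end = max(cluster_end, r.interval.end)
            else:
                if cluster:
                    kept.append(_pick(cluster))
                cluster = [r]
                cluster_end = r.interval.end
        if cluster:
            kept.append(_pick(cluster))
    kept.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return kept


def _pick(cluster: list[PrecursorRecord]) -> PrecursorRecord:
    winner = min(
        cluster,
        key=lambda r: (r.thermo.mfe, -r.length, r.interval.start),
    )
    dropped = [r.candidate_id for r in cluster if r is not winner]
    if dropped:
        winner.provenance.setdefault("superseded", []).extend(dropped)
    return winner


def mismatch_count(a: str, b: str) -> int:
    """Hamming distance; sequences of unequal length are incomparable."""
    if len(a) != len(b):
        return 10**9
    return sum(1 for x, y in zip(a, b) if x != y)


def assign_family(
    mature_seq: str,
    references: list[ReferenceMature],
    max_mismatches: int = 3,
) -> str | None:
    """Family of the closest reference mature within the mismatch budget.

    Ties go to the lexicographically smallest family label. The candidate
    mature is compared on both the given orientation and as-is only: the
    seeding stage already fixed orientation.
    """
    if not references:
        raise ValueError("empty reference set")
    best: tuple[int, str] | None = None
    for ref in references:
        d = mismatch_count(mature_seq, ref.seq)
        if d > max_mismatches:
            continue
        key = (d, ref.family)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]


def name_precursors(records: list[PrecursorRecord], prefix: str = "ccp-") -> None:
    """Assign <prefix>MIR<family><letter> names in genomic order per family."""
    by_family: dict[str, list[PrecursorRecord]] = {}
    for r in records:
        by_family.setdefault(r.family or "MIRunk", []).append(r)
    for family in sorted(by_family):
        members = sorted(
            by_family[family], key=lambda r: (r.interval.chrom, r.interval.start)
        )
        for i, r in enumerate(members):
            suffix = _letters(i)
            r.name = f"{prefix}{family}{suffix}"


def _letters(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("a") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out
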