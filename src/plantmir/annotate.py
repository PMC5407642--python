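"""Genomic context of accepted precursors.

Genic/intergenic calls are strand-agnostic any-overlap tests against
gene-level features; MIR clusters chain precursors whose boundary gap is
at most 10 kb (inclusive), matching the study's clustering distance; an
antiparallel cluster holds members on both strands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core import GeneModel, GenomicInterval, PrecursorRecord


@dataclass(frozen=True)
class ClusterParams:
    max_gap: int = 10_000  # nt, inclusive

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("gap must be non-negative")


@dataclass
class MirCluster:
    members: list[str]  # precursor ids, sorted by start
    chrom: str
    span: GenomicInterval
    antiparallel: bool


def classify_genic(
    interval: GenomicInterval, genes: list[GeneModel]
) -> str:
    """'genic' iff the precursor overlaps any gene by >=1 nt."""
    for g in genes:
        if interval.overlaps(g.interval):
            return "genic"
    return "intergenic"


def cluster_precursors(
    precursors: list[PrecursorRecord],
    params: ClusterParams = ClusterParams(),
) -> list[MirCluster]:
    """Single-linkage chains per chromosome; singletons are not clusters.

    The gap between consecutive precursors (sorted by start) is measured
    next.start - previous.end; a gap of exactly ``max_gap`` still joins.
    """
    by_chrom: dict[str, list[PrecursorRecord]] = {}
    for p in precursors:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    clusters: list[MirCluster] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        chain: list[PrecursorRecord] = []
        for p in items:
            if chain and p.interval.start - chain[-1].interval.end <= params.max_gap:
                chain.append(p)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chain))
                chain = [p]
        if len(chain) >= 2:
            clusters.append(_make_cluster(chain))
    return clusters


def _make_cluster(chain: list[PrecursorRecord]) -> MirCluster:
    strands = {p.interval.strand for p in chain}
    chrom = chain[0].interval.chrom
    return MirCluster(
        members=[p.name or p.candidate_id for p in chain],
        chrom=chrom,
        span=GenomicInterval(
            chrom, chain[0].interval.start, max(p.interval.end for p in chain)
        ),
        antiparallel=(strands == {"+", "-"}),
    )


def summarize(
    precursors: list[PrecursorRecord],
    clusters: list[MirCluster] | None = None,
    genes: list[GeneModel] | None = None,
) -> dict:
    """Deterministic summary report of an accepted precursor set."""
    per_chrom = Counter(p.interval.chrom for p in precursors)
    per_family = Counter(p.family or "MIRunk" for p in precursors)
    locations = Counter()
    if genes is not None:
        for p in precursors:
            loc = p.provenance.get("location") or classify_genic(p.interval, genes)
            locations[loc] += 1
    else:
        for p in precursors:
            if p.provenance.get("location"):
                locations[p.provenance["location"]] += 1
    mature_lengths = Counter(
        p.mature.end - p.mature.start for p in precursors if p.mature
    )
    first_nt = Counter(p.mature.first_nt for p in precursors if p.mature)
    clustered_ids = set()
    antiparallel = 0
    for c in clusters or []:
        clustered_ids.update(c.members)
        antiparallel += int(c.antiparallel)
    n_first = sum(first_nt.values())
    return {
        "n_precursors": len(precursors),
        "n_families": len(per_family),
        "per_chromosome": dict(sorted(per_chrom.items())),
        "per_family": dict(sorted(per_family.items())),
        "genic": locations.get("genic", 0),
        "intergenic": locations.get("intergenic", 0),
        "n_clusters": len(clusters or []),
        "n_antiparallel_clusters": antiparallel,
        "n_clustered_precursors": len(clustered_ids),
        "mature_length_histogram": dict(sorted(mature_lengths.items())),
        "first_nt_frequencies": {
            k: v / n_first for k, v in sorted(first_nt.items())
        }
        if n_first
        else {},
    }
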