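"""End-to-end orchestration: discovery (seed -> fold-back scan -> descriptors
-> filter cascade -> genomic annotation) and the protein-side machinery run.

Every candidate that reaches the cascade carries full provenance: its
seeding reference, the inverted repeat that defined its extent, and the
filter decision with all failure reasons. A run manifest records the
configuration, seed, and folding-engine identity so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import annotate, filters, hairpin, machinery, seqio, structure
from .core import GenomeSequence, GenomicInterval, PrecursorRecord, revcomp
from .filters import FilterThresholds
from .hairpin import IRScanParams
from .annotate import ClusterParams


@dataclass
class RunConfig:
    engine: str = "auto"
    flank: int = 336
    max_seed_mismatches: int = 3
    ir_params: IRScanParams = field(default_factory=IRScanParams)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0  # echoed to the manifest; discovery itself is deterministic

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    accepted: list[PrecursorRecord]
    candidates: list[PrecursorRecord]
    decisions: list[filters.FilterDecision]
    clusters: list
    summary: dict
    manifest: dict


def _candidates_from_window(window, genome_seq, config: RunConfig):
    """One candidate per inverted repeat, seeded by its best-matching mature."""
    wseq = genome_seq[window.start : window.end]
    repeats = hairpin.scan_inverted_repeats(wseq, config.ir_params)
    out = []
    for rep in repeats:
        cand_start = window.start + rep.left_start
        cand_end = window.start + rep.right_end
        inside = [
            s
            for s in window.seeds
            if cand_start <= s.interval.start and s.interval.end <= cand_end
        ]
        if not inside:
            continue
        best = min(
            inside, key=lambda s: (s.mismatches, s.interval.strand != "+", s.ref_id)
        )
        strand = best.interval.strand
        seq = genome_seq[cand_start:cand_end]
        if strand == "-":
            seq = revcomp(seq)
            m_start = cand_end - best.interval.end
        else:
            m_start = best.interval.start - cand_start
        m_end = m_start + best.interval.length
        cand = PrecursorRecord(
            candidate_id=(
                f"cand:{window.chrom}:{cand_start}-{cand_end}:{strand}"
            ),
            seq=seq,
            interval=GenomicInterval(window.chrom, cand_start, cand_end, strand),
            mature_mismatches=best.mismatches,
            seed_ref_id=best.ref_id,
            provenance={
                "repeat_score": rep.score,
                "repeat_identity": round(rep.identity, 4),
                "seed": best.ref_id,
                "n_seeds_in_window": len(window.seeds),
            },
        )
        cand.provenance["mature_span"] = (m_start, m_end)
        out.append(cand)
    return out


def run_discovery(
    genome: list[GenomeSequence],
    references,
    genes=None,
    blocklist=None,
    config: RunConfig = RunConfig(),
) -> DiscoveryResult:
    """Run the full discovery cascade and annotate the accepted set."""
    genes = genes or []
    blocklist = blocklist or []
    engine = structure.get_engine(config.engine)
    seeds = hairpin.seed_by_homology(
        genome, references, config.max_seed_mismatches
    ) if references else []
    windows = hairpin.window_candidates(seeds, genome, config.flank) if seeds else []
    chrom_seq = {g.chrom: g.seq for g in genome}

    candidates: list[PrecursorRecord] = []
    for window in windows:
        candidates.extend(
            _candidates_from_window(window, chrom_seq[window.chrom], config)
        )

    decisions = []
    accepted = []
    for cand in candidates:
        ss, thermo, comp = structure.characterize(cand.seq, engine)
        cand.structure = ss.dotbracket
        cand.thermo = thermo
        cand.composition = comp
        m_span = cand.provenance["mature_span"]
        try:
            cand.mature = structure.place_mature(ss, m_span, cand.seq)
            cand.loop = ss.loop_interval()
        except (structure.AmbiguousHairpinError, structure.LoopOverlapError, ValueError):
            cand.mature = None
        decision = filters.apply_cascade(cand, config.thresholds, blocklist)
        decisions.append(decision)
        if decision.accepted:
            accepted.append(cand)

    accepted = filters.resolve_overlaps(accepted)
    if accepted and references:
        for rec in accepted:
            span = rec.provenance["mature_span"]
            mature_seq = rec.seq[span[0] : span[1]]
            rec.family = filters.assign_family(
                mature_seq, references, config.max_seed_mismatches
            )
        filters.name_precursors(accepted)
    for rec in accepted:
        rec.provenance["location"] = annotate.classify_genic(rec.interval, genes)
    clusters = annotate.cluster_precursors(accepted, config.cluster_params)
    summary = annotate.summarize(accepted, clusters, genes)
    manifest = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "engine": engine.name,
        "seed": config.seed,
        "n_references": len(list(references)) if references else 0,
        "n_seeds": len(seeds),
        "n_windows": len(windows),
        "n_candidates": len(candidates),
        "n_accepted": len(accepted),
    }
    return DiscoveryResult(accepted, candidates, decisions, clusters, summary, manifest)


def run_machinery(proteins, domains) -> list[machinery.CatalyticReport]:
    """Classify every protein whose family can be inferred."""
    reports = []
    for prot in proteins:
        fam = machinery.infer_family(prot.protein_id, domains, prot.seq)
        if fam == "AGO":
            reports.append(machinery.classify_ago(prot))
        elif fam == "DCL":
            reports.append(machinery.classify_dcl(prot, domains))
        elif fam == "RDR":
            reports.append(machinery.classify_rdr(prot, domains))
    return reports


def machinery_table(reports, domains=None) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "protein_id": r.protein_id,
            "family": r.family,
            "motif": r.motif,
            "positions": "-".join(
                "?" if p is None else str(p) for p in r.positions
            ),
            "evaluable": r.evaluable,
            "partial": r.partial,
            "clade": r.clade or "",
            "upstream": r.upstream or "",
        }
        if domains is not None:
            arch = machinery.classify_architecture(r.protein_id, domains, r.family)
            row["complete"] = arch.complete
            row["missing_domains"] = ";".join(
                f"{k}x{v}" for k, v in sorted(arch.missing.items())
            )
        rows.append(row)
    return pd.DataFrame(rows)


def decisions_table(decisions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate_id": d.candidate_id,
                "accepted": d.accepted,
                "reasons": ";".join(d.reasons),
            }
            for d in decisions
        ]
    )


def emit_discovery(result: DiscoveryResult, outdir: str) -> None:
    """Persist the standard report set for a discovery run."""
    os.makedirs(outdir, exist_ok=True)
    seqio.precursor_table(result.accepted).to_csv(
        os.path.join(outdir, "precursors.tsv"), sep="\t", index=False
    )
    seqio.descriptor_table(result.accepted).to_csv(
        os.path.join(outdir, "descriptors.tsv"), sep="\t", index=False
    )
    decisions_table(result.decisions).to_csv(
        os.path.join(outdir, "decisions.tsv"), sep="\t", index=False
    )
    cluster_rows = [
        {
            "chrom": c.chrom,
            "start": c.span.start,
            "end": c.span.end,
            "antiparallel": c.antiparallel,
            "members": ";".join(c.members),
        }
        for c in result.clusters
    ]
    pd.DataFrame(cluster_rows).to_csv(
        os.path.join(outdir, "clusters.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "precursors.fa"), "w") as fh:
        seqio.write_fasta(
            [(r.name or r.candidate_id, r.seq) for r in result.accepted],
            fh,
            rna=True,
        )
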