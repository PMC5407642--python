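"""Readers and writers for the pipeline's external formats.

FASTA parsing is backed by Biopython, GFF3 row parsing by gffutils, tabular
IO by pandas. Internal coordinates are 0-based half-open; GFF3 and all
report columns use 1-based inclusive coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .core import (
    DOMAIN_VOCABULARY,
    DomainAnnotation,
    GeneModel,
    GenomicInterval,
    to_dna,
    to_rna,
)

_ALPHABETS = {
    "dna": set("ACGTN"),
    "rna": set("ACGUN"),
    "protein": set("ACDEFGHIKLMNPQRSTVWYX"),
}


@dataclass(frozen=True)
class FastaRecord:
    record_id: str
    seq: str
    description: str = ""


def _as_handle(source) -> TextIO:
    if isinstance(source, str) and "\n" not in source and "\r" not in source:
        return open(source)
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def parse_fasta(source, alphabet: str = "dna") -> list[FastaRecord]:
    """Parse FASTA text into validated, uppercased records.

    ``source`` may be a path, FASTA text, or an open handle. For ``dna`` U
    is mapped to T; for ``rna`` T is mapped to U. Residues outside the
    alphabet (plus N for nucleotide, X for protein) reject the record by id.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = _ALPHABETS[alphabet]
    out: list[FastaRecord] = []
    handle = _as_handle(source)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if alphabet == "dna":
                seq = to_dna(seq)
            elif alphabet == "rna":
                seq = to_rna(seq)
            if not seq:
                raise ValueError(f"empty FASTA record {rec.id!r}")
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"record {rec.id!r}: illegal {alphabet} residues "
                    f"{sorted(bad)}"
                )
            out.append(FastaRecord(rec.id, seq, rec.description))
    finally:
        if handle is not source:
            handle.close()
    return out


def write_fasta(
    records: Iterable, handle_or_path, rna: bool = False, width: int = 70
) -> None:
    """Write records (anything with .record_id/.seq or (id, seq) pairs)."""

    def emit(handle: TextIO) -> None:
        for rec in records:
            if hasattr(rec, "record_id"):
                rid, seq = rec.record_id, rec.seq
            elif hasattr(rec, "chrom"):
                rid, seq = rec.chrom, rec.seq
            else:
                rid, seq = rec
            if rna:
                seq = to_rna(seq)
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")

    if isinstance(handle_or_path, str):
        with open(handle_or_path, "w") as fh:
            emit(fh)
    else:
        emit(handle_or_path)


def parse_gff3(source, feature_types: frozenset[str] = frozenset({"gene"})) -> list[GeneModel]:
    """Parse GFF3 rows of the requested feature types into gene models.

    1-based inclusive GFF3 coordinates become 0-based half-open. Rows whose
    end precedes their start are rejected with the offending line number.
    """
    handle = _as_handle(source)
    models: list[GeneModel] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"GFF3 line {lineno}: expected 9 columns")
            feat = feature_from_line(line)
            if feat.featuretype not in feature_types:
                continue
            if feat.end < feat.start:
                raise ValueError(
                    f"GFF3 line {lineno}: end {feat.end} < start {feat.start}"
                )
            gene_id = feat.attributes.get("ID", [feat.id or f"line{lineno}"])[0]
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            models.append(
                GeneModel(
                    gene_id,
                    GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand),
                )
            )
    finally:
        if handle is not source:
            handle.close()
    return models


def write_gff3(models: Iterable[GeneModel], handle_or_path) -> None:
    def emit(handle: TextIO) -> None:
        handle.write("##gff-version 3\n")
        for m in models:
            start, end = m.interval.as_one_based()
            handle.write(
                f"{m.interval.chrom}\tplantmir\tgene\t{start}\t{end}\t.\t"
                f"{m.interval.strand}\t.\tID={m.gene_id}\n"
            )

    if isinstance(handle_or_path, str):
        with open(handle_or_path, "w") as fh:
            emit(fh)
    else:
        emit(handle_or_path)


def parse_domain_table(source) -> list[DomainAnnotation]:
    """Parse a TSV of protein_id, domain_name, start, end (1-based inclusive).

    Unknown domain names are kept but flagged ``other`` (original name
    preserved); rows with start > end are rejected.
    """
    handle = _as_handle(source)
    try:
        df = pd.read_csv(
            handle,
            sep="\t",
            header=None,
            names=["protein_id", "domain_name", "start", "end"],
            comment="#",
            skip_blank_lines=True,
            dtype={"protein_id": str, "domain_name": str},
        )
    finally:
        if handle is not source:
            handle.close()
    if len(df) and df.iloc[0]["protein_id"] == "protein_id":
        df = df.iloc[1:].reset_index(drop=True)
    out: list[DomainAnnotation] = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        name = str(row.domain_name)
        canonical = name if name in DOMAIN_VOCABULARY else "other"
        out.append(
            DomainAnnotation(str(row.protein_id), canonical, start, end, raw_name=name)
        )
    return out


def write_domain_table(annotations: Iterable[DomainAnnotation], handle_or_path) -> None:
    rows = [
        (a.protein_id, a.raw_name, a.start, a.end) for a in annotations
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "domain_name", "start", "end"])
    df.to_csv(handle_or_path, sep="\t", index=False, header=False)


def parse_blocklist(source) -> list[GenomicInterval]:
    """BED-like TSV (chrom, start, end[, name[, strand]]) of masked intervals."""
    handle = _as_handle(source)
    out = []
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    finally:
        if handle is not source:
            handle.close()
    return out


def write_bed(intervals: Iterable[GenomicInterval], handle_or_path, names=None) -> None:
    def emit(handle: TextIO) -> None:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )

    if isinstance(handle_or_path, str):
        with open(handle_or_path, "w") as fh:
            emit(fh)
    else:
        emit(handle_or_path)


def precursor_table(records) -> pd.DataFrame:
    """S2-style locus report: one row per accepted precursor, 1-based."""
    rows = []
    for r in records:
        start, end = r.interval.as_one_based()
        mat = r.mature
        rows.append(
            {
                "precursor": r.name or r.candidate_id,
                "family": r.family or "",
                "chromosome": r.interval.chrom,
                "start": start,
                "end": end,
                "strand": r.interval.strand,
                "location": r.provenance.get("location", ""),
                "mature_arm": mat.arm if mat else "",
                "mature_start": mat.start + 1 if mat else "",
                "mature_end": mat.end if mat else "",
                "mature_size": (mat.end - mat.start) if mat else "",
                "first_nt": mat.first_nt if mat else "",
            }
        )
    return pd.DataFrame(rows)


def descriptor_table(records) -> pd.DataFrame:
    """S3-style thermodynamic/compositional report, one row per precursor."""
    rows = []
    for r in records:
        t, c = r.thermo, r.composition
        rows.append(
            {
                "precursor": r.name or r.candidate_id,
                "length": r.length,
                "MFE": t.mfe if t else "",
                "AMFE": round(t.amfe, 4) if t else "",
                "MFEI": round(t.mfei, 4) if t else "",
                "MFEE": "" if t is None or t.mfee is None else round(t.mfee, 4),
                "Diversity": ""
                if t is None or t.diversity is None
                else round(t.diversity, 4),
                "Frequency": ""
                if t is None or t.frequency is None
                else round(t.frequency, 6),
                "A_pct": round(c.a, 2) if c else "",
                "U_pct": round(c.u, 2) if c else "",
                "C_pct": round(c.c, 2) if c else "",
                "G_pct": round(c.g, 2) if c else "",
                "GC_pct": round(c.gc, 2) if c else "",
                "AU_pct": round(c.au, 2) if c else "",
                "GC_ratio": "" if c is None or c.gc_ratio is None else round(c.gc_ratio, 4),
                "AU_ratio": "" if c is None or c.au_ratio is None else round(c.au_ratio, 4),
                "engine": t.engine if t else "",
            }
        )
    return pd.DataFrame(rows)
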