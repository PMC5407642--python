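"""Core value types shared across the pipeline.

Coordinates are 0-based half-open internally; every user-facing report
converts to 1-based inclusive. DNA is the storage alphabet: RNA inputs are
normalized to DNA on read and re-emitted as RNA only in miRNA-facing output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Controlled vocabulary for protein domain annotations.
DOMAIN_VOCABULARY = frozenset(
    {
        "DExD",
        "Helicase-C",
        "DUF283",
        "PAZ",
        "RIBOc",
        "DSRM",
        "Gly-rich_Ago1",
        "ArgoN",
        "ArgoMid",
        "Piwi",
        "RdRP",
    }
)

_FAMILY_RE = re.compile(r"(?:mir|miR|MIR)[-]?(\d+)", re.ASCII)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >=1 nt (strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def as_one_based(self) -> tuple[int, int]:
        """(start, end) in the 1-based inclusive convention of the reports."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class GenomeSequence:
    chrom: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.chrom}: illegal genome residues {bad}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class ReferenceMature:
    """A known mature miRNA (stored as DNA; family parsed from the id)."""

    mirna_id: str
    seq: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.family == "":
            object.__setattr__(self, "family", parse_family(self.mirna_id))

    @property
    def length(self) -> int:
        return len(self.seq)


def parse_family(mirna_id: str) -> str:
    """MIR-family label from a miRBase-style id, e.g. ath-miR156a-5p -> MIR156."""
    m = _FAMILY_RE.search(mirna_id)
    if m is None:
        raise ValueError(f"cannot parse family from id {mirna_id!r}")
    return f"MIR{m.group(1)}"


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.protein_id}: empty protein sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain, 1-based inclusive amino-acid coordinates.

    ``domain_name`` is normalized to the controlled vocabulary; unknown
    names are flagged ``other`` with the original kept in ``raw_name``.
    """

    protein_id: str
    domain_name: str
    start: int
    end: int
    raw_name: str = ""

    def __post_init__(self) -> None:
        if self.raw_name == "":
            object.__setattr__(self, "raw_name", self.domain_name)
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.raw_name}: bad span "
                f"{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ThermoProfile:
    """Per-precursor thermodynamic descriptors.

    MFE/MFEE in the engine's energy units (kcal/mol for a thermodynamic
    engine); AMFE per 100 nt; MFEI reported as a positive magnitude.
    Ensemble quantities are None when the configured engine cannot supply
    them (fallback engine on sequences > 30 nt).
    """

    mfe: float
    amfe: float
    mfei: float
    mfee: float | None = None
    diversity: float | None = None
    frequency: float | None = None
    engine: str = ""


@dataclass
class BaseComposition:
    """Base percentages over non-N residues (RNA lettering: T counted as U)."""

    a: float
    u: float
    c: float
    g: float

    @property
    def gc(self) -> float:
        return self.g + self.c

    @property
    def au(self) -> float:
        return self.a + self.u

    @property
    def gc_ratio(self) -> float | None:
        return None if self.c == 0 else self.g / self.c

    @property
    def au_ratio(self) -> float | None:
        return None if self.u == 0 else self.a / self.u


@dataclass
class MatureArmPlacement:
    """Mature location within the precursor (0-based half-open internally)."""

    arm: str  # "5p" or "3p"
    start: int
    end: int
    first_nt: str  # first 5' nucleotide, RNA lettering


@dataclass
class PrecursorRecord:
    """A candidate or accepted pre-miRNA with its full descriptor set."""

    candidate_id: str
    seq: str  # DNA, precursor orientation (5'->3' on its strand)
    interval: GenomicInterval
    structure: str | None = None  # dot-bracket
    thermo: ThermoProfile | None = None
    composition: BaseComposition | None = None
    mature: MatureArmPlacement | None = None
    mature_mismatches: int | None = None  # vs the seeding reference
    seed_ref_id: str | None = None
    family: str | None = None
    name: str | None = None  # e.g. ccp-MIR156a
    loop: tuple[int, int] | None = None  # loop interval within precursor
    provenance: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.seq)
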