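"""Synthetic genomes, reference miRNA sets, gene models, and protein sets
with known ground truth.

The generator emulates the statistical shape of a homology-based plant
MIR annotation study: fold-back precursors (arm + loop + reverse-
complement arm) planted in an i.i.d. background genome, mature sequences
of 19-25 nt with a 21-nt mode and a 5'-U bias, a miRBase-style reference
set holding a slightly diverged "ortholog" per planted family, gene
models realizing an exact genic/intergenic split, and transposon-like
decoy inverted repeats whose intervals form the repeat blocklist.
Background composition is i.i.d. with configurable GC; no higher-order
structure is simulated.

All randomness flows through one numpy Generator seeded from the config;
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import (
    DomainAnnotation,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    ProteinRecord,
    ReferenceMature,
    revcomp,
)
from . import machinery

_BASES = np.array(list("ACGT"))

#: Conserved plant MIR family numbers used to label planted families.
_FAMILY_NUMBERS = (
    156, 159, 160, 162, 164, 166, 167, 168, 169, 171,
    172, 319, 390, 393, 394, 395, 396, 397, 398, 399,
    408, 482, 535, 827, 2111,
)


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 7
    n_chromosomes: int = 3
    chromosome_length: int = 50_000
    n_plants: int = 20
    arm_length: tuple[int, int] = (45, 60)
    loop_length: tuple[int, int] = (8, 15)
    per_arm_mismatches: int = 2
    ref_mismatches: int = 1  # divergence of the "known ortholog" mature
    gc_background: float = 0.38
    #: relative weights of mature lengths 19..25 (mode 21, as in plants)
    mature_length_weights: tuple[int, ...] = (2, 3, 8, 3, 2, 1, 1)
    first_u_bias: float = 0.8
    genic_fraction: float = 0.2
    n_background_genes: int = 8
    n_decoy_repeats: int = 5
    min_separation: int = 1_500  # between planted features

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_background <= 1.0):
            raise ValueError("gc_background must be a probability")
        if not (0.0 <= self.genic_fraction <= 1.0):
            raise ValueError("genic_fraction must be a probability")
        if self.arm_length[0] > self.arm_length[1] or self.loop_length[0] > self.loop_length[1]:
            raise ValueError("empty length range")
        if len(self.mature_length_weights) != 7:
            raise ValueError("need weights for lengths 19..25")


@dataclass
class PlantedHairpinTruth:
    family: str
    interval: GenomicInterval  # precursor span, genome coordinates
    mature_seq: str  # DNA, precursor orientation
    arm: str  # 5p or 3p
    mature_offset: int  # 0-based within precursor
    mutations: int  # per-arm mismatch count used
    decoy: bool = False


@dataclass
class SynthResult:
    genome: list[GenomeSequence]
    genes: list[GeneModel]
    truth: list[PlantedHairpinTruth]  # true plants only
    references: list[ReferenceMature]
    blocklist: list[GenomicInterval]  # decoy repeat intervals
    decoys: list[PlantedHairpinTruth]
    config: SynthConfig


def _exact_counts(weights: tuple[int, ...], n: int) -> list[int]:
    """Largest-remainder apportionment so the histogram is exact."""
    total = sum(weights)
    raw = [w * n / total for w in weights]
    counts = [int(x) for x in raw]
    rest = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rest]:
        counts[i] += 1
    return counts


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    if k == 0 or not seq:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(k, len(chars)), replace=False)
    for pos in positions:
        options = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = options[rng.integers(0, 3)]
    return "".join(chars)


def _build_hairpin(rng, config, mature_len):
    """One fold-back precursor; returns (seq, mature, arm, offset)."""
    for _ in range(200):
        arm_len = int(rng.integers(config.arm_length[0], config.arm_length[1] + 1))
        loop_len = int(rng.integers(config.loop_length[0], config.loop_length[1] + 1))
        mature = _random_seq(rng, mature_len, 0.45)
        if rng.random() < config.first_u_bias:
            mature = "T" + mature[1:]
        host = list(_random_seq(rng, arm_len, config.gc_background))
        offset_in_arm = int(rng.integers(0, arm_len - mature_len + 1))
        host[offset_in_arm : offset_in_arm + mature_len] = mature
        host = "".join(host)
        other = _mutate(rng, revcomp(host), config.per_arm_mismatches)
        loop = _random_seq(rng, loop_len, config.gc_background)
        arm = "5p" if rng.random() < 0.5 else "3p"
        if arm == "5p":
            seq = host + loop + other
            offset = offset_in_arm
        else:
            seq = other + loop + host
            offset = arm_len + loop_len + offset_in_arm
        gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        if 25.0 <= gc <= 60.0:
            return seq, mature, arm, offset
    raise RuntimeError("could not draw a hairpin inside the GC window")


def generate_genome(config: SynthConfig = SynthConfig()) -> SynthResult:
    """Genome + gene models + planted-hairpin truth + reference set.

    Raises before emission when the genome cannot host the requested
    number of planted features at the configured separation.
    """
    rng = np.random.default_rng(config.seed)
    n_features = config.n_plants + config.n_decoy_repeats
    capacity = config.n_chromosomes * max(
        0, config.chromosome_length // config.min_separation - 1
    )
    if n_features > capacity:
        raise ValueError(
            f"genome too short: {n_features} features exceed capacity {capacity}"
        )

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {
        name: list(_random_seq(rng, config.chromosome_length, config.gc_background))
        for name in chrom_names
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_names}

    def place(length: int) -> GenomicInterval:
        for _ in range(1000):
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            start = int(rng.integers(0, config.chromosome_length - length))
            lo, hi = start - config.min_separation, start + length + config.min_separation
            if all(e <= lo or s >= hi for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return GenomicInterval(chrom, start, start + length)
        raise ValueError("could not place feature; genome too crowded")

    mature_counts = _exact_counts(config.mature_length_weights, config.n_plants)
    mature_lengths = [
        19 + i for i, c in enumerate(mature_counts) for _ in range(c)
    ]
    rng.shuffle(mature_lengths)

    truth: list[PlantedHairpinTruth] = []
    references: list[ReferenceMature] = []
    for idx in range(config.n_plants):
        fam_num = _FAMILY_NUMBERS[idx % len(_FAMILY_NUMBERS)]
        family = f"MIR{fam_num}"
        seq, mature, arm, offset = _build_hairpin(rng, config, mature_lengths[idx])
        iv = place(len(seq))
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, strand)
        inserted = seq if strand == "+" else revcomp(seq)
        chroms[iv.chrom][iv.start : iv.end] = list(inserted)
        truth.append(
            PlantedHairpinTruth(
                family, iv, mature, arm, offset, config.per_arm_mismatches
            )
        )
        letter = chr(ord("a") + idx // len(_FAMILY_NUMBERS))
        ortholog = _mutate(rng, mature, config.ref_mismatches)
        references.append(
            ReferenceMature(f"ath-miR{fam_num}{letter}", ortholog, family)
        )

    decoys: list[PlantedHairpinTruth] = []
    blocklist: list[GenomicInterval] = []
    for d in range(config.n_decoy_repeats):
        donor = truth[int(rng.integers(0, len(truth)))]
        seq, mature, arm, offset = _build_hairpin(
            rng, config, len(donor.mature_seq)
        )
        # reuse the donor's mature so the decoy seeds like a real precursor
        seq = (
            seq[:offset] + donor.mature_seq + seq[offset + len(donor.mature_seq) :]
        )
        iv = place(len(seq))
        chroms[iv.chrom][iv.start : iv.end] = list(seq)
        decoys.append(
            PlantedHairpinTruth(
                donor.family, iv, donor.mature_seq, arm, offset, 0, decoy=True
            )
        )
        pad = 50  # blocklist the repeat with margin, like a masked element
        blocklist.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - pad),
                min(config.chromosome_length, iv.end + pad),
            )
        )

    genes: list[GeneModel] = []
    n_genic = round(config.genic_fraction * config.n_plants)
    genic_idx = rng.choice(config.n_plants, size=n_genic, replace=False)
    for gi, t_idx in enumerate(sorted(int(i) for i in genic_idx)):
        iv = truth[t_idx].interval
        pad_l = int(rng.integers(100, 400))
        pad_r = int(rng.integers(100, 400))
        genes.append(
            GeneModel(
                f"SYNG{gi + 1:03d}",
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - pad_l),
                    min(config.chromosome_length, iv.end + pad_r),
                ),
            )
        )
    for bg in range(config.n_background_genes):
        length = int(rng.integers(500, 2000))
        try:
            iv = place(length)
        except ValueError:
            break
        genes.append(GeneModel(f"SYNBG{bg + 1:03d}", iv))

    genome = [GenomeSequence(name, "".join(chroms[name])) for name in chrom_names]
    return SynthResult(
        genome=genome,
        genes=sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)),
        truth=truth,
        references=references,
        blocklist=sorted(blocklist),
        decoys=decoys,
        config=config,
    )


def evaluate_discovery(accepted, truth: list[PlantedHairpinTruth]) -> dict:
    """Precision/recall of accepted precursors against the planted truth.

    An accepted record matches a truth entry when their genomic intervals
    overlap; each truth entry may be claimed once.
    """
    unmatched = list(range(len(truth)))
    tp = 0
    for rec in accepted:
        hit = None
        for k in unmatched:
            if rec.interval.overlaps(truth[k].interval):
                hit = k
                break
        if hit is not None:
            unmatched.remove(hit)
            tp += 1
    fp = len(accepted) - tp
    fn = len(truth) - tp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / len(accepted) if accepted else 0.0,
        "recall": tp / len(truth) if truth else 0.0,
    }


# ---------------------------------------------------------------------------
# Protein sets
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: AGO scaffold domain layout (1-based, before any padding).
_AGO_DOMAINS = (
    ("ArgoN", 205, 341),
    ("PAZ", 407, 532),
    ("ArgoMid", 600, 674),
    ("Piwi", 694, 1013),
)
_DCL_RIBOC1_START = 1201  # 1-based; RNase III reference occupies 160 aa
_DCL_RIBOC2_START = 1423


@dataclass
class ExpectedReport:
    protein_id: str
    family: str
    motif: str
    clade: str | None = None
    upstream: str | None = None


@dataclass
class SynthProteinResult:
    proteins: list[ProteinRecord]
    domains: list[DomainAnnotation]
    expected: list[ExpectedReport]


def _shift(doms, pad):
    return [(n, s + pad, e + pad) for n, s, e in doms]


def _ago_protein(rng, pid, rules):
    anchors = {760: "D", 845: "D", 986: "H", 798: "H"}
    for rule in rules:
        anchors[_parse_ago_rule(rule)[0]] = _parse_ago_rule(rule)[1]
    seq = list(machinery.SYNTHETIC_AGO_REFERENCE.seq)
    for pos, aa in anchors.items():
        seq[pos - 1] = aa
    pad = int(rng.integers(0, 31))
    seq = list(_random_protein(rng, pad)) + seq
    motif = f"{anchors[760]}{anchors[845]}{anchors[986]}/{anchors[798]}"
    doms = [
        DomainAnnotation(pid, n, s + pad, e + pad) for n, s, e in _AGO_DOMAINS
    ]
    return ProteinRecord(pid, "".join(seq)), doms, ExpectedReport(pid, "AGO", motif)


def _parse_ago_rule(rule: str) -> tuple[int, str]:
    known = {"D760": 760, "D845": 845, "H986": 986, "H798": 798}
    try:
        left, right = rule.replace("→", "->").split("->")
        return known[left.strip()], right.strip()
    except (ValueError, KeyError) as exc:
        raise ValueError(f"unknown AGO corruption rule {rule!r}") from exc


def _random_protein(rng, length):
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _dcl_protein(rng, pid, rules):
    rn = machinery.SYNTHETIC_RNASE3_REFERENCE.seq
    anchor_pos = machinery.RNASE3_ANCHOR_POSITIONS
    domain_motifs = [list("EDDE"), list("EDDE")]
    for rule in rules:
        dom_idx, slot, aa = _parse_dcl_rule(rule)
        domain_motifs[dom_idx][slot] = aa
    seq = list(_random_protein(rng, 1747))
    layout = [
        ("DExD", 114, 266),
        ("Helicase-C", 503, 619),
        ("DUF283", 693, 784),
        ("PAZ", 1029, 1164),
        ("RIBOc", _DCL_RIBOC1_START, _DCL_RIBOC1_START + len(rn) - 1),
        ("RIBOc", _DCL_RIBOC2_START, _DCL_RIBOC2_START + len(rn) - 1),
        ("DSRM", 1600, 1660),
        ("DSRM", 1680, 1740),
    ]
    for d, start in enumerate((_DCL_RIBOC1_START, _DCL_RIBOC2_START)):
        dom = list(rn)
        for slot, pos in enumerate(anchor_pos):
            dom[pos - 1] = domain_motifs[d][slot]
        seq[start - 1 : start - 1 + len(rn)] = dom
    doms = [DomainAnnotation(pid, n, s, e) for n, s, e in layout]
    motif = "/".join("".join(m) for m in domain_motifs)
    return ProteinRecord(pid, "".join(seq)), doms, ExpectedReport(pid, "DCL", motif)


def _parse_dcl_rule(rule: str) -> tuple[int, int, str]:
    # e.g. "RIBOc1:E1->Q" : domain 1, anchor slot 1 (of EDDE), to Q
    try:
        dom_part, rest = rule.split(":")
        left, right = rest.replace("→", "->").split("->")
        dom_idx = int(dom_part.removeprefix("RIBOc")) - 1
        slot = int(left[1:]) - 1
        assert dom_idx in (0, 1) and 0 <= slot <= 3
        return dom_idx, slot, right.strip()
    except (ValueError, AssertionError) as exc:
        raise ValueError(f"unknown DCL corruption rule {rule!r}") from exc


def _rdr_protein(rng, pid, rules):
    core, upstream = "DLDGD", "CSGS"
    for rule in rules:
        if rule in ("L->F", "DLDGD->DFDGD"):
            core = "DFDGD"
        elif rule in ("C->A", "CSGS->ASGS"):
            upstream = "ASGS"
        elif rule in ("S4->G", "CSGS->CSGG"):
            upstream = "CSGG"
        else:
            raise ValueError(f"unknown RDR corruption rule {rule!r}")
    seq = list(_random_protein(rng, 1100))
    motif_at = 480  # 0-based insert position inside the RdRP domain
    gamma = core == "DFDGD"
    # the gamma clade carries the DxDGD motif without the (C/A)SG(S/G) preamble
    preamble = _random_protein(rng, 4) if gamma else upstream
    insert = preamble + _random_protein(rng, 8) + core
    seq[motif_at : motif_at + len(insert)] = insert
    keep_start = motif_at + len(insert) - 5 if gamma else motif_at
    keep_len = 5 if gamma else len(insert)
    s = _scrub_rdr("".join(seq), keep_start, keep_len)
    doms = [DomainAnnotation(pid, "RdRP", 300, 900)]
    expected_up = None if gamma else upstream
    motif = core if gamma else f"{core}+{upstream}"
    return (
        ProteinRecord(pid, s),
        doms,
        ExpectedReport(pid, "RDR", motif, clade="gamma" if gamma else "alpha",
                       upstream=expected_up),
    )


def _scrub_rdr(seq: str, keep_start: int, keep_len: int) -> str:
    """Remove accidental DxDGD / (C/A)SG(S/G) occurrences outside the insert."""
    chars = list(seq)
    for pat in (machinery.RDR_MOTIF_RE, machinery.RDR_UPSTREAM_RE):
        while True:
            hit = None
            for m in pat.finditer("".join(chars)):
                if not (keep_start <= m.start() < keep_start + keep_len):
                    hit = m
                    break
            if hit is None:
                break
            chars[hit.start()] = "W"
    return "".join(chars)


def generate_protein_set(
    seed: int,
    families: dict[str, int] | None = None,
    corruptions: dict[str, list[str]] | None = None,
) -> SynthProteinResult:
    """Synthetic AGO/DCL/RDR proteins with planted catalytic residues.

    ``families`` maps family name to count (default one of each);
    ``corruptions`` maps a protein id (e.g. "synAGO2") to rule strings
    such as "H798->S", "RIBOc1:E1->Q", or "CSGS->ASGS". The emitted
    expected reports are what the machinery classifiers must return.
    """
    rng = np.random.default_rng(seed)
    families = families or {"AGO": 1, "DCL": 1, "RDR": 1}
    corruptions = corruptions or {}
    builders = {"AGO": _ago_protein, "DCL": _dcl_protein, "RDR": _rdr_protein}
    proteins: list[ProteinRecord] = []
    domains: list[DomainAnnotation] = []
    expected: list[ExpectedReport] = []
    for family in sorted(families):
        if family not in builders:
            raise ValueError(f"unknown protein family {family!r}")
        for i in range(families[family]):
            pid = f"syn{family}{i + 1}"
            rules = corruptions.get(pid, [])
            prot, doms, exp = builders[family](rng, pid, rules)
            proteins.append(prot)
            domains.extend(doms)
            expected.append(exp)
    unknown = set(corruptions) - {p.protein_id for p in proteins}
    if unknown:
        raise ValueError(f"corruption rules for unknown proteins: {sorted(unknown)}")
    return SynthProteinResult(proteins, domains, expected)


def write_synth(result: SynthResult, outdir: str) -> None:
    """Persist a synthetic dataset as FASTA/GFF3/TSV/BED + YAML config.

    Fixed seed gives byte-identical files across runs.
    """
    import os

    import yaml

    from . import seqio

    os.makedirs(outdir, exist_ok=True)
    seqio.write_fasta(result.genome, os.path.join(outdir, "genome.fa"))
    seqio.write_gff3(result.genes, os.path.join(outdir, "genes.gff3"))
    with open(os.path.join(outdir, "references.fa"), "w") as fh:
        seqio.write_fasta(
            [(r.mirna_id, r.seq) for r in result.references], fh, rna=True
        )
    seqio.write_bed(
        result.blocklist,
        os.path.join(outdir, "blocklist.bed"),
        names=[f"decoy{i + 1}" for i in range(len(result.blocklist))],
    )
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write(
            "family\tchrom\tstart\tend\tstrand\tarm\tmature_offset\t"
            "mature_seq\tmutations\n"
        )
        for t in result.truth:
            iv = t.interval
            fh.write(
                f"{t.family}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{t.arm}\t{t.mature_offset}\t{t.mature_seq}\t{t.mutations}\n"
            )
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config_as_dict(result.config), fh, sort_keys=True)


def read_truth(path: str) -> list[PlantedHairpinTruth]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            fam, chrom, start, end, strand, arm, off, mseq, mut = (
                line.rstrip("\n").split("\t")
            )
            out.append(
                PlantedHairpinTruth(
                    fam,
                    GenomicInterval(chrom, int(start), int(end), strand),
                    mseq,
                    arm,
                    int(off),
                    int(mut),
                )
            )
    return out


def config_as_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["arm_length"] = list(config.arm_length)
    d["loop_length"] = list(config.loop_length)
    d["mature_length_weights"] = list(config.mature_length_weights)
    return d
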