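"""miRNA target prediction with expectation scoring.

The scoring schema follows the classic small-RNA/target complementarity
penalty table: each mismatch costs 1.0, each G:U wobble 0.5, each gap
position 2.0, and penalties inside the seed window (miRNA positions 2-13
from the 5' end) are doubled. Sites scoring at or below the expectation
cutoff (study setting: 2.0) are reported. A mismatched, wobbled, or
gapped position wholly inside miRNA positions 9-11 marks the hit as
translational inhibition; otherwise cleavage is called. Target-site
accessibility energy (UPE) is carried as an optional pass-through field,
not computed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import revcomp, to_dna, to_rna

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA space, DNA lettering


@dataclass(frozen=True)
class TargetScoringParams:
    expectation_cutoff: float = 2.0
    hspsize: int = 20  # minimum complementarity window, nt
    seed_start: int = 2  # miRNA positions with doubled penalty, inclusive
    seed_end: int = 13
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0  # per gap position
    max_gaps: int = 1
    inhibition_start: int = 9  # central window for translational calls
    inhibition_end: int = 11
    upe_cutoff: float = 25.0  # recorded only; accessibility is not computed


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # transcript site, 0-based half-open
    end: int
    expectation: float
    alignment: str  # three-line duplex rendering
    inhibition: str  # "cleavage" or "translation"
    upe: float | None = None  # optional externally supplied accessibility


def _position_penalties(mirna: str, site_rc: str, params: TargetScoringParams):
    """Penalty per miRNA position for an ungapped duplex.

    ``site_rc`` is the reverse complement of the transcript site, so that
    position k pairs miRNA[k] (both 5'->3'); equal bases mean a perfect
    Watson-Crick pair in the duplex.
    """
    pens = []
    for k, (a, b) in enumerate(zip(mirna, site_rc), start=1):
        t = b  # genome base the miRNA base must match after revcomp
        if a == t:
            p, kind = 0.0, "|"
        elif (a, t) in (("G", "A"), ("T", "C")):
            # miRNA G across site U, or miRNA U across site G -> G:U wobble
            p, kind = params.gu_penalty, "o"
        else:
            p, kind = params.mismatch_penalty, "x"
        if params.seed_start <= k <= params.seed_end:
            p *= 2.0
        pens.append((p, kind))
    return pens


def score_duplex(
    mirna: str, site: str, params: TargetScoringParams = TargetScoringParams()
) -> tuple[float, str]:
    """Expectation score of a miRNA / target-site duplex.

    ``mirna`` is the mature sequence 5'->3' (RNA or DNA lettering);
    ``site`` is the transcript site 5'->3'. Site length may differ from
    the miRNA length by at most ``max_gaps``; the best gap placement is
    taken and each gap position costs ``gap_penalty`` (doubled in seed).
    """
    m = to_dna(mirna.upper())
    s = to_dna(site.upper())
    diff = len(s) - len(m)
    if abs(diff) > params.max_gaps:
        raise ValueError(
            f"site length {len(s)} incompatible with miRNA length {len(m)}"
        )
    site_rc = revcomp(s)
    if diff == 0:
        pens = _position_penalties(m, site_rc, params)
        exp = sum(p for p, _ in pens)
        return exp, _render(m, site_rc, [k for _, k in pens])
    best = None
    longer, shorter, gap_in_mirna = (
        (site_rc, m, True) if diff > 0 else (m, site_rc, False)
    )
    for g in range(len(shorter) + 1):
        padded = shorter[:g] + "-" * abs(diff) + shorter[g:]
        mm = padded if gap_in_mirna else longer
        ss = longer if gap_in_mirna else padded
        pens = []
        for k, (a, b) in enumerate(zip(mm, ss), start=1):
            if a == "-" or b == "-":
                p, kind = params.gap_penalty, "-"
            elif a == b:
                p, kind = 0.0, "|"
            elif (a, b) in (("G", "A"), ("T", "C")):
                p, kind = params.gu_penalty, "o"
            else:
                p, kind = params.mismatch_penalty, "x"
            if params.seed_start <= k <= params.seed_end:
                p *= 2.0
            pens.append((p, kind))
        exp = sum(p for p, _ in pens)
        if best is None or exp < best[0]:
            best = (exp, _render(mm, ss, [k for _, k in pens]))
    return best


def _render(mirna_row: str, site_rc_row: str, kinds: list[str]) -> str:
    marks = "".join({"|": "|", "o": "o", "x": " ", "-": " "}[k] for k in kinds)
    return f"miRNA 5' {to_rna(mirna_row)} 3'\n         {marks}\nsite  3' {to_rna(site_rc_row)} 5'"


def _inhibition(kinds: list[str], params: TargetScoringParams) -> str:
    lo, hi = params.inhibition_start, params.inhibition_end
    for k, kind in enumerate(kinds, start=1):
        if kind != "|" and lo <= k <= hi:
            return "translation"
    return "cleavage"


def find_targets(
    mirnas,
    transcripts,
    params: TargetScoringParams = TargetScoringParams(),
) -> list[TargetHit]:
    """All target sites at or below the expectation cutoff.

    ``mirnas``: records with .mirna_id/.seq (or (id, seq) pairs);
    ``transcripts``: records with .record_id/.seq or (id, seq) pairs.
    Overlapping candidate sites of one miRNA on one transcript keep the
    best (then leftmost) site. Hits are ranked per miRNA by expectation,
    then transcript id, then position.
    """
    hits: list[TargetHit] = []
    norm_mirnas = [
        (r.mirna_id, r.seq) if hasattr(r, "mirna_id") else tuple(r) for r in mirnas
    ]
    norm_tx = [
        (r.record_id, r.seq) if hasattr(r, "record_id") else tuple(r)
        for r in transcripts
    ]
    for mid, mseq in norm_mirnas:
        m = to_dna(mseq.upper())
        for tid, tseq in norm_tx:
            t = to_dna(tseq.upper())
            raw: list[TargetHit] = []
            for site_len in range(
                len(m) - params.max_gaps, len(m) + params.max_gaps + 1
            ):
                for start in range(0, len(t) - site_len + 1):
                    site = t[start : start + site_len]
                    exp, aln = score_duplex(m, site, params)
                    if exp <= params.expectation_cutoff:
                        kinds = _kinds_from_alignment(aln)
                        raw.append(
                            TargetHit(
                                mid,
                                tid,
                                start,
                                start + site_len,
                                exp,
                                aln,
                                _inhibition(kinds, params),
                            )
                        )
            raw.sort(key=lambda h: (h.expectation, h.start, h.end - h.start))
            chosen: list[TargetHit] = []
            for h in raw:
                if all(
                    h.end <= c.start or c.end <= h.start for c in chosen
                ):
                    chosen.append(h)
            hits.extend(chosen)
    hits.sort(key=lambda h: (h.mirna_id, h.expectation, h.transcript_id, h.start))
    return hits


def _kinds_from_alignment(aln: str) -> list[str]:
    rows = aln.split("\n")
    mrow = rows[0].split(" ")[2]
    marks = rows[1][9:].ljust(len(mrow))
    kinds = []
    for a, mk in zip(mrow, marks):
        if mk == "|":
            kinds.append("|")
        elif mk == "o":
            kinds.append("o")
        elif a == "-":
            kinds.append("-")
        else:
            kinds.append("x")
    return kinds


def summarize_targets(hits: list[TargetHit]) -> dict:
    """Distinct targets per miRNA and distinct miRNAs per transcript."""
    per_mirna: dict[str, set[str]] = {}
    per_tx: dict[str, set[str]] = {}
    for h in hits:
        per_mirna.setdefault(h.mirna_id, set()).add(h.transcript_id)
        per_tx.setdefault(h.transcript_id, set()).add(h.mirna_id)
    return {
        "targets_per_mirna": {k: len(v) for k, v in sorted(per_mirna.items())},
        "mirnas_per_transcript": {k: len(v) for k, v in sorted(per_tx.items())},
        "n_hits": len(hits),
        "n_target_transcripts": len(per_tx),
    }
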