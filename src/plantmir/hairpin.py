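"""Candidate discovery: homology seeding and inverted-repeat detection.

Stage 1 finds genome windows matching known mature miRNAs by ungapped
Hamming comparison (mature miRNAs are too short for meaningful gapped
seeds). Stage 2 detects fold-back arms inside each candidate window with a
Smith-Waterman local alignment of the window against its own reverse
complement, using the einverted-style scoring scheme: match +3, mismatch
-4, linear gap 12 per gap position, score threshold 25, maximum repeat
extent 336 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenomeSequence, GenomicInterval, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SeedMatch:
    ref_id: str
    interval: GenomicInterval
    mismatches: int


@dataclass(frozen=True)
class IRScanParams:
    match: int = 3
    mismatch: int = -4
    gap: int = 12  # linear, per gap position
    threshold: int = 25
    max_extent: int = 336
    min_loop: int = 3
    hard_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class InvertedRepeat:
    """Two arms of a fold-back, window-local 0-based half-open coordinates."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    score: float
    identity: float  # matches / aligned columns

    @property
    def loop_length(self) -> int:
        return self.right_start - self.left_end

    @property
    def extent(self) -> int:
        return self.right_end - self.left_start


@dataclass
class CandidateWindow:
    chrom: str
    start: int
    end: int
    seeds: list[SeedMatch] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def seed_by_homology(
    genome: list[GenomeSequence],
    references,
    max_mismatches: int = 3,
    both_strands: bool = True,
) -> list[SeedMatch]:
    """All genome windows within ``max_mismatches`` of a reference mature.

    Each (reference, position, strand) is reported exactly once. N never
    matches. References shorter than 15 nt are rejected by id.
    """
    for ref in references:
        if len(ref.seq) < 15:
            raise ValueError(f"reference {ref.mirna_id!r} shorter than 15 nt")
    out: list[SeedMatch] = []
    for chrom_rec in genome:
        g = _encode(chrom_rec.seq)
        n_mask = g == ord("N")
        for ref in references:
            m = len(ref.seq)
            if m > len(g):
                continue
            win = np.lib.stride_tricks.sliding_window_view(g, m)
            win_n = np.lib.stride_tricks.sliding_window_view(n_mask, m)
            queries = [("+", ref.seq)]
            if both_strands:
                queries.append(("-", revcomp(ref.seq)))
            for strand, qseq in queries:
                q = _encode(qseq)
                mism = (win != q).sum(axis=1) + 0 * win_n[:, 0]
                # windows containing N: N != any base already counts as mismatch
                hits = np.nonzero(mism <= max_mismatches)[0]
                for pos in hits:
                    out.append(
                        SeedMatch(
                            ref.mirna_id,
                            GenomicInterval(
                                chrom_rec.chrom, int(pos), int(pos) + m, strand
                            ),
                            int(mism[pos]),
                        )
                    )
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.strand, s.ref_id))
    return out


def window_candidates(
    seeds: list[SeedMatch], genome: list[GenomeSequence], flank: int = 336
) -> list[CandidateWindow]:
    """Windows of +-``flank`` nt around each seed, clipped and merged."""
    lengths = {g.chrom: g.length for g in genome}
    by_chrom: dict[str, list[SeedMatch]] = {}
    for s in seeds:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    windows: list[CandidateWindow] = []
    for chrom in sorted(by_chrom):
        chrom_len = lengths[chrom]
        items = sorted(by_chrom[chrom], key=lambda s: s.interval.start)
        current: CandidateWindow | None = None
        for s in items:
            start = max(0, s.interval.start - flank)
            end = min(chrom_len, s.interval.end + flank)
            if current is not None and start <= current.end:
                current.end = max(current.end, end)
                current.seeds.append(s)
            else:
                if current is not None:
                    windows.append(current)
                current = CandidateWindow(chrom, start, end, [s])
        if current is not None:
            windows.append(current)
    return windows


def scan_inverted_repeats(seq: str, params: IRScanParams = IRScanParams()) -> list[InvertedRepeat]:
    """Non-overlapping inverted repeats in ``seq`` scoring >= the threshold.

    Local alignment of the sequence against its own reverse complement;
    arms must be separated by at least ``min_loop`` nt and a repeat may
    not start wider than ``max_extent``. Results are sorted by score
    descending, then leftmost start, then shortest extent. The stored
    score is the recomputed alignment score.
    """
    n = len(seq)
    if n > params.hard_cap:
        raise ValueError(f"window of {n} nt exceeds hard cap {params.hard_cap}")
    seq = seq.upper()
    if n < 2 * 2 + params.min_loop:
        return []
    s = _encode(seq)
    t = _encode(revcomp(seq))
    out: list[InvertedRepeat] = []
    used_i = np.zeros(n, dtype=bool)
    used_j = np.zeros(n, dtype=bool)
    while True:
        hit = _best_local(s, t, params, used_i, used_j)
        if hit is None:
            break
        (i0, i1, j0, j1, score, ident) = hit
        # map t-coordinates back to genome: t[j] is complement of s[n-1-j]
        right_start, right_end = n - 1 - j1, n - j0
        out.append(
            InvertedRepeat(i0, i1 + 1, right_start, right_end, score, ident)
        )
        used_i[i0 : i1 + 1] = True
        used_j[j0 : j1 + 1] = True
        used_i[right_start:right_end] = True
        used_j[n - 1 - i1 : n - i0] = True
        if len(out) >= 25:
            break
    out.sort(key=lambda r: (-r.score, r.left_start, r.extent))
    return out


def _best_local(s, t, params, used_i, used_j):
    """One Smith-Waterman pass; returns the best unmasked alignment."""
    n = len(s)
    NEG = -1e18
    match, mismatch, gap = float(params.match), float(params.mismatch), float(params.gap)
    # cell (i, j) pairs s[i] with s[n-1-j]; validity: loop >= min_loop
    j_idx = np.arange(n)
    H = np.zeros((n + 1, n + 1))
    best = (0.0, None)
    best_cell = None
    for i in range(n):
        valid = (i + j_idx) <= (n - 2 - params.min_loop)
        valid &= ~used_i[i] & ~used_j
        sub = np.where(t == s[i], match, mismatch)
        start_ok = (n - i - j_idx) <= params.max_extent
        prev = H[i, :-1]  # H[i-1, j-1] row-aligned
        diag_base = np.where(prev > 0, prev, np.where(start_ok, 0.0, NEG))
        cand = np.maximum(diag_base + sub, H[i, 1:] - gap)  # diag, up
        cand = np.where(valid, cand, NEG)
        # leftward gap propagation within the row (prefix-max trick)
        shifted = cand + gap * j_idx
        run = np.maximum.accumulate(shifted) - gap * j_idx
        row = np.maximum(cand, run)
        row = np.where(valid, row, 0.0)
        row = np.maximum(row, 0.0)
        H[i + 1, 1:] = row
        jmax = int(np.argmax(row))
        if row[jmax] > best[0] + 1e-9:
            best = (float(row[jmax]), None)
            best_cell = (i, jmax)
    if best_cell is None or best[0] < params.threshold:
        return None
    return _traceback_local(s, t, H, best_cell, params)


def _traceback_local(s, t, H, cell, params):
    """Recover the alignment ending at ``cell``; prefers diagonal moves."""
    match, mismatch, gap = float(params.match), float(params.mismatch), float(params.gap)
    i, j = cell
    score = H[i + 1, j + 1]
    i1, j1 = i, j
    matches = 0
    cols = 0
    while True:
        here = H[i + 1, j + 1]
        sub = match if s[i] == t[j] else mismatch
        diag = H[i, j]
        if diag > 0 and abs(here - (diag + sub)) < 1e-9:
            cols += 1
            matches += int(s[i] == t[j])
            i -= 1
            j -= 1
            continue
        if abs(here - sub) < 1e-9:  # alignment starts at this cell
            cols += 1
            matches += int(s[i] == t[j])
            return (i, i1, j, j1, float(score), matches / cols)
        if i >= 1 and abs(here - (H[i, j + 1] - gap)) < 1e-9:
            cols += 1
            i -= 1
            continue
        if j >= 1 and abs(here - (H[i + 1, j] - gap)) < 1e-9:
            cols += 1
            j -= 1
            continue
        # no consistent predecessor (masked rerun edge case): stop here
        return (i, i1, j, j1, float(score), matches / max(cols, 1))
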