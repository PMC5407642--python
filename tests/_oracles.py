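"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by exhaustive enumeration or
direct formula evaluation, sharing no code path with the package
implementations they check.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

MIN_LOOP = 3
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


# ---------------------------------------------------------------------------
# Structure enumeration
# ---------------------------------------------------------------------------


def enumerate_structures(seq: str, cap: int = 500_000) -> list[frozenset]:
    """Every nested secondary structure (pair sets) of a short RNA."""
    rna = seq.upper().replace("T", "U")
    n = len(rna)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if j - i < MIN_LOOP + 1:
            return [frozenset()]
        out = [s for s in rec(i + 1, j)]
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (rna[i], rna[k]) in _PAIRS:
                for a in rec(i + 1, k - 1):
                    for b in rec(k + 1, j):
                        out.append(frozenset({(i, k)}) | a | b)
                        if len(out) > cap:
                            raise RuntimeError("structure count exceeds cap")
        return out

    if n == 0:
        return [frozenset()]
    return rec(0, n - 1)


def structure_energy(pairs: frozenset) -> float:
    """Fallback-model energy: -1 per pair, -1 per stacked pair."""
    return -(len(pairs) + sum(1 for (i, j) in pairs if (i + 1, j - 1) in pairs))


def ensemble_by_enumeration(seq: str, rt: float = 0.61633):
    """(MFE, MFEE, diversity, frequency) by full enumeration."""
    structs = enumerate_structures(seq)
    energies = [structure_energy(s) for s in structs]
    mfe = min(energies)
    weights = [math.exp(-e / rt) for e in energies]
    z = sum(weights)
    mfee = -rt * math.log(z)
    pair_w: dict = {}
    for s, w in zip(structs, weights):
        for p in s:
            pair_w[p] = pair_w.get(p, 0.0) + w
    diversity = sum(2 * (w / z) * (1 - w / z) for w in pair_w.values())
    frequency = math.exp(-mfe / rt) / z
    return mfe, mfee, diversity, frequency


# ---------------------------------------------------------------------------
# Inverted-repeat arm-pair enumeration
# ---------------------------------------------------------------------------

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


def ir_best_score(seq: str, match=3, mismatch=-4, gap=12, min_loop=3, max_extent=336):
    """Best inverted-repeat score by enumerating all arm pairs.

    For every pair of arm substrings (left, right) separated by at least
    ``min_loop`` and spanning at most ``max_extent``, the left arm is
    globally aligned against the reverse complement of the right arm; the
    maximum alignment score is returned (None if no positive-score pair).
    """
    n = len(seq)
    s = seq.upper()
    t = s.translate(_DNA_COMP)[::-1]  # reverse complement
    best = None
    s_arr = np.frombuffer(s.encode(), dtype=np.uint8)
    t_arr = np.frombuffer(t.encode(), dtype=np.uint8)
    for a in range(n):
        for c in range(n):
            if (n - c - a) > max_extent:
                continue
            # grow global alignments of s[a:a+x] vs t[c:c+y] for all x, y
            X, Y = n - a, n - c
            yy = np.arange(Y + 1, dtype=float)
            prev = -gap * yy
            for x in range(1, X + 1):
                cur = np.empty(Y + 1)
                cur[0] = -gap * x
                sub = np.where(s_arr[a + x - 1] == t_arr[c : c + Y], match, mismatch)
                diag = prev[:-1] + sub
                up = prev[1:] - gap
                base = np.maximum(diag, up)
                ext = np.concatenate(([cur[0]], base))
                run = np.maximum.accumulate(ext + gap * yy) - gap * yy
                cur[1:] = np.maximum(base, run[1:])
                prev = cur
                b = a + x
                # left arm s[a:b], right arm s[n-(c+y):n-c]; loop >= min_loop
                y_max = n - c - b - min_loop
                if y_max >= 1:
                    v = float(cur[1 : min(y_max, Y) + 1].max())
                    if best is None or v > best:
                        best = v
    return best


# ---------------------------------------------------------------------------
# Homology seeding
# ---------------------------------------------------------------------------


def hamming_windows(genome: str, query: str, max_mism: int) -> list[tuple[int, int]]:
    """(position, mismatches) of every window within the budget."""
    m = len(query)
    out = []
    for i in range(len(genome) - m + 1):
        d = sum(1 for a, b in zip(genome[i : i + m], query) if a != b)
        if d <= max_mism:
            out.append((i, d))
    return out


# ---------------------------------------------------------------------------
# Duplex penalty summation
# ---------------------------------------------------------------------------


def duplex_expectation(mirna: str, site: str, seed_lo=2, seed_hi=13,
                       mismatch=1.0, gu=0.5) -> float:
    """Expectation of an equal-length (ungapped) duplex by direct summation.

    Pairs the k-th miRNA base (5'->3') with the k-th base from the 3' end
    of the site and sums the penalty table, doubling inside the seed.
    """
    m = mirna.upper().replace("U", "T")
    s = site.upper().replace("U", "T")
    assert len(m) == len(s)
    total = 0.0
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("T", "G")}
    for k in range(1, len(m) + 1):
        a = m[k - 1]
        b = s[len(s) - k]  # antiparallel partner
        if (a, b) in wc:
            p = 0.0
        elif (a, b) in wobble:
            p = gu
        else:
            p = mismatch
        if seed_lo <= k <= seed_hi:
            p *= 2.0
        total += p
    return total


# ---------------------------------------------------------------------------
# Least-squares all-topology NJ oracle
# ---------------------------------------------------------------------------


def _all_topologies(n: int):
    """All unrooted binary topologies on taxa 0..n-1 as lists of splits."""
    # tree as dict node -> set(neighbours); leaves are 0..n-1
    trees = [({0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}, n + 1)]
    for leaf in range(3, n):
        new_trees = []
        for adj, next_id in trees:
            edges = {
                frozenset((u, v)) for u, nbrs in adj.items() for v in nbrs
            }
            for e in edges:
                u, v = tuple(e)
                a2 = {k: set(s) for k, s in adj.items()}
                w = next_id
                a2[u].discard(v)
                a2[v].discard(u)
                a2[u].add(w)
                a2[v].add(w)
                a2[w] = {u, v, leaf}
                a2[leaf] = {w}
                new_trees.append((a2, next_id + 1))
        trees = new_trees
    out = []
    for adj, _ in trees:
        out.append(_splits_of(adj, n))
    return out


def _splits_of(adj, n):
    splits = []
    for u, nbrs in adj.items():
        for v in nbrs:
            if u < v:
                side = _reachable(adj, u, without=v) & set(range(n))
                splits.append((frozenset((u, v)), frozenset(side)))
    return splits


def _reachable(adj, start, without):
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y != without and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def ls_best_topology(D: np.ndarray):
    """(best nontrivial splits, residual) over all topologies by least squares."""
    n = D.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    y = np.array([D[i, j] for i, j in pairs])
    best = None
    for splits in _all_topologies(n):
        cols = []
        for _, side in splits:
            cols.append([int((i in side) != (j in side)) for i, j in pairs])
        A = np.array(cols, dtype=float).T
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(np.linalg.norm(A @ x - y))
        internal = {
            side if 0 not in side else frozenset(range(n)) - side
            for _, side in splits
            if 1 < len(side) < n - 1
        }
        lengths = {}
        for (edge, side), length in zip(splits, x):
            key = side if 0 not in side else frozenset(range(n)) - side
            lengths[key] = float(length)
        if best is None or resid < best[1] - 1e-12:
            best = (internal, resid, lengths)
    return best
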