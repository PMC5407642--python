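"""Distance-based phylogenetics: K2P / protein distances, neighbor joining,
bootstrap majority-rule consensus with sub-50% collapse, newick export.

Distances follow the study's choices for pre-miRNAs (Kimura 1980
two-parameter) while protein divergence uses p-distance or Poisson
correction (a deliberate substitution for maximum-likelihood JTT
distances, recorded in the tree metadata: neighbor-joining topology at
these divergence scales is robust to the distance flavour). Gap handling
defaults to complete deletion (columns with any gap removed), matching
the published tree legends; pairwise deletion is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CTU")
_NT = frozenset("ACGTU")


@dataclass
class Msa:
    """Pre-aligned sequences (equal length, '-' gaps)."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "nucleotide"  # or "protein"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def complete_deletion(self) -> "Msa":
        """Drop every column containing a gap or missing character."""
        keep = [
            i
            for i in range(self.n_sites)
            if all(r[i] not in "-?." for r in self.rows)
        ]
        return Msa(
            list(self.ids), ["".join(r[i] for i in keep) for r in self.rows],
            self.alphabet,
        )

    def resample_columns(self, rng: np.random.Generator) -> "Msa":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        return Msa(
            list(self.ids),
            ["".join(r[c] for c in cols) for r in self.rows],
            self.alphabet,
        )


class SaturatedDistanceError(ValueError):
    """Distance formula left its domain (too-divergent pair)."""


def k2p_distance(row_i: str, row_j: str) -> float:
    """Kimura two-parameter distance between two aligned nucleotide rows.

    Sites with a gap or ambiguity in either row are excluded pairwise.
    d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)] with P, Q the transition and
    transversion proportions; saturation returns +inf.
    """
    n = 0
    transitions = 0
    transversions = 0
    for a, b in zip(row_i.upper(), row_j.upper()):
        if a not in _NT or b not in _NT:
            continue
        a = "U" if a == "T" else a
        b = "U" if b == "T" else b
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable sites between rows")
    p, q = transitions / n, transversions / n
    arg = (1 - 2 * p - q) * math.sqrt(max(1 - 2 * q, 0.0))
    if arg <= 0:
        return float("inf")
    return -0.5 * math.log(arg)


def protein_distance(row_i: str, row_j: str, model: str = "poisson") -> float:
    """p-distance or Poisson-corrected distance over gap-free sites."""
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown protein distance model {model!r}")
    n = 0
    diff = 0
    for a, b in zip(row_i.upper(), row_j.upper()):
        if a in "-?.X" or b in "-?.X":
            continue
        n += 1
        diff += int(a != b)
    if n == 0:
        raise ValueError("no comparable sites between rows")
    p = diff / n
    if model == "p-distance":
        return p
    if p >= 1.0:
        return float("inf")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if np.diag(m).any():
            raise ValueError("nonzero diagonal")
        self.matrix = m

    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if not math.isfinite(self.matrix[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def distance_matrix(
    msa: Msa,
    metric: str = "auto",
    deletion: str = "complete",
    model: str = "poisson",
) -> DistanceMatrix:
    """All-pairs distances; complete deletion first by default."""
    if metric == "auto":
        metric = "k2p" if msa.alphabet == "nucleotide" else "protein"
    work = msa.complete_deletion() if deletion == "complete" else msa
    n = work.n_taxa
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "k2p":
                d = k2p_distance(work.rows[i], work.rows[j])
            else:
                d = protein_distance(work.rows[i], work.rows[j], model=model)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(list(work.ids), m)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            label = self.name or ""
        else:
            inner = ",".join(c._newick() for c in self.children)
            label = f"({inner})"
            if self.support is not None:
                label += f"{int(round(self.support))}"
            elif self.name:
                label += self.name
        if self.length is not None:
            label += f":{self.length:.6g}"
        return label


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node) with optional supports."""

    root: TreeNode
    metadata: dict = field(default_factory=dict)

    def to_newick(self) -> str:
        return self.root.to_newick()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset[str], float | None]:
        """Internal-edge splits, each keyed by the side not containing the
        alphabetically first taxon; value is the edge's branch length."""
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out: dict[frozenset[str], float | None] = {}

        def walk(node: TreeNode) -> None:
            for child in node.children:
                side = child.leaf_names()
                if child.children and 1 < len(side) < len(all_leaves) - 0:
                    key = side if anchor not in side else all_leaves - side
                    if 1 < len(key) < len(all_leaves):
                        out[frozenset(key)] = child.length
                walk(child)

        walk(self.root)
        return out

    def support_of(self, split: frozenset[str]) -> float | None:
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        want = split if anchor not in split else all_leaves - split

        def walk(node):
            for child in node.children:
                side = child.leaf_names()
                key = side if anchor not in side else all_leaves - side
                if child.children and frozenset(key) == want:
                    return child.support
                got = walk(child)
                if got is not None:
                    return got
            return None

        return walk(self.root)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lowest index pair; negative
    branch lengths are clamped to zero with the clamped deficit recorded
    in tree metadata.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    bad = dm.saturated_pairs()
    if bad:
        raise ValueError(f"infinite distance between {bad[0][0]} and {bad[0][1]}")
    D = dm.matrix.copy()
    nodes = [TreeNode(name=t) for t in dm.ids]
    active = list(range(n))
    clamped = 0.0
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        ai, aj = divmod(int(flat), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            clamped += -li
            lj = dij
            li = 0.0
        if lj < 0:
            clamped += -lj
            li = min(dij, li + lj)
            lj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distances to the new node, stored in slot i
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, l in ((a, la), (b, lb), (c, lc)):
        if l < 0:
            clamped += -l
            l = 0.0
        nodes[idx].length = l
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    meta = {"method": "nj"}
    if clamped:
        meta["clamped_negative_length"] = clamped
    return PhyloTree(root, meta)


def bootstrap_consensus(
    msa: Msa,
    n_replicates: int,
    seed: int = 0,
    metric: str = "auto",
    deletion: str = "complete",
    model: str = "poisson",
    collapse_below: float = 50.0,
) -> PhyloTree:
    """Majority-rule bootstrap consensus with sub-threshold collapse.

    Columns are resampled with replacement per replicate (after the
    deletion policy is applied once), a NJ tree is built per replicate,
    bipartition frequencies become percentage supports, and internal
    branches below ``collapse_below`` percent are collapsed. Consensus
    branch lengths are means over the replicates containing each edge.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = msa.complete_deletion() if deletion == "complete" else msa
    rng = np.random.default_rng(seed)
    split_counts: dict[frozenset[str], int] = {}
    split_lengths: dict[frozenset[str], float] = {}
    leaf_lengths: dict[str, float] = {t: 0.0 for t in base.ids}
    leaf_counts: dict[str, int] = {t: 0 for t in base.ids}
    for _ in range(n_replicates):
        rep = base.resample_columns(rng)
        try:
            dm = distance_matrix(rep, metric=metric, deletion="pairwise", model=model)
            tree = neighbor_joining(dm)
        except ValueError:
            continue  # saturated replicate: contributes no splits
        for split, length in tree.bipartitions().items():
            split_counts[split] = split_counts.get(split, 0) + 1
            if length is not None:
                split_lengths[split] = split_lengths.get(split, 0.0) + length
        for leaf in tree.root.leaves():
            if leaf.length is not None:
                leaf_lengths[leaf.name] += leaf.length
                leaf_counts[leaf.name] += 1
    taxa = sorted(base.ids)
    keep = {
        s: 100.0 * c / n_replicates
        for s, c in split_counts.items()
        if 100.0 * c / n_replicates >= collapse_below
    }
    tree = _tree_from_splits(taxa, keep, split_counts, split_lengths)
    for leaf in tree.root.leaves():
        if leaf_counts[leaf.name]:
            leaf.length = leaf_lengths[leaf.name] / leaf_counts[leaf.name]
    tree.metadata = {
        "method": "nj-bootstrap-majority-consensus",
        "replicates": n_replicates,
        "collapse_below_percent": collapse_below,
        "distance": metric,
        "protein_model": model,
        "note": "protein distances are p/Poisson, not ML-JTT",
    }
    return tree


def _tree_from_splits(taxa, supported, counts, lengths) -> PhyloTree:
    """Greedy compatible insertion of splits by decreasing support."""
    anchor = min(taxa)
    all_set = frozenset(taxa)
    root = TreeNode(children=[TreeNode(name=t) for t in sorted(taxa)])
    placed: list[frozenset[str]] = []

    def compatible(s: frozenset[str]) -> bool:
        for p in placed:
            if not (s <= p or p <= s or not (s & p)):
                return False
        return True

    order = sorted(supported, key=lambda s: (-supported[s], sorted(s)))
    for split in order:
        side = split if anchor not in split else all_set - split
        if not compatible(side):
            continue
        # find the node currently holding all of `side` among its children
        node = root
        while True:
            for child in node.children:
                if child.children and side <= child.leaf_names():
                    node = child
                    break
            else:
                break
        group = [c for c in node.children if c.leaf_names() <= side]
        if frozenset().union(*(c.leaf_names() for c in group)) != side:
            continue
        mean_len = (
            lengths.get(split, 0.0) / counts[split] if split in counts else None
        )
        new = TreeNode(
            support=supported[split], length=mean_len, children=group
        )
        node.children = [c for c in node.children if c not in group] + [new]
        placed.append(side)
    return PhyloTree(root)
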