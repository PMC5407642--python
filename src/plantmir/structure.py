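"""RNA secondary structure, thermodynamic descriptors, and mature-arm placement.

Two folding engines sit behind one interface:

* ``fallback`` — a self-contained base-pair maximization model (each pair
  scores -1, each stacked pair an extra -1, minimum hairpin loop 3,
  Watson-Crick plus G:U wobble). Its "energies" are dimensionless scores,
  not kcal/mol, and the engine name is recorded in every profile so outputs
  are never mistaken for thermodynamic values. Ensemble quantities are
  computed exactly with an inside/outside partition function over the same
  model and are refused above 30 nt, where a thermodynamic engine should be
  used instead.
* ``vienna`` — ViennaRNA (RNAfold) via its python bindings, used when
  available; MFE in kcal/mol at 37 degC.

Descriptor conventions: AMFE = MFE/length x 100 (per 100 nt, negative);
MFEI = |AMFE| / GC%, reported as a positive magnitude so that plant miRNA
precursors land on the familiar ~0.7-1.7 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import BaseComposition, MatureArmPlacement, ThermoProfile, to_rna

#: Gas constant x temperature at 37 degC, kcal/mol.
RT = 0.61633

#: Minimum number of unpaired bases enclosed by a hairpin loop.
MIN_LOOP = 3

_PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class EngineRequiredError(RuntimeError):
    """Raised when the fallback engine refuses an ensemble computation."""


class AmbiguousHairpinError(ValueError):
    """Structure is multi-branched at the mature site (no dominant loop)."""


class LoopOverlapError(ValueError):
    """Mature interval spans the terminal loop."""


def pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------


@dataclass
class SecondaryStructure:
    """Dot-bracket structure with derived pair/loop geometry."""

    dotbracket: str

    def __post_init__(self) -> None:
        self._pairs = _parse_pairs(self.dotbracket)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(self._pairs)

    def pair_partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self._pairs:
            d[i] = j
            d[j] = i
        return d

    def hairpin_loops(self) -> list[tuple[int, int, int]]:
        """(i, j, stem_depth) for every leaf pair (hairpin-closing pair).

        Stem depth counts the leaf pair plus the unbranched chain of pairs
        enclosing it (bulges allowed, branching ends the chain).
        """
        pairs = self._pairs
        if not pairs:
            return []
        # children[pair] = directly nested pairs
        sorted_pairs = sorted(pairs, key=lambda p: (p[0], -p[1]))
        stack: list[tuple[int, int]] = []
        children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
        roots: list[tuple[int, int]] = []
        parent: dict[tuple[int, int], tuple[int, int] | None] = {}
        for p in sorted_pairs:
            while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
                stack.pop()
            if stack:
                children[stack[-1]].append(p)
                parent[p] = stack[-1]
            else:
                roots.append(p)
                parent[p] = None
            stack.append(p)
        out = []
        for p in pairs:
            if children[p]:
                continue
            depth = 1
            cur = p
            while True:
                par = parent[cur]
                if par is None or len(children[par]) != 1:
                    break
                depth += 1
                cur = par
            out.append((p[0], p[1], depth))
        out.sort(key=lambda t: t[0])
        return out

    def loop_interval(self) -> tuple[int, int]:
        """Terminal loop of the longest stem, 0-based half-open.

        The loop is the unpaired run enclosed by the innermost pair of the
        deepest stem; ties broken leftmost.
        """
        loops = self.hairpin_loops()
        if not loops:
            raise AmbiguousHairpinError("structure has no hairpin loop")
        best = max(loops, key=lambda t: (t[2], -t[0]))
        return best[0] + 1, best[1]


def _parse_pairs(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# Fallback engine
# ---------------------------------------------------------------------------


class FallbackEngine:
    """Base-pair maximization with stacking bonus; deterministic traceback.

    Energy model: E(S) = -(number of pairs) - (number of stacks), where a
    stack is a pair (i,j) whose inner neighbour (i+1,j-1) is also paired.
    Traceback prefers pairing the 5'-most base, then the nearest partner.
    """

    name = "fallback-bpmax"
    max_ensemble_length = 30

    def fold(self, seq: str) -> tuple[str, float]:
        rna = to_rna(seq.upper())
        n = len(rna)
        if n == 0:
            return "", 0.0
        can = _pair_matrix(rna)
        V, W = _mfe_tables(can, n)
        db = ["."] * n
        _traceback(0, n - 1, can, V, W, db, paired_mode=False)
        return "".join(db), float(W[0, n - 1])

    def energy_of(self, seq: str, dotbracket: str) -> float:
        """Recompute the model energy of an explicit structure."""
        pairs = set(_parse_pairs(dotbracket))
        stacks = sum(1 for (i, j) in pairs if (i + 1, j - 1) in pairs)
        return float(-(len(pairs) + stacks))

    def ensemble(self, seq: str) -> tuple[float, float, float]:
        """(MFEE, diversity, frequency) by exact partition function.

        Refuses sequences above ``max_ensemble_length``: a thermodynamic
        engine is required for precursor-scale inputs.
        """
        rna = to_rna(seq.upper())
        n = len(rna)
        if n > self.max_ensemble_length:
            raise EngineRequiredError(
                f"fallback ensemble limited to {self.max_ensemble_length} nt "
                f"(got {n}); configure a thermodynamic engine"
            )
        _, mfe = self.fold(rna)
        if n == 0:
            return 0.0, 0.0, 1.0
        can = _pair_matrix(rna)
        z_total, probs = _partition_function(can, n)
        mfee = -RT * math.log(z_total)
        frequency = math.exp((mfee - mfe) / RT)
        diversity = float(np.sum(2.0 * probs * (1.0 - probs)))
        return mfee, diversity, frequency


def _pair_matrix(rna: str) -> np.ndarray:
    n = len(rna)
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            if pairable(rna[i], rna[j]):
                can[i, j] = True
    return can


def _mfe_tables(can: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    INF = 1e9
    V = np.full((n, n), INF)
    # W padded with one extra row/col so W[k+1, j] is always indexable
    W = np.zeros((n + 1, n + 1))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can[i, j]:
                inner = 0.0
                if j - i - 1 > MIN_LOOP:
                    stack = (V[i + 1, j - 1] - 1.0) if can[i + 1, j - 1] else INF
                    inner = min(W[i + 1, j - 1], stack)
                V[i, j] = -1.0 + inner
            # W recurrence
            ks = np.nonzero(can[i, i + MIN_LOOP + 1 : j + 1])[0] + i + MIN_LOOP + 1
            best = W[i + 1, j]
            if ks.size:
                cand = V[i, ks] + W[ks + 1, j]
                best = min(best, float(cand.min()))
            W[i, j] = best
    return V, W


def _traceback(i, j, can, V, W, db, paired_mode) -> None:
    while True:
        if i >= j:
            return
        if paired_mode:
            db[i], db[j] = "(", ")"
            ii, jj = i + 1, j - 1
            if jj - ii <= MIN_LOOP:
                return
            if can[ii, jj] and abs((V[i, j] + 1.0) - (V[ii, jj] - 1.0)) < 1e-9:
                i, j = ii, jj
                continue
            i, j, paired_mode = ii, jj, False
            continue
        # W mode: prefer pairing i, nearest partner first
        target = W[i, j]
        if target == 0.0:
            return
        found = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            if can[i, k] and abs(V[i, k] + W[k + 1, j] - target) < 1e-9:
                _traceback(i, k, can, V, W, db, paired_mode=True)
                i, paired_mode = k + 1, False
                found = True
                break
        if not found:
            i += 1


def _partition_function(can: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    """Exact inside/outside over the fallback energy model.

    Returns (Z, pair probability matrix). Weight of a structure is
    exp(-(E)/RT) with E from ``FallbackEngine.energy_of``.
    """
    wp = math.exp(1.0 / RT)  # weight per pair
    ws = math.exp(1.0 / RT)  # extra weight per stack
    Z = np.ones((n + 1, n + 1))  # Z[i][j] over [i, j-1]... use closed [i,j]
    Zb = np.zeros((n, n))

    def z_at(i, j):  # total partition over closed [i, j]; empty -> 1
        return Z[i, j] if i <= j else 1.0

    Z = np.ones((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if can[i, j]:
                inner_total = z_at(i + 1, j - 1)
                inner_zb = Zb[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
                Zb[i, j] = wp * ((inner_total - inner_zb) + ws * inner_zb)
            total = z_at(i + 1, j)
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can[i, k]:
                    total += Zb[i, k] * z_at(k + 1, j)
            Z[i, j] = total

    z_total = Z[0, n - 1] if n > 1 else 1.0

    # outside pass
    S = np.zeros((n, n))  # segment [i,j] appearing as a free Z-factor
    O = np.zeros((n, n))  # exterior weight of pair (i,j)
    if n > 1:
        S[0, n - 1] = 1.0
    for span in range(n - 1, 0, -1):
        for i in range(0, n - span):
            j = i + span
            s_ij = S[i, j]
            if s_ij != 0.0:
                if i + 1 <= j:
                    S[i + 1, j] += s_ij
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if can[i, k]:
                        O[i, k] += s_ij * z_at(k + 1, j)
                        if k + 1 <= j:
                            S[k + 1, j] += s_ij * Zb[i, k]
            o_ij = O[i, j]
            if o_ij != 0.0 and can[i, j]:
                if i + 1 <= j - 1:
                    S[i + 1, j - 1] += o_ij * wp
                    if can[i + 1, j - 1]:
                        O[i + 1, j - 1] += o_ij * wp * (ws - 1.0)

    probs = O * Zb / z_total
    return float(z_total), probs


# ---------------------------------------------------------------------------
# ViennaRNA engine
# ---------------------------------------------------------------------------


class ViennaEngine:
    """ViennaRNA (RNAfold) engine; MFE and ensemble at 37 degC, kcal/mol."""

    name = "viennarna"

    def __init__(self) -> None:
        import RNA  # noqa: F401 -- lazy; raises ImportError when absent

        self._rna = RNA
        self.name = f"viennarna-{getattr(RNA, '__version__', '?')}"

    def fold(self, seq: str) -> tuple[str, float]:
        fc = self._rna.fold_compound(to_rna(seq.upper()))
        ss, mfe = fc.mfe()
        return ss, float(mfe)

    def ensemble(self, seq: str) -> tuple[float, float, float]:
        fc = self._rna.fold_compound(to_rna(seq.upper()))
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, mfee = fc.pf()
        diversity = float(fc.mean_bp_distance())
        frequency = math.exp((mfee - mfe) / RT)
        return float(mfee), diversity, min(frequency, 1.0)


_ENGINES: dict[str, object] = {}


def get_engine(name: str | None = None):
    """Resolve an engine by name: 'fallback', 'vienna', 'auto', or None.

    None and 'fallback' give the built-in engine; 'auto' prefers ViennaRNA
    when its bindings are importable and falls back otherwise.
    """
    key = name or "fallback"
    if key in _ENGINES:
        return _ENGINES[key]
    if key == "fallback":
        eng = FallbackEngine()
    elif key == "vienna":
        eng = ViennaEngine()
    elif key == "auto":
        try:
            eng = ViennaEngine()
        except ImportError:
            eng = FallbackEngine()
    else:
        raise ValueError(f"unknown folding engine {name!r}")
    _ENGINES[key] = eng
    return eng


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _check_n_fraction(seq: str) -> None:
    if seq and seq.upper().count("N") / len(seq) > 0.10:
        raise ValueError("sequence has >10% N; refusing to fold")


def fold(seq: str, engine=None) -> tuple[SecondaryStructure, float]:
    """Minimum-free-energy structure of ``seq`` under the given engine."""
    _check_n_fraction(seq)
    eng = engine if engine is not None and not isinstance(engine, str) else get_engine(engine)
    db, mfe = eng.fold(seq)
    return SecondaryStructure(db), mfe


def ensemble_stats(seq: str, engine=None) -> tuple[float, float, float]:
    """(MFEE, ensemble diversity, MFE-structure frequency)."""
    _check_n_fraction(seq)
    eng = engine if engine is not None and not isinstance(engine, str) else get_engine(engine)
    return eng.ensemble(seq)


def amfe(mfe: float, length: int) -> float:
    """MFE normalized to 100 nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return mfe / length * 100.0


def mfei(amfe_value: float, gc_percent: float) -> float:
    """Minimal free energy index, |AMFE| / GC%, as a positive magnitude."""
    if gc_percent <= 0:
        raise ValueError("GC% must be positive for MFEI")
    return abs(amfe_value) / gc_percent


def base_composition(seq: str) -> BaseComposition:
    """Percent composition over non-N residues (T counted as U)."""
    if not seq:
        raise ValueError("empty sequence")
    rna = to_rna(seq.upper())
    counts = {b: rna.count(b) for b in "AUCG"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence is all N")
    return BaseComposition(
        a=counts["A"] / total * 100.0,
        u=counts["U"] / total * 100.0,
        c=counts["C"] / total * 100.0,
        g=counts["G"] / total * 100.0,
    )


def place_mature(
    structure: SecondaryStructure,
    mature_interval: tuple[int, int],
    seq: str,
    min_side_stem: int = 3,
) -> MatureArmPlacement:
    """Assign the mature to the 5p or 3p arm relative to the terminal loop.

    0-based half-open ``mature_interval`` within the precursor. Raises
    :class:`AmbiguousHairpinError` when more than one loop closes a stem of
    depth >= ``min_side_stem`` (multi-branched at the mature site), and
    :class:`LoopOverlapError` when the mature spans the loop.
    """
    start, end = mature_interval
    if not (0 <= start < end <= len(structure.dotbracket)):
        raise ValueError("mature interval outside precursor bounds")
    loops = structure.hairpin_loops()
    deep = [t for t in loops if t[2] >= min_side_stem]
    if len(deep) > 1:
        raise AmbiguousHairpinError(
            f"{len(deep)} competing stems of depth >= {min_side_stem}"
        )
    loop_start, loop_end = structure.loop_interval()
    if end <= loop_start:
        arm = "5p"
    elif start >= loop_end:
        arm = "3p"
    else:
        raise LoopOverlapError("mature interval overlaps the terminal loop")
    first = to_rna(seq[start].upper())
    return MatureArmPlacement(arm=arm, start=start, end=end, first_nt=first)


def characterize(
    seq: str, engine=None, with_ensemble: bool = True
) -> tuple[SecondaryStructure, ThermoProfile, BaseComposition]:
    """Fold and compute the full descriptor block for one precursor."""
    eng = engine if engine is not None and not isinstance(engine, str) else get_engine(engine)
    structure, mfe = fold(seq, eng)
    comp = base_composition(seq)
    a = amfe(mfe, len(seq))
    index = mfei(a, comp.gc) if comp.gc > 0 else float("nan")
    mfee = diversity = frequency = None
    if with_ensemble:
        try:
            mfee, diversity, frequency = eng.ensemble(seq)
        except EngineRequiredError:
            pass
    profile = ThermoProfile(
        mfe=mfe,
        amfe=a,
        mfei=index,
        mfee=mfee,
        diversity=diversity,
        frequency=frequency,
        engine=eng.name,
    )
    return structure, profile, comp
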