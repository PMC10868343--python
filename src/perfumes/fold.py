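"""Secondary-structure folding engines with hard constraints.

Two engines implement the same contract:

* :class:`InternalEngine` — a minimal nearest-neighbour-flavoured model
  (per-pair and per-stack energies in arbitrary units) whose MFE,
  partition function and Boltzmann sampler are exactly verifiable by
  exhaustive enumeration on short sequences.
* :class:`ViennaRNAEngine` — an adapter to the Turner-parameter engine
  of the ViennaRNA package, for realistic analyses.

A *hard constraint* forces a set of positions to stay unpaired and a
non-crossing set of pairs to be present; the constrained ensemble is the
set of structures satisfying all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from . import _kernels
from ._kernels import INF

ALPHABET = "ACGU"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
# allowed pairs: Watson-Crick + wobble
_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ("AU", "UA", "GC", "CG", "GU", "UG"):
    _CAN_PAIR[_IDX[_a], _IDX[_b]] = True


class FoldError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IDX[c] for c in seq], dtype=np.int64)
    except KeyError as e:
        raise FoldError(f"non-ACGU character in sequence: {e.args[0]!r}")


@dataclass(frozen=True)
class FoldConstraint:
    """Hard folding constraint: forced-unpaired positions and forced pairs.

    Coordinates are 0-based; forced pairs are (i, j) with i < j and must
    be mutually non-crossing and endpoint-disjoint.
    """

    length: int
    forced_unpaired: frozenset = field(default_factory=frozenset)
    forced_pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        fu = frozenset(self.forced_unpaired)
        fp = frozenset((min(i, j), max(i, j)) for i, j in self.forced_pairs)
        object.__setattr__(self, "forced_unpaired", fu)
        object.__setattr__(self, "forced_pairs", fp)
        for p in fu:
            if not (0 <= p < self.length):
                raise FoldError(f"forced-unpaired position {p} outside sequence")
        ends = set()
        for i, j in fp:
            if not (0 <= i < j < self.length):
                raise FoldError(f"forced pair {(i, j)} outside sequence")
            if i in ends or j in ends:
                raise FoldError(f"position in more than one forced pair: {(i, j)}")
            ends.update((i, j))
        if ends & fu:
            raise FoldError("position both forced unpaired and forced paired")
        pairs = sorted(fp)
        for a, b in pairs:
            for c, d in pairs:
                if a < c < b < d:
                    raise FoldError(f"crossing forced pairs {(a, b)} and {(c, d)}")

    def to_string(self) -> str:
        """RNAfold-style constraint line: 'x' unpaired, '('/')' pair, '.' free."""
        out = ["."] * self.length
        for p in self.forced_unpaired:
            out[p] = "x"
        for i, j in self.forced_pairs:
            out[i] = "("
            out[j] = ")"
        return "".join(out)

    @classmethod
    def from_string(cls, s: str) -> "FoldConstraint":
        unpaired = {i for i, c in enumerate(s) if c == "x"}
        stack, pairs = [], set()
        for i, c in enumerate(s):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise FoldError("unbalanced ')' in constraint string")
                pairs.add((stack.pop(), i))
            elif c not in ".x":
                raise FoldError(f"unknown constraint character {c!r}")
        if stack:
            raise FoldError("unbalanced '(' in constraint string")
        return cls(len(s), frozenset(unpaired), frozenset(pairs))


@dataclass
class FoldResult:
    structure: str
    energy: float
    valid: bool = True


@dataclass
class EnsembleResult:
    log_partition: float
    n_structures: Optional[int] = None


def pairs_to_dotbracket(n: int, pairs) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def dotbracket_to_pairs(db: str) -> frozenset:
    stack, pairs = [], set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.add((stack.pop(), i))
    return frozenset(pairs)


def partner_array(db: str) -> np.ndarray:
    arr = np.full(len(db), -1, dtype=np.int64)
    for i, j in dotbracket_to_pairs(db):
        arr[i] = j
        arr[j] = i
    return arr


class InternalEngine:
    """Exactly-testable engine: E = n_pairs*e_pair + n_stacks*e_stack.

    Units are arbitrary (negative = stabilising); ``rt`` sets the
    Boltzmann temperature scale in the same units.  Hairpin loops must
    contain at least ``min_loop`` unpaired nucleotides; lonely pairs are
    permitted.
    """

    name = "internal"

    def __init__(self, e_pair: float = -1.0, e_stack: float = -1.0,
                 min_loop: int = 3, rt: float = 1.0):
        if rt <= 0:
            raise FoldError("rt must be positive")
        self.e_pair = float(e_pair)
        self.e_stack = float(e_stack)
        self.min_loop = int(min_loop)
        self.rt = float(rt)

    # -- constraint masks ------------------------------------------------
    def _masks(self, pseq: np.ndarray, constraint: Optional[FoldConstraint]):
        n = len(pseq)
        allowed = np.zeros((n, n), dtype=np.bool_)
        for i in range(n):
            for j in range(i + self.min_loop + 1, n):
                allowed[i, j] = _CAN_PAIR[pseq[i], pseq[j]]
        can_unpair = np.ones(n, dtype=np.bool_)
        if constraint is not None:
            if constraint.length != n:
                raise FoldError("constraint length does not match sequence")
            for p in constraint.forced_unpaired:
                allowed[p, :] = False
                allowed[:, p] = False
            forced_ends = {}
            for i, j in constraint.forced_pairs:
                forced_ends[i] = j
                forced_ends[j] = i
            for p, q in forced_ends.items():
                can_unpair[p] = False
                keep = allowed[min(p, q), max(p, q)]
                allowed[p, :] = False
                allowed[:, p] = False
                allowed[min(p, q), max(p, q)] = keep
        return allowed, can_unpair

    # -- contract --------------------------------------------------------
    def mfe(self, seq: str, constraint: Optional[FoldConstraint] = None) -> FoldResult:
        pseq = encode(seq)
        n = len(pseq)
        if n == 0:
            return FoldResult("", 0.0, True)
        allowed, can_unpair = self._masks(pseq, constraint)
        E, Eb, Enp = _kernels.mfe_tables(n, allowed, can_unpair,
                                         self.e_pair, self.e_stack)
        if E[0, n - 1] >= INF / 2:
            return FoldResult("", math.nan, False)
        partner = _kernels.mfe_traceback(n, E, Eb, Enp, allowed, can_unpair,
                                         self.e_pair, self.e_stack)
        pairs = [(i, int(partner[i])) for i in range(n) if partner[i] > i]
        return FoldResult(pairs_to_dotbracket(n, pairs), float(E[0, n - 1]), True)

    def partition(self, seq: str, constraint: Optional[FoldConstraint] = None,
                  rt: Optional[float] = None) -> EnsembleResult:
        rt = self.rt if rt is None else float(rt)
        if rt <= 0:
            raise FoldError("rt must be positive")
        pseq = encode(seq)
        n = len(pseq)
        if n == 0:
            return EnsembleResult(0.0)
        allowed, can_unpair = self._masks(pseq, constraint)
        Z, _, _ = self._pf(pseq, allowed, can_unpair, rt)
        z = Z[0, n - 1]
        if z <= 0.0:
            return EnsembleResult(-math.inf)
        return EnsembleResult(math.log(z))

    def _pf(self, pseq, allowed, can_unpair, rt):
        qpair = math.exp(-self.e_pair / rt)
        qstack = math.exp(-self.e_stack / rt)
        return _kernels.pf_tables(len(pseq), allowed, can_unpair, qpair, qstack)

    def sample(self, seq: str, constraint: Optional[FoldConstraint] = None,
               rt: Optional[float] = None, n: int = 1, seed: int = 0) -> list:
        rt = self.rt if rt is None else float(rt)
        pseq = encode(seq)
        ln = len(pseq)
        if ln == 0:
            return [""] * n
        allowed, can_unpair = self._masks(pseq, constraint)
        Z, Zb, Znp = self._pf(pseq, allowed, can_unpair, rt)
        if Z[0, ln - 1] <= 0.0:
            raise FoldError("unsatisfiable constraint: empty ensemble")
        qpair = math.exp(-self.e_pair / rt)
        qstack = math.exp(-self.e_stack / rt)
        partners = _kernels.sample_structures(ln, Z, Zb, Znp, allowed, can_unpair,
                                              qpair, qstack, n, seed % (2 ** 31))
        out = []
        for s in range(n):
            pairs = [(i, int(partners[s, i])) for i in range(ln) if partners[s, i] > i]
            out.append(pairs_to_dotbracket(ln, pairs))
        return out


# -- exhaustive oracle ---------------------------------------------------

def structure_energy(pairs, e_pair: float = -1.0, e_stack: float = -1.0) -> float:
    """Energy of a structure counted directly from its pair set."""
    ps = set(pairs)
    stacks = sum(1 for (i, j) in ps if (i + 1, j - 1) in ps)
    return len(ps) * e_pair + stacks * e_stack


def enumerate_structures(seq: str,
                         constraint: Optional[FoldConstraint] = None,
                         min_loop: int = 3) -> Iterator[frozenset]:
    """Yield every admissible structure as a frozenset of pairs.

    Brute-force recursion over intervals; intended for short sequences
    where it serves as an independent oracle for the DP engine.
    """
    pseq = encode(seq)
    n = len(pseq)
    eng = InternalEngine(min_loop=min_loop)
    allowed, can_unpair = eng._masks(pseq, constraint)

    def rec(i, j):
        if j < i:
            yield frozenset()
            return
        if can_unpair[j]:
            yield from rec(i, j - 1)
        for k in range(i, j):
            if allowed[k, j]:
                for left in rec(i, k - 1):
                    for inner in rec(k + 1, j - 1):
                        yield left | inner | {(k, j)}

    if n == 0:
        yield frozenset()
        return
    yield from rec(0, n - 1)


def enumerate_partition(seq: str, constraint: Optional[FoldConstraint] = None,
                        rt: float = 1.0, e_pair: float = -1.0,
                        e_stack: float = -1.0, min_loop: int = 3) -> EnsembleResult:
    """Partition function by explicit summation over all structures."""
    z = 0.0
    count = 0
    for s in enumerate_structures(seq, constraint, min_loop):
        z += math.exp(-structure_energy(s, e_pair, e_stack) / rt)
        count += 1
    return EnsembleResult(math.log(z) if z > 0 else -math.inf, count)


# -- constraint construction from a motif hit ---------------------------

MODES = ("loop_only", "closed", "stacked")


def build_constraint(seq_len: int, hit, mode: str = "closed") -> FoldConstraint:
    """Constraint describing 'the structure contains this loop placement'.

    ``loop_only`` forces loop nucleotides unpaired; ``closed`` also
    forces the closing pair(s); ``stacked`` additionally forces, for
    each closing pair, the adjacent pair on its far (helix) side.
    """
    if mode not in MODES:
        raise FoldError(f"unknown constraint mode {mode!r}")
    unpaired = set()
    for a, b in hit.strand_spans:
        unpaired.update(range(a, b))
    pairs = set()
    if mode in ("closed", "stacked"):
        pairs.update((min(i, j), max(i, j)) for i, j in hit.closing_pair_coords)
    if mode == "stacked":
        closings = sorted((min(i, j), max(i, j)) for i, j in hit.closing_pair_coords)
        outer = closings[0]
        if outer[0] - 1 < 0 or outer[1] + 1 >= seq_len:
            raise FoldError("stacked mode: no room for outward pair at sequence boundary")
        pairs.add((outer[0] - 1, outer[1] + 1))
        for c, d in closings[1:]:
            # inner closing pair of an internal loop: stack away from the loop
            pairs.add((c + 1, d - 1))
    return FoldConstraint(seq_len, frozenset(unpaired), frozenset(pairs))


# -- ViennaRNA adapter ---------------------------------------------------

class ViennaRNAEngine:
    """Adapter to ViennaRNA's Turner-model engine (kcal/mol units).

    Satisfies the same constraint-semantics contract as the internal
    engine; sampling determinism depends on ViennaRNA's global RNG.
    """

    name = "viennarna"
    RT_KCAL = 0.6163207755  # kcal/mol at 37 C

    def __init__(self):
        import RNA  # deferred: optional dependency
        self._RNA = RNA
        self.rt = self.RT_KCAL

    def _compound(self, seq, constraint):
        RNA = self._RNA
        fc = RNA.fold_compound(seq)
        if constraint is not None:
            for p in constraint.forced_unpaired:
                fc.hc_add_up(p + 1, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS)
            for i, j in constraint.forced_pairs:
                fc.hc_add_bp(i + 1, j + 1,
                             RNA.CONSTRAINT_CONTEXT_ALL_LOOPS
                             | RNA.CONSTRAINT_CONTEXT_ENFORCE)
        return fc

    def mfe(self, seq, constraint=None):
        fc = self._compound(seq, constraint)
        db, e = fc.mfe()
        if constraint is not None and not _satisfies(db, constraint):
            return FoldResult("", math.nan, False)
        return FoldResult(db, float(e), True)

    def partition(self, seq, constraint=None, rt=None):
        fc = self._compound(seq, constraint)
        _, dg = fc.pf()
        return EnsembleResult(-float(dg) / self.RT_KCAL)

    def sample(self, seq, constraint=None, rt=None, n=1, seed=0):
        self._RNA.init_rand(int(seed) % (2 ** 31))
        fc = self._compound(seq, constraint)
        fc.pf()
        return list(fc.pbacktrack(n))


def _satisfies(db: str, constraint: FoldConstraint) -> bool:
    arr = partner_array(db)
    for p in constraint.forced_unpaired:
        if arr[p] != -1:
            return False
    for i, j in constraint.forced_pairs:
        if arr[i] != j:
            return False
    return True


def get_engine(name: str = "internal", **kwargs):
    if name == "internal":
        return InternalEngine(**kwargs)
    if name == "viennarna":
        return ViennaRNAEngine()
    raise FoldError(f"unknown engine {name!r}")
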