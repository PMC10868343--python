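"""Dinucleotide-preserving sequence shuffles.

The null model for motif scoring requires shuffled sequences with the
exact overlapping-2-mer counts of the original, so that local
composition cannot create spurious score signal.  The Altschul–Erikson
construction is used: build the multigraph whose edges are the
dinucleotides, pick a random last edge out of every vertex such that the
chosen edges form a tree toward the final nucleotide (guaranteeing an
Eulerian path ending there), shuffle the remaining edge lists, and read
the path off.  Endpoints are preserved exactly.  The standard
last-edge randomisation does not weight all Eulerian paths uniformly;
this mild bias is accepted and documented.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import List

ALPHABET = "ACGU"


class ShuffleError(ValueError):
    pass


def dinucleotide_counts(seq: str) -> dict:
    counts = {}
    for i in range(len(seq) - 1):
        d = seq[i:i + 2]
        counts[d] = counts.get(d, 0) + 1
    return counts


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Random shuffle of ``seq`` preserving all 16 dinucleotide counts
    and both terminal nucleotides."""
    for c in seq:
        if c not in ALPHABET:
            raise ShuffleError(f"non-ACGU character {c!r}")
    n = len(seq)
    if n <= 2:
        return seq
    # adjacency: vertex -> multiset of successors (fixed alphabet order so
    # RNG consumption is independent of string hashing)
    succ = {c: [] for c in ALPHABET if c in seq}
    for i in range(n - 1):
        succ[seq[i]].append(seq[i + 1])
    last = seq[-1]
    vertices = [v for v in succ if v != last and succ[v]]
    # choose a random last edge per vertex until they form a spanning
    # tree toward `last` (every chosen chain reaches `last`)
    while True:
        last_edge = {v: rng.choice(succ[v]) for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:  # dead end or cycle
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    out_edges = {}
    for v, edges in succ.items():
        edges = list(edges)
        if v in last_edge:
            edges.remove(last_edge[v])
        rng.shuffle(edges)
        if v in last_edge:
            edges.append(last_edge[v])
        out_edges[v] = edges
    # walk the Eulerian path
    result = [seq[0]]
    ptr = {v: 0 for v in out_edges}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = out_edges[cur][ptr[cur]]
        ptr[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


@dataclass
class ShuffleBatch:
    original: str
    shuffles: List[str]
    seed: int = 0

    def check(self) -> bool:
        ref = dinucleotide_counts(self.original)
        for s in self.shuffles:
            if len(s) != len(self.original):
                return False
            if self.original and (s[0] != self.original[0] or s[-1] != self.original[-1]):
                return False
            if dinucleotide_counts(s) != ref:
                return False
        return True


def make_shuffle_batch(seq: str, n_shuffles: int = 100, seed: int = 0) -> ShuffleBatch:
    if n_shuffles < 1:
        raise ShuffleError("n_shuffles must be >= 1")
    rng = random.Random(seed)
    return ShuffleBatch(seq, [dinucleotide_shuffle(seq, rng) for _ in range(n_shuffles)],
                        seed)
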