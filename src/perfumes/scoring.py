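"""Tree-Bayesian-network motif scoring and shuffle-null calibration.

Each motif is scored with a directed tree Bayesian network over its
model positions (loop nucleotides plus closing-pair nucleotides).  The
dependency graph combines the strand backbone, the closing pair(s) and
any annotated within-loop interactions; it is reduced to a maximum
spanning tree under empirical mutual information of the instance
alignment, so the strongest pairwise couplings survive.  Scores are
log-odds in bits against an i.i.d. background.

Candidate placements on a target sequence are loops of matching size
extracted from the MFE structure and from Boltzmann samples of a
folding engine.  Significance is calibrated per (sequence, motif): the
best-hit score is compared to a normal fit of best-hit scores on
dinucleotide-preserving shuffles of the same sequence.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .fold import partner_array
from .motif_library import LoopMotif
from .shuffle import make_shuffle_batch

_IDX = {c: i for i, c in enumerate("ACGU")}
LOG2 = math.log(2.0)


class ScoringError(ValueError):
    pass


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary labelled parts (below 2**31)."""
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# model

@dataclass
class MotifBNModel:
    motif_id: str
    loop_type: str
    strand_lengths: List[int]
    closing_pairs: List[Tuple[int, int]]
    n_positions: int
    tree_edges: List[Tuple[int, int]]          # (parent, child), rooted at 0
    root: int
    root_marginal: np.ndarray                  # (4,)
    cpts: Dict[int, np.ndarray]                # child -> (4, 4) rows: parent symbol
    background: np.ndarray                     # (4,)
    pseudocount: float = 1.0

    def parent_of(self) -> Dict[int, int]:
        return {c: p for p, c in self.tree_edges}


def _mutual_information(col_i: np.ndarray, col_j: np.ndarray) -> float:
    n = len(col_i)
    joint = np.zeros((4, 4))
    for a, b in zip(col_i, col_j):
        joint[a, b] += 1
    joint /= n
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    mi = 0.0
    for a in range(4):
        for b in range(4):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log(joint[a, b] / (pi[a] * pj[b]))
    return mi / LOG2


def train_bn(motif: LoopMotif, pseudocount: float = 1.0,
             background: Optional[Sequence[float]] = None) -> MotifBNModel:
    """Fit the tree BN to the motif's aligned instances."""
    if not motif.instances:
        raise ScoringError(f"{motif.motif_id}: cannot train on zero instances")
    if pseudocount < 0:
        raise ScoringError("pseudocount must be >= 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ScoringError("background must be a positive length-4 probability vector")

    npos = motif.n_positions
    data = np.array([[_IDX[c] for c in motif.instance_model_sequence(inst)]
                     for inst in motif.instances], dtype=np.int64)
    if data.shape[1] != npos:
        raise ScoringError(f"{motif.motif_id}: instance length mismatch")

    # dependency graph: backbone + closing pairs + annotated interactions
    edges = set()
    start = 0
    for width in motif.strand_position_lengths:
        for p in range(start, start + width - 1):
            edges.add((p, p + 1))
        start += width
    for i, j in motif.closing_pairs:
        edges.add((min(i, j), max(i, j)))
    for i, j, _lab in motif.interactions:
        if i != j:
            edges.add((min(i, j), max(i, j)))

    weighted = sorted(((-_mutual_information(data[:, i], data[:, j]), i, j)
                       for i, j in edges))
    # Kruskal maximum spanning tree, ties broken lexicographically
    parent = list(range(npos))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for _negmi, i, j in weighted:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j))

    # orient from root 0 by BFS
    adj: Dict[int, List[int]] = {p: [] for p in range(npos)}
    for i, j in tree:
        adj[i].append(j)
        adj[j].append(i)
    root = 0
    oriented = []
    seen = {root}
    queue = [root]
    while queue:
        u = queue.pop(0)
        for v in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                oriented.append((u, v))
                queue.append(v)
    if len(seen) != npos:
        raise ScoringError(f"{motif.motif_id}: dependency graph is not connected")

    n = data.shape[0]
    counts_root = np.bincount(data[:, root], minlength=4).astype(float)
    root_marginal = (counts_root + pseudocount) / (n + 4 * pseudocount)
    cpts = {}
    for p, c in oriented:
        joint = np.zeros((4, 4))
        for a, b in zip(data[:, p], data[:, c]):
            joint[a, b] += 1
        table = joint + pseudocount
        rows = table.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            table = np.where(rows > 0, table / rows, 0.25)
        cpts[c] = table
    return MotifBNModel(
        motif_id=motif.motif_id, loop_type=motif.loop_type,
        strand_lengths=list(motif.strand_lengths),
        closing_pairs=list(motif.closing_pairs), n_positions=npos,
        tree_edges=oriented, root=root, root_marginal=root_marginal,
        cpts=cpts, background=bg, pseudocount=pseudocount)


def score_loop(model: MotifBNModel, loop_seq: str) -> float:
    """Log-odds (bits) of the loop sequence under the motif BN vs background."""
    s = loop_seq.replace("&", "")
    if len(s) != model.n_positions:
        raise ScoringError(
            f"loop length {len(s)} does not match model ({model.n_positions})")
    try:
        sym = [_IDX[c] for c in s]
    except KeyError as e:
        raise ScoringError(f"non-ACGU character {e.args[0]!r}")
    p = model.root_marginal[sym[model.root]]
    if p <= 0.0:
        return -math.inf
    logp = math.log2(p)
    for parent, child in model.tree_edges:
        p = model.cpts[child][sym[parent], sym[child]]
        if p <= 0.0:
            return -math.inf
        logp += math.log2(p)
    logbg = sum(math.log2(model.background[a]) for a in sym)
    return logp - logbg


# ---------------------------------------------------------------------------
# hits

@dataclass
class MotifHit:
    sequence_id: str
    motif_id: str
    strand_spans: List[Tuple[int, int]]        # 0-based half-open, loop only
    closing_pair_coords: List[Tuple[int, int]]
    score: float
    variant: str = ""                          # model-coordinate sequence, '&'-separated
    p_value: Optional[float] = None
    null: Optional["NullDistribution"] = None


@dataclass
class NullDistribution:
    sequence_id: str
    motif_id: str
    mean: float
    sd: float
    n: int
    n_sentinel: int = 0


def fit_null(scores: Sequence[float], sd_floor: float = 0.05,
             sequence_id: str = "", motif_id: str = "",
             n_sentinel: int = 0) -> NullDistribution:
    if len(scores) < 2:
        raise ScoringError("need at least 2 scores to fit a null")
    arr = np.asarray(scores, float)
    sd = float(arr.std(ddof=1))
    return NullDistribution(sequence_id, motif_id, float(arr.mean()),
                            max(sd, sd_floor), len(arr), n_sentinel)


def score_p_value(score: float, null: NullDistribution) -> float:
    p = float(norm.sf((score - null.mean) / null.sd))
    return min(max(p, 1e-300), 1.0 - 1e-16)


def best_hit(hits: Sequence[MotifHit]) -> Optional[MotifHit]:
    """Maximum-score hit; ties broken by leftmost first span then motif id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, h.strand_spans[0][0], h.motif_id))


# ---------------------------------------------------------------------------
# candidate enumeration

def extract_loops(db: str):
    """Hairpin loops [(a, b)] and internal loops [((a, b), (c, d))] of a
    dot-bracket structure; (a, b) closes the loop, (c, d) is the inner
    pair of an internal loop."""
    arr = partner_array(db)
    n = len(db)
    hairpins, internals = [], []
    for a in range(n):
        b = int(arr[a])
        if b <= a:
            continue
        children = []
        i = a + 1
        while i < b:
            j = int(arr[i])
            if j > i:
                children.append((i, j))
                i = j + 1
            else:
                i += 1
        if not children:
            hairpins.append((a, b))
        elif len(children) == 1:
            c, d = children[0]
            if (c - a - 1) + (b - d - 1) >= 1:
                internals.append(((a, b), (c, d)))
    return hairpins, internals


def _structures_for(seq: str, engine, n_samples: int, seed: int) -> List[str]:
    res = engine.mfe(seq)
    structures = [res.structure] if res.valid else []
    if n_samples > 0:
        structures.extend(engine.sample(seq, None, None, n_samples, seed))
    return structures


def _placements(seq: str, structures: List[str]):
    """Dedupe loop placements across structures."""
    hp, il = set(), set()
    for db in structures:
        h, i = extract_loops(db)
        hp.update(h)
        il.update(i)
    return sorted(hp), sorted(il)


def _hits_from_placements(seq: str, sequence_id: str, model: MotifBNModel,
                          hairpins, internals,
                          cache: Optional[dict] = None) -> List[MotifHit]:
    def cached_score(key, loop_seq):
        if cache is None:
            return score_loop(model, loop_seq)
        full = (model.motif_id, key)
        if full not in cache:
            cache[full] = score_loop(model, loop_seq)
        return cache[full]

    hits = []
    if model.loop_type == "hairpin":
        (L,) = model.strand_lengths
        for a, b in hairpins:
            if b - a - 1 == L:
                sub = seq[a:b + 1]
                hits.append(MotifHit(
                    sequence_id, model.motif_id, [(a + 1, b)], [(a, b)],
                    cached_score(sub, sub), variant=sub))
    else:
        L1, L2 = model.strand_lengths
        for (a, b), (c, d) in internals:
            if c - a - 1 == L1 and b - d - 1 == L2:
                s1, s2 = seq[a:c + 1], seq[d:b + 1]
                variant = f"{s1}&{s2}"
                hits.append(MotifHit(
                    sequence_id, model.motif_id,
                    [(a + 1, c), (d + 1, b)], [(a, b), (c, d)],
                    cached_score(variant, s1 + s2), variant=variant))
    return hits


def enumerate_candidates(seq: str, model: MotifBNModel, engine,
                         n_samples: int = 20, seed: int = 0,
                         sequence_id: str = "") -> List[MotifHit]:
    hairpins, internals = _placements(seq, _structures_for(seq, engine, n_samples, seed))
    return _hits_from_placements(seq, sequence_id, model, hairpins, internals)


# ---------------------------------------------------------------------------
# calibration

def _best_scores(seq: str, sequence_id: str, models: Sequence[MotifBNModel],
                 engine, n_samples: int, seed: int,
                 cache: Optional[dict] = None) -> Dict[str, Optional[MotifHit]]:
    hairpins, internals = _placements(seq, _structures_for(seq, engine, n_samples, seed))
    out = {}
    for model in models:
        hits = _hits_from_placements(seq, sequence_id, model, hairpins,
                                     internals, cache)
        out[model.motif_id] = best_hit(hits)
    return out


def calibrate_sequence(sequence_id: str, seq: str,
                       models: Sequence[MotifBNModel], engine,
                       n_shuffles: int = 100, n_samples: int = 20,
                       seed: int = 0, threshold: float = 0.05,
                       sd_floor: float = 0.05) -> List[MotifHit]:
    """Best hit per motif with a p-value against the shuffle null.

    The same shuffle batch (and the same folded structures) serves every
    motif.  When a motif has no candidate on a shuffle, its null score
    is a sentinel one bit below the minimum observed score, so the null
    stays defined; the sentinel count is recorded on the null.
    """
    batch = make_shuffle_batch(seq, n_shuffles, derive_seed(seed, sequence_id, "shuffle"))
    cache: dict = {}  # shuffles share composition, so loop k-mers repeat
    orig = _best_scores(seq, sequence_id, models, engine, n_samples,
                        derive_seed(seed, sequence_id, "orig"), cache)
    shuffle_best: List[Dict[str, Optional[MotifHit]]] = []
    for k, shuf in enumerate(batch.shuffles):
        shuffle_best.append(_best_scores(shuf, sequence_id, models, engine,
                                         n_samples,
                                         derive_seed(seed, sequence_id, k), cache))
    calibrated = []
    for model in models:
        mid = model.motif_id
        hit = orig[mid]
        if hit is None:
            continue
        raw = [sb[mid].score if sb[mid] is not None else None for sb in shuffle_best]
        observed = [s for s in raw if s is not None and math.isfinite(s)]
        if math.isfinite(hit.score):
            observed.append(hit.score)
        if not observed:
            continue
        sentinel = min(observed) - 1.0
        scores = [s if (s is not None and math.isfinite(s)) else sentinel for s in raw]
        n_sent = sum(1 for s in raw if s is None or not math.isfinite(s))
        null = fit_null(scores, sd_floor, sequence_id, mid, n_sent)
        p = score_p_value(hit.score, null)
        if p <= threshold:
            hit.p_value = p
            hit.null = null
            calibrated.append(hit)
    return calibrated
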