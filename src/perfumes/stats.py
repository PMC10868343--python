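"""Motif-level enrichment statistics and sequence-variant analysis.

A motif is enriched when the fraction of positive-set sequences carrying
a significant hit exceeds the background fraction.  The default test is
the pooled two-sample proportion z-test (one-sided, enrichment
direction); Fisher's exact test is available for small counts.
Multiple testing across motifs is controlled with Benjamini-Hochberg by
default; method "none" applies the bare per-motif threshold.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact, norm

from .scoring import MotifHit


class StatsError(ValueError):
    pass


@dataclass
class EnrichmentRecord:
    motif_id: str
    k_pos: int
    n_pos: int
    k_bg: int
    n_bg: int
    z: float
    p_raw: float
    p_adj: float = 1.0
    enriched: bool = False


@dataclass
class VariantRecord:
    motif_id: str
    variant: str
    c_pos: int
    c_bg: int
    enrichment_factor: float


def proportion_test(k_pos: int, n_pos: int, k_bg: int, n_bg: int,
                    continuity: bool = False,
                    method: str = "z") -> Tuple[float, float]:
    """One-sided test of p_pos > p_bg.

    ``z`` uses the pooled two-sample z statistic
    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)); ``fisher``
    returns z from the same formula but the one-sided exact p.
    """
    if n_pos <= 0 or n_bg <= 0:
        raise StatsError("sample sizes must be positive")
    if not (0 <= k_pos <= n_pos and 0 <= k_bg <= n_bg):
        raise StatsError("counts must satisfy 0 <= k <= n")
    p1, p2 = k_pos / n_pos, k_bg / n_bg
    pooled = (k_pos + k_bg) / (n_pos + n_bg)
    denom = math.sqrt(pooled * (1 - pooled) * (1 / n_pos + 1 / n_bg))
    if denom == 0.0:
        # pooled proportion 0 or 1: both proportions equal, no evidence
        return 0.0, 1.0 if p1 == p2 else 0.5
    diff = p1 - p2
    if continuity:
        cc = 0.5 * (1 / n_pos + 1 / n_bg)
        diff = math.copysign(max(abs(diff) - cc, 0.0), diff)
    z = diff / denom
    if method == "fisher":
        table = [[k_pos, n_pos - k_pos], [k_bg, n_bg - k_bg]]
        p = float(fisher_exact(table, alternative="greater")[1])
    elif method == "z":
        p = float(norm.sf(z))
    else:
        raise StatsError(f"unknown test method {method!r}")
    return z, p


def adjust_pvalues(p_list: Sequence[float], method: str = "bh") -> List[float]:
    """Benjamini-Hochberg step-up ('bh') or identity ('none')."""
    arr = np.asarray(p_list, float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    if method == "none":
        return [float(p) for p in arr]
    if method != "bh":
        raise StatsError(f"unknown adjustment method {method!r}")
    m = arr.size
    if m == 0:
        return []
    order = np.argsort(arr, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, arr[idx] * m / (rank + 1))
        adj[idx] = running
    return [float(p) for p in adj]


def _presence_counts(hits: Iterable[MotifHit]) -> Dict[str, set]:
    by_motif: Dict[str, set] = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, set()).add(h.sequence_id)
    return by_motif


def motif_enrichment(hits_pos: Sequence[MotifHit], hits_bg: Sequence[MotifHit],
                     n_pos: int, n_bg: int, alpha: float = 0.05,
                     adjust: str = "bh", method: str = "z",
                     continuity: bool = False) -> List[EnrichmentRecord]:
    """Per-motif 2x2 enrichment records over both datasets.

    Counts are sequences with at least one calibrated hit; a motif is
    enriched when its adjusted p-value passes ``alpha`` *and* the
    positive-set proportion is the larger one.
    """
    pos = _presence_counts(hits_pos)
    bg = _presence_counts(hits_bg)
    records = []
    for motif_id in sorted(set(pos) | set(bg)):
        k_pos = len(pos.get(motif_id, ()))
        k_bg = len(bg.get(motif_id, ()))
        z, p = proportion_test(k_pos, n_pos, k_bg, n_bg, continuity, method)
        records.append(EnrichmentRecord(motif_id, k_pos, n_pos, k_bg, n_bg, z, p))
    adj = adjust_pvalues([r.p_raw for r in records], adjust)
    for r, pa in zip(records, adj):
        r.p_adj = pa
        r.enriched = bool(pa <= alpha and r.k_pos / r.n_pos > r.k_bg / r.n_bg)
    return records


def variant_table(hits_pos: Sequence[MotifHit], hits_bg: Sequence[MotifHit],
                  motif_id: str, n_pos: int, n_bg: int,
                  pseudocount: float = 1.0) -> List[VariantRecord]:
    """Sequence variants of one motif with positive-set enrichment factors.

    Each sequence contributes the variant of its (single calibrated)
    best hit; the enrichment factor is the ratio of pseudocounted
    per-dataset frequencies, finite even for variants absent from the
    background.
    """
    mh_pos = [h for h in hits_pos if h.motif_id == motif_id]
    mh_bg = [h for h in hits_bg if h.motif_id == motif_id]
    if not mh_pos and not mh_bg:
        raise StatsError(f"motif {motif_id!r} has no hits in either dataset")
    c_pos = Counter(h.variant for h in mh_pos)
    c_bg = Counter(h.variant for h in mh_bg)
    out = []
    for variant in sorted(set(c_pos) | set(c_bg)):
        cp, cb = c_pos.get(variant, 0), c_bg.get(variant, 0)
        ef = ((cp + pseudocount) / (n_pos + pseudocount)) / \
             ((cb + pseudocount) / (n_bg + pseudocount))
        out.append(VariantRecord(motif_id, variant, cp, cb, ef))
    out.sort(key=lambda r: (-r.c_pos, r.variant))
    return out
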