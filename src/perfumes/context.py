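"""Thermodynamic context of motif hits.

Three per-hit metrics describe how well the surrounding sequence
supports the loop placement: the minimum free energy among structures
compatible with the placement, the Boltzmann probability of folding into
a compatible structure (a constrained-to-unconstrained partition
function ratio), and — for hairpins — the mean length of the helix
stacked on the closing pair across the compatible ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import mannwhitneyu

from .fold import (FoldConstraint, FoldError, build_constraint,
                   enumerate_structures, partner_array, structure_energy)
from .scoring import MotifHit, derive_seed

EXACT_ENUMERATION_MAX_LEN = 14


class ContextError(ValueError):
    pass


@dataclass
class StructureContext:
    sequence_id: str
    motif_id: str
    variant: str
    mfe_constrained: float
    mfe_unconstrained: float
    p_compatible: float
    mode: str
    helix_length_mean: Optional[float] = None
    n_helix_samples: int = 0
    valid: bool = True
    dataset: str = ""                  # 'positive' or 'background'


def compatibility_probability(seq: str, hit: MotifHit, engine,
                              mode: str = "closed",
                              rt: Optional[float] = None) -> float:
    """P(structure compatible with the hit) = Z_constrained / Z."""
    constraint = build_constraint(len(seq), hit, mode)
    zc = engine.partition(seq, constraint, rt).log_partition
    if zc == -math.inf:
        return 0.0
    z = engine.partition(seq, None, rt).log_partition
    return min(math.exp(zc - z), 1.0)


def constrained_mfe_delta(seq: str, hit: MotifHit, engine,
                          mode: str = "closed") -> Tuple[float, float]:
    """(constrained MFE, unconstrained MFE); the first is never lower."""
    constraint = build_constraint(len(seq), hit, mode)
    rc = engine.mfe(seq, constraint)
    ru = engine.mfe(seq)
    if not rc.valid:
        return math.nan, ru.energy
    return rc.energy, ru.energy


def _helix_length(partner: np.ndarray, closing: Tuple[int, int]) -> int:
    """Contiguous stacked pairs outward from the closing pair (which
    counts as 1 when present)."""
    a, b = min(closing), max(closing)
    n = len(partner)
    k = 0
    while a - k >= 0 and b + k < n and partner[a - k] == b + k:
        k += 1
    return k


def mean_helix_length(seq: str, hit: MotifHit, engine, mode: str = "closed",
                      rt: Optional[float] = None, n_samples: int = 1000,
                      seed: int = 0, exact: str = "auto") -> Tuple[float, int]:
    """Boltzmann-mean helix length around a hairpin hit's closing pair.

    Exact by enumeration for short sequences (or ``exact='always'``),
    otherwise the mean over ``n_samples`` stochastic samples of the
    constrained ensemble.  Returns (mean, n_structures_used).
    """
    if len(hit.closing_pair_coords) != 1:
        raise ContextError("mean helix length is defined for hairpin hits only")
    closing = hit.closing_pair_coords[0]
    constraint = build_constraint(len(seq), hit, mode)
    use_exact = exact == "always" or (exact == "auto"
                                      and len(seq) <= EXACT_ENUMERATION_MAX_LEN)
    if use_exact:
        rt_ = engine.rt if rt is None else rt
        num = den = 0.0
        count = 0
        for pairs in enumerate_structures(seq, constraint, engine.min_loop):
            arr = np.full(len(seq), -1, dtype=np.int64)
            for i, j in pairs:
                arr[i] = j
                arr[j] = i
            w = math.exp(-structure_energy(pairs, engine.e_pair, engine.e_stack) / rt_)
            num += w * _helix_length(arr, closing)
            den += w
            count += 1
        if den == 0.0:
            raise ContextError("empty compatible ensemble")
        return num / den, count
    samples = engine.sample(seq, constraint, rt, n_samples,
                            derive_seed(seed, hit.sequence_id, hit.motif_id, "helix"))
    lengths = [_helix_length(partner_array(db), closing) for db in samples]
    return float(np.mean(lengths)), len(lengths)


def hit_context(seq: str, hit: MotifHit, engine, mode: str = "closed",
                rt: Optional[float] = None, n_samples: int = 1000,
                seed: int = 0, helix: bool = True) -> StructureContext:
    """All context metrics for one hit."""
    p = compatibility_probability(seq, hit, engine, mode, rt)
    mfe_c, mfe_u = constrained_mfe_delta(seq, hit, engine, mode)
    hl = None
    nh = 0
    if helix and len(hit.closing_pair_coords) == 1 and p > 0:
        hl, nh = mean_helix_length(seq, hit, engine, mode, rt, n_samples, seed)
    return StructureContext(hit.sequence_id, hit.motif_id, hit.variant,
                            mfe_c, mfe_u, p, mode, hl, nh,
                            valid=not math.isnan(mfe_c))


def _stats(values: Sequence[float]) -> Dict[str, float]:
    arr = np.asarray(values, float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"count": int(arr.size), "mean": float(arr.mean()),
            "median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize_context(contexts: Sequence[StructureContext],
                      by_variant: bool = True) -> List[dict]:
    """Per-(motif, variant) summaries of the two datasets with one-sided
    rank-sum comparisons (positive expected lower MFE, higher
    compatibility probability).

    Each context must carry a dataset label in ``sequence_id`` prefix
    form 'pos:' / 'bg:' or be passed pre-labelled via the ``dataset``
    attribute set by the pipeline.
    """
    groups: Dict[Tuple[str, str], Dict[str, List[StructureContext]]] = {}
    for c in contexts:
        if not c.valid:
            continue
        label = c.dataset
        if not label:
            label = "positive" if c.sequence_id.startswith("pos") else "background"
        key = (c.motif_id, c.variant if by_variant else "")
        groups.setdefault(key, {}).setdefault(label, []).append(c)
    out = []
    for (motif_id, variant), by_label in sorted(groups.items()):
        entry = {"motif_id": motif_id, "variant": variant, "datasets": {}}
        for label, cs in sorted(by_label.items()):
            entry["datasets"][label] = {
                "mfe_constrained": _stats([c.mfe_constrained for c in cs]),
                "p_compatible": _stats([c.p_compatible for c in cs]),
            }
        if "positive" in by_label and "background" in by_label:
            pos, bg = by_label["positive"], by_label["background"]
            if len(pos) >= 1 and len(bg) >= 1:
                entry["tests"] = {
                    "mfe_constrained_less": _ranksum(
                        [c.mfe_constrained for c in pos],
                        [c.mfe_constrained for c in bg], "less"),
                    "p_compatible_greater": _ranksum(
                        [c.p_compatible for c in pos],
                        [c.p_compatible for c in bg], "greater"),
                }
        out.append(entry)
    return out


def _ranksum(x, y, alternative):
    try:
        return float(mannwhitneyu(x, y, alternative=alternative)[1])
    except ValueError:
        return 1.0
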