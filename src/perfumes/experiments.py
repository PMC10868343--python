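"""Reference experiments: exactness, calibration and recovery studies.

These seeded, self-contained studies quantify the behaviour of the
pipeline on synthetic data — shuffle exactness, agreement of the folding
engine with exhaustive enumeration, uniformity of null-calibrated
p-values, type-I error of the enrichment decision, and recovery of a
planted motif against decoys.  They are used by the test suite and by
the reporting script; problem sizes are arguments so callers choose
their own cost/precision trade-off.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .context import compatibility_probability
from .fold import (FoldConstraint, InternalEngine, enumerate_partition,
                   enumerate_structures, structure_energy)
from .motif_library import LoopMotif, MotifLibrary
from .pipeline import RunConfig, run_pipeline
from .scoring import (best_hit, calibrate_sequence, derive_seed,
                      enumerate_candidates, train_bn)
from .shuffle import dinucleotide_shuffle, make_shuffle_batch
from .stats import proportion_test
from .synth import SynthConfig, decoy_motifs, default_motif, generate_datasets


def _random_rna(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


# ---------------------------------------------------------------------------

def shuffle_exactness(n_sequences: int = 1000, shuffles_per_seq: int = 3,
                      seed: int = 0) -> Dict[str, float]:
    """Fraction of shuffles preserving the 16-entry dinucleotide count
    vector and both terminal nucleotides exactly (lengths 10-80)."""
    rng = random.Random(derive_seed(seed, "shuffle-exactness"))
    ok = total = 0
    for _ in range(n_sequences):
        seq = _random_rna(rng.randint(10, 80), rng)
        batch = make_shuffle_batch(seq, shuffles_per_seq, rng.randrange(2 ** 31))
        total += shuffles_per_seq
        if batch.check():
            ok += shuffles_per_seq
        else:
            ok += sum(batch.__class__(seq, [s]).check() for s in batch.shuffles)
    return {"exact_fraction": ok / total, "n": n_sequences}


def fold_oracle_errors(n_sequences: int = 200, n_constraints: int = 50,
                       seed: int = 0, max_len: int = 14) -> Dict[str, float]:
    """Max |DP - enumeration| for MFE and log-partition on short random
    sequences, plus constrained cases; also counts ordering violations
    (constrained MFE below unconstrained, or Z_c above Z)."""
    rng = random.Random(derive_seed(seed, "fold-oracle"))
    eng = InternalEngine()
    mfe_err = logz_err = 0.0
    order_violations = 0
    seqs = [_random_rna(rng.randint(5, max_len), rng) for _ in range(n_sequences)]
    for seq in seqs:
        emin = min(structure_energy(s) for s in enumerate_structures(seq))
        mfe_err = max(mfe_err, abs(eng.mfe(seq).energy - emin))
        logz_err = max(logz_err,
                       abs(eng.partition(seq).log_partition
                           - enumerate_partition(seq).log_partition))
    done = 0
    while done < n_constraints:
        seq = seqs[rng.randrange(len(seqs))]
        n = len(seq)
        fu = frozenset(rng.sample(range(n), rng.randint(0, 2)))
        fp = frozenset()
        if n >= 6:
            i = rng.randrange(0, n - 5)
            j = rng.randrange(i + 4, n)
            if i not in fu and j not in fu:
                fp = frozenset({(i, j)})
        c = FoldConstraint(n, fu, fp)
        ez = enumerate_partition(seq, c).log_partition
        dz = eng.partition(seq, c).log_partition
        if not (math.isinf(ez) and math.isinf(dz)):
            logz_err = max(logz_err, abs(dz - ez))
        if dz > eng.partition(seq).log_partition + 1e-9:
            order_violations += 1
        res = eng.mfe(seq, c)
        energies = [structure_energy(s) for s in enumerate_structures(seq, c)]
        if energies:
            mfe_err = max(mfe_err, abs(res.energy - min(energies)))
            if res.energy < eng.mfe(seq).energy - 1e-9:
                order_violations += 1
        elif res.valid:
            order_violations += 1
        done += 1
    return {"mfe_max_abs_error": mfe_err, "logz_max_abs_error": logz_err,
            "order_violations": order_violations, "n": n_sequences}


def compatibility_oracle(n_cases: int = 60, seed: int = 0) -> Dict[str, float]:
    """Max |Z_c/Z - enumerated compatible Boltzmann mass| over hairpin
    hits on short sequences, and count of mode-monotonicity violations
    (loop_only >= closed >= stacked)."""
    from .scoring import MotifHit, extract_loops
    rng = random.Random(derive_seed(seed, "compat-oracle"))
    eng = InternalEngine()
    max_err = 0.0
    violations = 0
    done = 0
    while done < n_cases:
        seq = _random_rna(rng.randint(10, 14), rng)
        hairpins, _ = extract_loops(eng.mfe(seq).structure)
        hairpins = [(a, b) for a, b in hairpins
                    if a >= 1 and b <= len(seq) - 2]
        if not hairpins:
            continue
        a, b = hairpins[0]
        hit = MotifHit("s", "m", [(a + 1, b)], [(a, b)], 0.0)
        ps = []
        den = enumerate_partition(seq).log_partition
        for mode in ("loop_only", "closed", "stacked"):
            from .fold import build_constraint
            c = build_constraint(len(seq), hit, mode)
            num = enumerate_partition(seq, c).log_partition
            expect = 0.0 if math.isinf(num) else math.exp(num - den)
            got = compatibility_probability(seq, hit, eng, mode)
            max_err = max(max_err, abs(got - expect))
            ps.append(got)
        if not (ps[0] >= ps[1] - 1e-9 and ps[1] >= ps[2] - 1e-9):
            violations += 1
        done += 1
    return {"max_abs_error": max_err, "monotonicity_violations": violations,
            "n": n_cases}


# ---------------------------------------------------------------------------

def calibration_motif() -> LoopMotif:
    """Loop-3 hairpin used for null-calibration studies: the commonest
    loop size under the internal model, so candidate placements are
    abundant on both original and shuffled sequences."""
    return LoopMotif(
        "HL_CAL.1", "hairpin", [3], [(0, 4)], [],
        ["CGCAG", "GAGAC", "CUCAG", "AACAU", "GGAAC", "CACGG", "UGCAA", "GAGCC"])


def null_pvalue_ks(n_replicates: int = 2000, seed: int = 0,
                   seq_length: int = 40, n_shuffles: int = 100,
                   n_samples: int = 4) -> Dict[str, float]:
    """Kolmogorov-Smirnov distance to uniformity of calibrated p-values
    when the 'original' sequence is itself drawn from the shuffle
    distribution (the per-sequence null)."""
    engine = InternalEngine()
    model = train_bn(calibration_motif())
    pvals: List[float] = []
    for rep in range(n_replicates):
        rng = random.Random(derive_seed(seed, "ks-base", rep))
        base = _random_rna(seq_length, rng)
        orig = dinucleotide_shuffle(base, rng)
        hits = calibrate_sequence(f"r{rep}", orig, [model], engine,
                                  n_shuffles, n_samples,
                                  derive_seed(seed, "ks-cal", rep),
                                  threshold=1.0)
        if hits:
            pvals.append(hits[0].p_value)
    p = np.sort(np.asarray(pvals))
    n = len(p)
    ks = float(max(np.max(np.arange(1, n + 1) / n - p),
                   np.max(p - np.arange(0, n) / n)))
    return {"ks_distance": ks, "n": n, "replicates": n_replicates}


def enrichment_type_i(n_tests: int = 2000, seed: int = 0, n_per_set: int = 200,
                      presence_prob: float = 0.14,
                      alpha: float = 0.05) -> Dict[str, float]:
    """Type-I error of the enrichment decision when motif presence is
    equally frequent in both datasets (the planting-model null)."""
    gen = np.random.default_rng(derive_seed(seed, "type1"))
    rejections = 0
    for _ in range(n_tests):
        k_pos = int(gen.binomial(n_per_set, presence_prob))
        k_bg = int(gen.binomial(n_per_set, presence_prob))
        _, p = proportion_test(k_pos, n_per_set, k_bg, n_per_set)
        if p <= alpha and k_pos > k_bg:
            rejections += 1
    return {"type_i_error": rejections / n_tests, "n": n_tests}


# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    n_runs: int
    planted_enriched_rate: float
    decoy_enriched_rate: float
    variant_major_fraction: float   # share of CGCACG among the two planted
    variant_total: int
    mean_p_compatible_planted: float
    mean_p_compatible_decoy: float
    per_run_enriched: List[List[str]] = field(default_factory=list)


def recovery_experiment(n_runs: int = 20, seed: int = 0,
                        n_shuffles: int = 25, n_samples: int = 10,
                        synth_config: Optional[SynthConfig] = None) -> RecoveryResult:
    """Planted-motif recovery under the default synthetic contrast.

    Each run generates a fresh dataset (defaults: 200/200 sequences,
    planting frequencies 0.3 vs 0.05, stem 6), scans it against the
    planted motif plus decoys, and records which motifs were flagged
    enriched (BH-adjusted).  Compatibility probabilities at planted and
    decoy sites are measured on the first run.
    """
    lib = MotifLibrary([default_motif()] + decoy_motifs(), source="synthetic")
    decoy_ids = {m.motif_id for m in decoy_motifs()}
    planted_id = default_motif().motif_id
    planted_hits = decoy_tests = 0
    per_run = []
    c_major = c_minor = 0
    p_planted: List[float] = []
    p_decoy: List[float] = []
    engine = InternalEngine()
    for r in range(n_runs):
        base_cfg = synth_config if synth_config is not None else SynthConfig()
        import dataclasses as _dc
        cfg = _dc.replace(base_cfg, seed=derive_seed(seed, "synth", r))
        pos, bg, truth = generate_datasets(cfg)
        rc = RunConfig(n_shuffles=n_shuffles, n_samples=n_samples,
                       seed=derive_seed(seed, "run", r), workers=1)
        report = run_pipeline(rc, pos, bg, lib)
        enriched = report["enriched_motifs"]
        per_run.append(enriched)
        if planted_id in enriched:
            planted_hits += 1
        decoy_tests += sum(1 for m in enriched if m in decoy_ids)
        for v in report["variant_tables"].get(planted_id, []):
            if v["variant"] == "CGCACG":
                c_major += v["c_pos"]
            elif v["variant"] == "CGCAAG":
                c_minor += v["c_pos"]
        if r == 0:
            seqs = dict(pos)
            from .scoring import MotifHit
            for row in truth:
                if not row.record_id.startswith("pos"):
                    continue
                hit = MotifHit(row.record_id, row.motif_id, row.strand_spans,
                               row.closing_pair_coords, 0.0)
                p_planted.append(compatibility_probability(
                    seqs[row.record_id], hit, engine, "closed"))
            decoy_hits = [h for h in report["hits_pos"] + report["hits_bg"]
                          if h["motif_id"] in decoy_ids]
            all_seqs = dict(pos + bg)
            for h in decoy_hits:
                hit = MotifHit(h["sequence_id"], h["motif_id"],
                               [(a - 1, b) for a, b in h["strand_spans"]],
                               [(i - 1, j - 1) for i, j in h["closing_pairs"]],
                               h["score"])
                p_decoy.append(compatibility_probability(
                    all_seqs[h["sequence_id"]], hit, engine, "closed"))
            if not p_decoy:
                # fall back to best uncalibrated decoy candidates
                models = [train_bn(m) for m in decoy_motifs()]
                for rid, seq in pos[:50]:
                    for model in models:
                        cand = best_hit(enumerate_candidates(
                            seq, model, engine, n_samples, derive_seed(seed, rid)))
                        if cand is not None:
                            p_decoy.append(compatibility_probability(
                                seq, cand, engine, "closed"))
    total_variants = c_major + c_minor
    return RecoveryResult(
        n_runs=n_runs,
        planted_enriched_rate=planted_hits / n_runs,
        decoy_enriched_rate=decoy_tests / (n_runs * len(decoy_ids)),
        variant_major_fraction=c_major / total_variants if total_variants else 0.0,
        variant_total=total_variants,
        mean_p_compatible_planted=float(np.mean(p_planted)) if p_planted else 0.0,
        mean_p_compatible_decoy=float(np.mean(p_decoy)) if p_decoy else 0.0,
        per_run_enriched=per_run)


def determinism_check(seed: int = 0, workers: int = 2) -> Dict[str, bool]:
    """Byte-identity of the pipeline report across reruns and across
    serial vs parallel execution."""
    from .pipeline import report_json
    cfg = SynthConfig(n_pos=25, n_bg=25, seed=derive_seed(seed, "det-synth"))
    pos, bg, _ = generate_datasets(cfg)
    lib = MotifLibrary([default_motif()] + decoy_motifs(), source="synthetic")
    rc = RunConfig(n_shuffles=10, n_samples=5, seed=derive_seed(seed, "det-run"),
                   workers=1)
    r1 = report_json(run_pipeline(rc, pos, bg, lib))
    r2 = report_json(run_pipeline(rc, pos, bg, lib))
    import dataclasses as _dc
    rc_par = _dc.replace(rc, workers=workers)
    r3 = run_pipeline(rc_par, pos, bg, lib)
    # workers is part of the embedded config; compare scientific content
    import json
    r1d, r3d = json.loads(r1), {k: v for k, v in r3.items()
                                if not k.startswith("_")}
    same_parallel = all(
        json.dumps(r1d[k], sort_keys=True) == json.dumps(r3d[k], sort_keys=True)
        for k in ("enrichment", "variant_tables", "context_summaries",
                  "hits_pos", "hits_bg"))
    return {"rerun_identical": r1 == r2, "parallel_identical": same_parallel}
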