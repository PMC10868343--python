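import math
import random

import numpy as np
import pytest

from perfumes.context import (ContextError, StructureContext,
                              compatibility_probability, constrained_mfe_delta,
                              hit_context, mean_helix_length, summarize_context)
from perfumes.fold import (build_constraint, enumerate_partition,
                           enumerate_structures, structure_energy)
from perfumes.scoring import MotifHit
from .conftest import random_rna


def _hairpin_hit(spans, closing, seq_id="s", motif_id="m"):
    return MotifHit(seq_id, motif_id, [spans], [closing], 1.0)


SEQ12 = "GGCAAAGGCCUA"
HIT12 = _hairpin_hit((3, 6), (2, 6))


class TestCompatibility:
    def test_enumeration_equality(self, engine):
        for mode in ("loop_only", "closed", "stacked"):
            c = build_constraint(12, HIT12, mode)
            num = enumerate_partition(SEQ12, c).log_partition
            den = enumerate_partition(SEQ12).log_partition
            expect = 0.0 if math.isinf(num) else math.exp(num - den)
            got = compatibility_probability(SEQ12, HIT12, engine, mode)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_mode_monotonicity(self, engine, rng):
        checked = 0
        while checked < 10:
            seq = random_rna(20, rng)
            db = engine.mfe(seq).structure
            from perfumes.scoring import extract_loops
            hairpins, _ = extract_loops(db)
            hairpins = [(a, b) for a, b in hairpins if a >= 1 and b <= 18]
            if not hairpins:
                continue
            a, b = hairpins[0]
            hit = _hairpin_hit((a + 1, b), (a, b))
            ps = [compatibility_probability(seq, hit, engine, m)
                  for m in ("loop_only", "closed", "stacked")]
            assert ps[0] >= ps[1] - 1e-12 >= ps[2] - 2e-12
            checked += 1

    def test_unsatisfiable_gives_zero(self, engine):
        hit = _hairpin_hit((3, 6), (2, 6))
        # closing pair C-C cannot form
        assert compatibility_probability("GGCAAACCCUAA", hit, engine,
                                         "closed") == 0.0


class TestConstrainedMFE:
    def test_hit_on_own_mfe_loop_zero_delta(self, engine):
        seq = "GGCAGCCGCACGGCUGCC"
        res = engine.mfe(seq)
        from perfumes.scoring import extract_loops
        (a, b), = extract_loops(res.structure)[0]
        hit = _hairpin_hit((a + 1, b), (a, b))
        mc, mu = constrained_mfe_delta(seq, hit, engine, "closed")
        assert mc == pytest.approx(mu)

    def test_matches_enumeration(self, engine):
        c = build_constraint(12, HIT12, "closed")
        energies = [structure_energy(s) for s in enumerate_structures(SEQ12, c)]
        mc, mu = constrained_mfe_delta(SEQ12, HIT12, engine, "closed")
        assert mc == pytest.approx(min(energies), abs=1e-9)
        assert mc >= mu - 1e-12

    def test_unsatisfiable_flagged(self, engine):
        hit = _hairpin_hit((3, 6), (2, 6))
        mc, mu = constrained_mfe_delta("GGCAAACCCUAA", hit, engine, "closed")
        assert math.isnan(mc)
        ctx = hit_context("GGCAAACCCUAA", hit, engine, "closed")
        assert not ctx.valid


class TestHelixLength:
    def test_unique_structure(self, engine):
        # only one compatible structure: the closing pair alone
        seq = "CGAAACA"
        hit = _hairpin_hit((2, 5), (1, 5))
        mean, n = mean_helix_length(seq, hit, engine, "closed")
        assert mean == pytest.approx(1.0) and n == 1

    def test_two_structure_hand_oracle(self, engine):
        # compatible: {(1,5)} (helix 1, E=-1) and {(1,5),(0,6)} (helix 2, E=-3)
        seq = "GGAAACC"
        hit = _hairpin_hit((2, 5), (1, 5))
        w1, w2 = math.exp(1.0), math.exp(3.0)
        expect = (1 * w1 + 2 * w2) / (w1 + w2)
        mean, n = mean_helix_length(seq, hit, engine, "closed")
        assert n == 2 and mean == pytest.approx(expect, abs=1e-9)

    def test_sampled_agrees_with_enumerated(self, engine):
        hit = HIT12
        exact, _ = mean_helix_length(SEQ12, hit, engine, "closed")
        sampled, n = mean_helix_length(SEQ12, hit, engine, "closed",
                                       n_samples=10000, seed=3, exact="never")
        assert n == 10000
        # helix length is in [1, 4]; generous 3-sigma envelope
        assert abs(sampled - exact) <= 3 * (1.5 / math.sqrt(n)) + 0.02

    def test_internal_hit_rejected(self, engine):
        hit = MotifHit("s", "m", [(2, 4), (10, 12)], [(1, 12), (4, 9)], 0.0)
        with pytest.raises(ContextError):
            mean_helix_length("G" * 14, hit, engine)

    def test_closed_mode_guarantees_helix(self, engine, rng):
        for _ in range(5):
            seq = random_rna(14, rng)
            from perfumes.scoring import extract_loops
            hairpins, _ = extract_loops(engine.mfe(seq).structure)
            for a, b in hairpins:
                hit = _hairpin_hit((a + 1, b), (a, b))
                mean, _ = mean_helix_length(seq, hit, engine, "closed")
                assert mean >= 1.0


def _ctx(motif, dataset, mfe, p):
    return StructureContext("x", motif, "GCAC", mfe, mfe - 1.0, p, "closed",
                            dataset=dataset)


class TestSummaries:
    def test_identical_groups_null_pvalue(self):
        ctxs = [_ctx("m", "positive", -5 - i * 0.1, 0.5) for i in range(20)] + \
               [_ctx("m", "background", -5 - i * 0.1, 0.5) for i in range(20)]
        out = summarize_context(ctxs)
        assert len(out) == 1
        p = out[0]["tests"]["mfe_constrained_less"]
        assert 0.3 < p < 0.7

    def test_shifted_groups_detected(self):
        rng = random.Random(17)
        ctxs = [_ctx("m", "positive", rng.gauss(-7, 1), 0.6) for _ in range(50)] + \
               [_ctx("m", "background", rng.gauss(-5, 1), 0.4) for _ in range(50)]
        out = summarize_context(ctxs)
        assert out[0]["tests"]["mfe_constrained_less"] < 0.01
        assert out[0]["tests"]["p_compatible_greater"] < 0.01
        pos = out[0]["datasets"]["positive"]["mfe_constrained"]
        bgd = out[0]["datasets"]["background"]["mfe_constrained"]
        assert pos["mean"] < bgd["mean"]

    def test_single_group_no_test(self):
        out = summarize_context([_ctx("m", "positive", -4.0, 0.5)])
        assert "tests" not in out[0]
        assert out[0]["datasets"]["positive"]["mfe_constrained"]["count"] == 1
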