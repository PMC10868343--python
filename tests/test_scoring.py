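import math
import random

import numpy as np
import pytest
from scipy.special import erfc

from perfumes.fold import InternalEngine
from perfumes.motif_library import LoopMotif
from perfumes.scoring import (MotifHit, ScoringError, best_hit,
                              calibrate_sequence, enumerate_candidates,
                              fit_null, score_loop, score_p_value, train_bn)
from perfumes.synth import default_motif, plant_instance
from .conftest import random_rna


def _degenerate_motif():
    return LoopMotif("HL_D", "hairpin", [2], [(0, 3)], [], ["GCAC", "GCAC"])


class TestTraining:
    def test_degenerate_model_is_certain(self):
        model = train_bn(_degenerate_motif(), pseudocount=0.0)
        assert score_loop(model, "GCAC") == pytest.approx(8.0)  # -4*log2(1/4)
        assert score_loop(model, "AAAA") == -math.inf

    def test_zero_instances_rejected(self):
        m = LoopMotif("HL_E", "hairpin", [2], [(0, 3)], [], [])
        with pytest.raises(ScoringError):
            train_bn(m)

    def test_smoothed_cpts_match_hand_computation(self):
        m = LoopMotif("HL_H", "hairpin", [2], [(0, 3)], [], ["GCAC", "GCAA"])
        model = train_bn(m, pseudocount=1.0)
        # MI ties resolved lexicographically: tree = (0,1), (0,3), (1,2)
        assert sorted(model.tree_edges) == [(0, 1), (0, 3), (1, 2)]
        A, C, G, U = 0, 1, 2, 3
        np.testing.assert_allclose(
            model.root_marginal, [1 / 6, 1 / 6, 3 / 6, 1 / 6])
        np.testing.assert_allclose(
            model.cpts[1][G], [1 / 6, 3 / 6, 1 / 6, 1 / 6])
        np.testing.assert_allclose(model.cpts[1][A], [0.25] * 4)
        np.testing.assert_allclose(
            model.cpts[3][G], [2 / 6, 2 / 6, 1 / 6, 1 / 6])
        np.testing.assert_allclose(
            model.cpts[2][C], [3 / 6, 1 / 6, 1 / 6, 1 / 6])

    def test_cpt_rows_normalised(self, hairpin_motif, internal_motif):
        for motif in (hairpin_motif, internal_motif):
            model = train_bn(motif, pseudocount=0.5)
            assert model.root_marginal.sum() == pytest.approx(1.0, abs=1e-9)
            for t in model.cpts.values():
                np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-9)


def _oracle_probability(model, seq):
    """Plain-probability tree traversal, independent of score_loop's
    log-space accumulation."""
    sym = ["ACGU".index(c) for c in seq.replace("&", "")]
    children = {}
    for p, c in model.tree_edges:
        children.setdefault(p, []).append(c)

    def rec(node, prob_table_value):
        p = prob_table_value
        for ch in children.get(node, []):
            p *= rec(ch, model.cpts[ch][sym[node], sym[ch]])
        return p

    return rec(model.root, model.root_marginal[sym[model.root]])


class TestScoreLoop:
    def test_matches_traversal_oracle_on_random_cases(self, rng):
        for _ in range(60):
            L = rng.randint(1, 4)
            insts = ["".join(rng.choice("ACGU") for _ in range(L + 2))
                     for _ in range(rng.randint(2, 8))]
            m = LoopMotif("HL_R", "hairpin", [L], [(0, L + 1)], [], insts)
            model = train_bn(m, pseudocount=rng.choice([0.1, 0.5, 1.0]))
            seq = random_rna(L + 2, rng)
            p = _oracle_probability(model, seq)
            bg = 0.25 ** (L + 2)
            assert score_loop(model, seq) == pytest.approx(
                math.log2(p) - math.log2(bg), abs=1e-9)

    def test_uniform_model_scores_zero(self):
        m = LoopMotif("HL_U", "hairpin", [1], [(0, 2)], [], ["GAC"])
        model = train_bn(m, pseudocount=1.0)
        model.root_marginal = np.full(4, 0.25)
        for c in model.cpts:
            model.cpts[c] = np.full((4, 4), 0.25)
        for seq in ("AAA", "GAC", "UGU"):
            assert score_loop(model, seq) == pytest.approx(0.0)

    def test_joint_distribution_normalised(self, hairpin_motif):
        import itertools
        model = train_bn(hairpin_motif, pseudocount=1.0)
        total = sum(_oracle_probability(model, "".join(s))
                    for s in itertools.product("ACGU", repeat=6))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch(self, hairpin_motif):
        model = train_bn(hairpin_motif)
        with pytest.raises(ScoringError):
            score_loop(model, "GCAC")


class TestBestHit:
    def _hit(self, score, start, mid="m"):
        return MotifHit("s", mid, [(start, start + 4)], [(start - 1, start + 4)],
                        score)

    def test_empty(self):
        assert best_hit([]) is None

    def test_tie_breaks_leftmost(self):
        a, b = self._hit(2.0, 10), self._hit(2.0, 4)
        assert best_hit([a, b]) is b
        assert best_hit([b, a]) is b

    def test_permutation_invariant(self, rng):
        hits = [self._hit(rng.choice([1.0, 2.0]), rng.randrange(30),
                          rng.choice("mn")) for _ in range(8)]
        ref = best_hit(hits)
        for _ in range(5):
            rng.shuffle(hits)
            got = best_hit(hits)
            assert (got.score, got.strand_spans, got.motif_id) == \
                (ref.score, ref.strand_spans, ref.motif_id)


class TestNull:
    def test_floor_rule(self):
        null = fit_null([1.0, 1.0, 1.0, 1.0], sd_floor=0.05)
        assert null.mean == 1.0 and null.sd == 0.05

    def test_two_point_sample(self):
        null = fit_null([0.0, 2.0], sd_floor=0.05)
        assert null.mean == 1.0 and null.sd == pytest.approx(math.sqrt(2))

    def test_monte_carlo_recovery(self):
        gen = np.random.default_rng(99)
        null = fit_null(gen.normal(3.0, 1.5, size=10000), sd_floor=0.01)
        assert abs(null.mean - 3.0) < 0.05 and abs(null.sd - 1.5) < 0.05

    def test_too_few_scores(self):
        with pytest.raises(ScoringError):
            fit_null([1.0])

    def test_p_value_symmetry_and_quantile(self):
        null = fit_null([0.0, 2.0], sd_floor=0.05)
        assert score_p_value(1.0, null) == pytest.approx(0.5)
        z975 = 1.959964
        assert score_p_value(null.mean + z975 * null.sd, null) == \
            pytest.approx(0.025, abs=1e-6)

    def test_p_value_matches_erfc(self, rng):
        null = fit_null([rng.gauss(0, 1) for _ in range(50)], sd_floor=0.05)
        for _ in range(20):
            s = rng.gauss(0, 2)
            z = (s - null.mean) / null.sd
            assert score_p_value(s, null) == pytest.approx(
                0.5 * erfc(z / math.sqrt(2)), abs=1e-12)


class TestCandidates:
    def test_designed_stemloop_found_at_designed_spans(self, engine, hairpin_motif):
        stem = "GGCAGC"
        seq = stem + "CGCACG" + "GCUGCC"
        model = train_bn(hairpin_motif)
        hits = enumerate_candidates(seq, model, engine, n_samples=0)
        assert len(hits) == 1
        assert hits[0].strand_spans == [(7, 11)]
        assert hits[0].closing_pair_coords == [(6, 11)]
        assert hits[0].variant == "CGCACG"

    def test_unstructured_sequence_yields_nothing(self, engine, hairpin_motif):
        model = train_bn(hairpin_motif)
        assert enumerate_candidates("A" * 30, model, engine, n_samples=5) == []

    def test_internal_loop_candidates(self, engine, internal_motif):
        rng = random.Random(1)
        base = random_rna(60, rng)
        seq, spans, closings = plant_instance(base, internal_motif,
                                              "CAAG&CACG", 6, rng)
        model = train_bn(internal_motif)
        hits = enumerate_candidates(seq, model, engine, n_samples=10, seed=4)
        assert any(h.strand_spans == spans and
                   h.closing_pair_coords == closings for h in hits)

    def test_samples_extend_mfe_candidates(self, engine, hairpin_motif):
        model = train_bn(hairpin_motif)
        seq = random_rna(60, random.Random(8))
        h0 = enumerate_candidates(seq, model, engine, n_samples=0)
        h1 = enumerate_candidates(seq, model, engine, n_samples=30, seed=2)
        assert len(h1) >= len(h0)


class TestCalibration:
    def test_planted_motif_significant(self, engine):
        motif = default_motif()
        model = train_bn(motif)
        for seed in range(5):
            rng = random.Random(1000 + seed)
            base = random_rna(60, rng)
            seq, spans, _ = plant_instance(base, motif, "CGCACG", 6, rng)
            hits = calibrate_sequence("s", seq, [model], engine,
                                      n_shuffles=30, n_samples=10,
                                      seed=seed, threshold=0.05)
            assert hits, f"planted instance missed at seed {seed}"
            assert hits[0].p_value <= 0.05

    def test_threshold_one_retains_any_candidate(self, engine):
        motif = default_motif()
        model = train_bn(motif)
        rng = random.Random(5)
        seq, _, _ = plant_instance(random_rna(60, rng), motif, "CGCAAG", 6, rng)
        hits = calibrate_sequence("s", seq, [model], engine, 10, 5, 3,
                                  threshold=1.0)
        assert len(hits) == 1

    def test_determinism(self, engine):
        motif = default_motif()
        model = train_bn(motif)
        seq = random_rna(50, random.Random(6))
        a = calibrate_sequence("s", seq, [model], engine, 15, 5, 9, 1.0)
        b = calibrate_sequence("s", seq, [model], engine, 15, 5, 9, 1.0)
        assert [(h.score, h.p_value) for h in a] == [(h.score, h.p_value) for h in b]
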