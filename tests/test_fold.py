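import math
import random

import pytest

from perfumes.fold import (FoldConstraint, FoldError, InternalEngine,
                           build_constraint, dotbracket_to_pairs,
                           enumerate_partition, enumerate_structures,
                           pairs_to_dotbracket, structure_energy)
from perfumes.scoring import MotifHit
from .conftest import random_rna


def _hit(spans, closings):
    return MotifHit("s", "m", spans, closings, 0.0)


class TestMFE:
    def test_known_stemloop(self, engine):
        res = engine.mfe("GGGAAACCC")
        assert res.structure == "(((...)))"
        assert res.energy == -5.0  # 3 pairs + 2 stacks

    def test_too_short_for_hairpin(self, engine):
        res = engine.mfe("ACGU")
        assert res.structure == "...." and res.energy == 0.0

    def test_unsatisfiable_forced_pair(self, engine):
        c = FoldConstraint(8, forced_pairs=frozenset({(0, 7)}))
        res = engine.mfe("AAAAAAAA", c)  # A-A cannot pair
        assert not res.valid

    def test_traceback_structure_has_reported_energy(self, engine, rng):
        for _ in range(40):
            seq = random_rna(rng.randint(5, 30), rng)
            res = engine.mfe(seq)
            assert res.valid
            assert structure_energy(dotbracket_to_pairs(res.structure)) \
                == pytest.approx(res.energy)


class TestOracleAgreement:
    def test_dp_equals_enumeration(self, engine, rng):
        for _ in range(40):
            seq = random_rna(rng.randint(4, 13), rng)
            emin = min(structure_energy(s) for s in enumerate_structures(seq))
            assert engine.mfe(seq).energy == pytest.approx(emin, abs=1e-9)
            assert engine.partition(seq).log_partition == pytest.approx(
                enumerate_partition(seq).log_partition, abs=1e-9)

    def test_dp_equals_enumeration_constrained(self, engine, rng):
        done = 0
        while done < 20:
            seq = random_rna(rng.randint(8, 13), rng)
            n = len(seq)
            fu = frozenset(rng.sample(range(n), rng.randint(0, 2)))
            i = rng.randrange(0, n - 5)
            j = rng.randrange(i + 4, n)
            fp = frozenset({(i, j)}) if i not in fu and j not in fu else frozenset()
            c = FoldConstraint(n, fu, fp)
            ez = enumerate_partition(seq, c).log_partition
            dz = engine.partition(seq, c).log_partition
            assert dz == pytest.approx(ez, abs=1e-9) or (
                math.isinf(ez) and math.isinf(dz))
            emfe = [structure_energy(s) for s in enumerate_structures(seq, c)]
            res = engine.mfe(seq, c)
            if emfe:
                assert res.valid and res.energy == pytest.approx(min(emfe), abs=1e-9)
            else:
                assert not res.valid
            done += 1

    def test_constraint_orderings(self, engine, rng):
        for _ in range(20):
            seq = random_rna(14, rng)
            fu = frozenset(rng.sample(range(14), 3))
            c = FoldConstraint(14, fu)
            assert engine.mfe(seq, c).energy >= engine.mfe(seq).energy - 1e-12
            assert engine.partition(seq, c).log_partition \
                <= engine.partition(seq).log_partition + 1e-12

    def test_all_unpaired_constraint_gives_unit_partition(self, engine):
        seq = "GGGAAACCC"
        c = FoldConstraint(9, frozenset(range(9)))
        assert engine.partition(seq, c).log_partition == pytest.approx(0.0)


class TestSampling:
    def test_determinism(self, engine):
        seq = "GGCAAAGGCCAUGC"
        assert engine.sample(seq, n=20, seed=5) == engine.sample(seq, n=20, seed=5)
        assert engine.sample(seq, n=20, seed=5) != engine.sample(seq, n=20, seed=6)

    def test_frequencies_match_boltzmann(self, engine):
        seq = "GGCAAAGGCCUA"  # length 12 toy
        Z = enumerate_partition(seq)
        probs = {}
        for s in enumerate_structures(seq):
            db = pairs_to_dotbracket(12, s)
            probs[db] = math.exp(-structure_energy(s) - Z.log_partition)
        n = 10000
        samples = engine.sample(seq, n=n, seed=11)
        from collections import Counter
        freq = Counter(samples)
        assert set(freq) <= set(probs)
        for db, p in probs.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq[db] / n - p) <= 3 * se + 1e-9

    def test_fully_determined_constraint(self, engine):
        seq = "GGGGAAACCCC"
        pairs = {(0, 10), (1, 9), (2, 8), (3, 7)}
        c = FoldConstraint(11, frozenset({4, 5, 6}), frozenset(pairs))
        samples = engine.sample(seq, c, n=50, seed=1)
        assert len(set(samples)) == 1
        assert dotbracket_to_pairs(samples[0]) == frozenset(pairs)

    def test_unsatisfiable_raises(self, engine):
        c = FoldConstraint(8, forced_pairs=frozenset({(0, 7)}))
        with pytest.raises(FoldError):
            engine.sample("AAAAAAAA", c, n=1, seed=0)


class TestConstraints:
    def test_string_roundtrip(self):
        c = FoldConstraint(10, frozenset({3, 4, 5}), frozenset({(2, 6)}))
        assert FoldConstraint.from_string(c.to_string()) == c

    def test_string_roundtrip_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=40, derandomize=True, deadline=None)
        @given(data=st.data())
        def run(data):
            n = data.draw(st.integers(6, 30))
            i = data.draw(st.integers(0, n - 6))
            j = data.draw(st.integers(i + 5, n - 1))
            free = sorted(set(range(n)) - {i, j})
            fu = frozenset(data.draw(st.sets(st.sampled_from(free), max_size=4)))
            c = FoldConstraint(n, fu, frozenset({(i, j)}))
            assert FoldConstraint.from_string(c.to_string()) == c

        run()

    def test_validation(self):
        with pytest.raises(FoldError):
            FoldConstraint(5, frozenset({7}))
        with pytest.raises(FoldError):
            FoldConstraint(10, frozenset({2}), frozenset({(2, 6)}))
        with pytest.raises(FoldError):  # crossing forced pairs
            FoldConstraint(10, frozenset(), frozenset({(0, 5), (2, 8)}))

    def test_build_constraint_hairpin_modes(self):
        hit = _hit([(3, 6)], [(2, 6)])
        c = build_constraint(9, hit, "loop_only")
        assert c.forced_unpaired == {3, 4, 5} and not c.forced_pairs
        c = build_constraint(9, hit, "closed")
        assert c.forced_pairs == {(2, 6)}
        c = build_constraint(9, hit, "stacked")
        assert c.forced_pairs == {(2, 6), (1, 7)}

    def test_build_constraint_internal(self):
        hit = _hit([(2, 4), (10, 12)], [(1, 12), (4, 9)])
        c = build_constraint(14, hit, "closed")
        assert c.forced_pairs == {(1, 12), (4, 9)}
        c = build_constraint(14, hit, "stacked")
        assert c.forced_pairs == {(1, 12), (4, 9), (0, 13), (5, 8)}

    def test_stacked_at_boundary_errors(self):
        hit = _hit([(1, 4)], [(0, 4)])
        with pytest.raises(FoldError):
            build_constraint(6, hit, "stacked")
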