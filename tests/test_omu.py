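import itertools

import numpy as np
import pytest

from omu_synergy.diffmod import DifferentialModule
from omu_synergy.io_formats import GRTable
from omu_synergy.omu import (OMU, OMUSystem, assign_mean_grmax,
                             build_omu_system, module_jaccard, omu_vector)


def mod(sample, index, edges, score=1.0):
    edges = [tuple(e) for e in edges]
    scores = {e: score for e in edges} if np.isscalar(score) else dict(zip(edges, score))
    return DifferentialModule(sample_id=sample, index=index, edges=edges,
                              edge_scores=scores)


E = [("t0", "g0"), ("t0", "g1"), ("t1", "g0"), ("t1", "g1"), ("t2", "g2"),
     ("t2", "g3"), ("t3", "g3"), ("t3", "g4"), ("t4", "g5"), ("t4", "g6")]


class TestJaccard:
    def test_identity(self):
        a = mod("s1", 0, E[:3])
        b = mod("s2", 0, E[:3])
        assert module_jaccard(a, b) == 1.0

    def test_disjoint(self):
        assert module_jaccard(mod("s1", 0, E[:3]), mod("s2", 0, E[5:8])) == 0.0

    def test_three_edge_sets_with_two_shared(self):
        # |A| = |B| = 3, |A & B| = 2 -> 2 / (3 + 3 - 2) = 0.5
        a = mod("s1", 0, E[0:3])
        b = mod("s2", 0, E[1:4])
        assert module_jaccard(a, b) == 0.5

    def test_empty_module_impossible(self):
        with pytest.raises(ValueError):
            mod("s1", 0, [])


def reference_build(modules, min_similarity=0.25):
    """Plain-loop reference of the greedy merge (independent of the impl)."""
    keyed = sorted(modules, key=lambda m: (m.sample_id, m.index))
    pairs = []
    for a, b in itertools.combinations(keyed, 2):
        if a.sample_id == b.sample_id:
            continue
        ea, eb = frozenset(a.edges), frozenset(b.edges)
        inter = len(ea & eb)
        j = inter / (len(ea) + len(eb) - inter)
        if j >= min_similarity:
            pairs.append((j, a, b))
    pairs.sort(key=lambda p: (-p[0], p[1].sample_id, p[1].index,
                              p[2].sample_id, p[2].index))
    omus = []  # list of [structure set, member list]
    placed = set()
    for j, a, b in pairs:
        shared = frozenset(a.edges) & frozenset(b.edges)
        members = [(a.sample_id, a.index), (b.sample_id, b.index)]
        for omu in omus:
            if omu[0] & shared:
                omu[0] = omu[0] & shared
                for mem in members:
                    if mem not in omu[1]:
                        omu[1].append(mem)
                break
        else:
            omus.append([set(shared), list(members)])
        placed.update(members)
    for m in keyed:
        key = (m.sample_id, m.index)
        if key not in placed:
            omus.append([set(m.edges), [key]])
    return [(frozenset(s), tuple(mem)) for s, mem in omus]


class TestBuildSystem:
    def test_two_identical_modules_one_omu(self):
        a = mod("s1", 0, E[:4])
        b = mod("s2", 0, E[:4])
        system = build_omu_system([a, b])
        assert len(system) == 1
        assert system.omus[0].structure == frozenset(E[:4])
        assert len(system.omus[0].members) == 2

    def test_three_disjoint_modules_three_singletons(self):
        mods = [mod("s1", 0, E[0:2]), mod("s2", 0, E[4:6]), mod("s3", 0, E[8:10])]
        system = build_omu_system(mods)
        assert len(system) == 3
        assert all(len(o.members) == 1 for o in system)

    def test_matches_reference_implementation(self, rng):
        # randomized <=5-module inventories vs the plain-loop reference
        for trial in range(60):
            mods = []
            n = rng.integers(2, 6)
            for i in range(n):
                size = rng.integers(2, 6)
                edges = [E[k] for k in rng.choice(len(E), size=size, replace=False)]
                mods.append(mod(f"s{rng.integers(1, 4)}", i, edges))
            # de-duplicate (sample, index) keys
            seen = set()
            uniq = []
            for m in mods:
                if (m.sample_id, m.index) not in seen:
                    uniq.append(m)
                    seen.add((m.sample_id, m.index))
            system = build_omu_system(uniq)
            expected = reference_build(uniq)
            got = [(o.structure, tuple(o.members)) for o in system.omus]
            assert got == expected

    def test_every_module_is_a_member(self, rng):
        mods = [mod(f"s{i}", 0, [E[k] for k in rng.choice(10, 4, replace=False)])
                for i in range(6)]
        system = build_omu_system(mods)
        members = {m for o in system for m in o.members}
        assert members == {(m.sample_id, m.index) for m in mods}

    def test_rebuild_bit_identical(self, rng):
        mods = [mod(f"s{i}", j, [E[k] for k in rng.choice(10, 3, replace=False)])
                for i in range(4) for j in range(2)]
        a = build_omu_system(mods)
        b = build_omu_system(list(reversed(mods)))
        assert [(o.structure, tuple(o.members)) for o in a.omus] == \
               [(o.structure, tuple(o.members)) for o in b.omus]

    def test_no_modules_rejected(self):
        with pytest.raises(ValueError):
            build_omu_system([])


class TestMeanGRmax:
    def test_single_member_hand_value(self):
        # member weight 2 of a sample whose total module weight is 8,
        # sample GRmax -0.4 -> mean = -0.4 * 2 / 8 = -0.1
        m1 = mod("s1", 0, E[:2], score=1.0)          # weight 2 (member)
        m2 = mod("s1", 1, E[4:8], score=1.5)         # weight 6 (same sample)
        m3 = mod("s2", 0, E[8:10], score=1.0)
        system = build_omu_system([m1, m2, m3])
        gr = GRTable(records={"s1": -0.4, "s2": 0.2})
        assign_mean_grmax(system, gr, [m1, m2, m3])
        omu_of_m1 = next(o for o in system if ("s1", 0) in o.members)
        assert omu_of_m1.mean_grmax == pytest.approx(-0.1)

    def test_only_module_of_sample_recovers_grmax(self):
        m1 = mod("s1", 0, E[:3])
        m2 = mod("s2", 0, E[4:6])
        system = build_omu_system([m1, m2])
        gr = GRTable(records={"s1": -0.7, "s2": 0.1})
        assign_mean_grmax(system, gr, [m1, m2])
        omu1 = next(o for o in system if ("s1", 0) in o.members)
        assert omu1.mean_grmax == pytest.approx(-0.7)

    def test_shared_sign_and_magnitude_bound(self):
        g = -0.6
        m1 = mod("s1", 0, E[:4])
        m1b = mod("s1", 1, E[8:10])
        m2 = mod("s2", 0, E[:4])
        system = build_omu_system([m1, m1b, m2])
        gr = GRTable(records={"s1": g, "s2": g})
        assign_mean_grmax(system, gr, [m1, m1b, m2])
        shared = next(o for o in system if len(o.members) == 2)
        assert shared.mean_grmax < 0
        assert abs(shared.mean_grmax) <= abs(g)

    def test_zero_weight_duplicate_member_is_neutral(self):
        m1 = mod("s1", 0, E[:4], score=1.0)
        m2 = mod("s2", 0, E[:4], score=1.0)
        zero = mod("s2", 1, E[:2], score=0.0)  # zero-weight module, same sample
        gr = GRTable(records={"s1": -0.4, "s2": 0.6})
        base = build_omu_system([m1, m2])
        assign_mean_grmax(base, gr, [m1, m2])
        with_zero = build_omu_system([m1, m2])
        with_zero.omus[0].members.append(("s2", 1))
        assign_mean_grmax(with_zero, gr, [m1, m2, zero])
        assert with_zero.omus[0].mean_grmax == pytest.approx(
            base.omus[0].mean_grmax
        )

    def test_missing_grmax_named(self):
        m1 = mod("s1", 0, E[:3])
        system = build_omu_system([m1])
        with pytest.raises(KeyError, match="s1"):
            assign_mean_grmax(system, GRTable(records={"other": 0.0}), [m1])


class TestOMUVector:
    def _system4(self):
        omus = [
            OMU(0, frozenset(E[0:2]), [("s1", 0)]),
            OMU(1, frozenset(E[2:4]), [("s2", 0)]),
            OMU(2, frozenset(E[4:6]), [("sX", 0), ("sX", 1)]),
            OMU(3, frozenset(E[6:8]), [("s3", 0)]),
        ]
        return OMUSystem(omus=omus, min_similarity=0.25)

    def test_single_module_single_component(self):
        system = self._system4()
        m = mod("sX", 0, E[4:6], score=2.5)  # weight 5 -> OMU position 2
        v = omu_vector([m], system)
        np.testing.assert_allclose(v.values, [0, 0, 5.0, 0])

    def test_two_modules_same_omu_sum(self):
        system = self._system4()
        m0 = mod("sX", 0, E[4:6], score=1.0)  # weight 2
        m1 = mod("sX", 1, E[6:8], score=1.5)  # weight 3, also member of OMU 2?
        system.omus[2].members = [("sX", 0), ("sX", 1)]
        v = omu_vector([m0, m1], system)
        assert v.values[2] == pytest.approx(5.0)

    def test_no_modules_rejected(self):
        with pytest.raises(ValueError):
            omu_vector([], self._system4())

    def test_vectors_are_sparse_in_fitted_study(self, results20):
        n = len(results20.omu_system)
        for v in results20.vectors.values():
            assert (v.values == 0).sum() >= 1
            assert (v.values > 0).any()
            assert len(v.values) == n
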