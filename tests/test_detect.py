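"""Pair detection rule, stack assembly, classification and their invariances.

Oracles here are independent of the implementation: plain-math pair
evaluation for the threshold rule and a hand-rolled union-find for the
connected components.
"""

import math

import numpy as np
import pytest

from pistacks.detect import (
    DetectionConfig, INTERCHAIN_PRESET, PiStack, StackPair, assemble_stacks,
    classify_and_filter, find_pairs, folded_normal_angle, is_stacking_pair,
)
from pistacks.rings import AromaticRing

from conftest import random_rotation


def ring(center, normal, chain="A", seq=1, name="PHE"):
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    return AromaticRing(chain, seq, name, tuple(np.asarray(center, float)),
                        tuple(n), ("CG",))


def oracle_pair(a: AromaticRing, b: AromaticRing, cfg: DetectionConfig) -> bool:
    """Independent evaluation of the rule with scalar math only."""
    d = math.dist(a.centroid, b.centroid)
    dot = sum(x * y for x, y in zip(a.normal, b.normal))
    theta = math.degrees(math.acos(max(-1.0, min(1.0, dot))))
    folded = min(theta, 180.0 - theta)
    return d < cfg.distance_threshold and folded <= cfg.angle_threshold


def oracle_components(n: int, edges) -> list[set]:
    """Union-find components, independent of networkx."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return [c for c in comps.values() if len(c) > 1]


class TestStackingRule:
    @pytest.mark.parametrize("center_b, normal_b, expected", [
        ((0, 0, 4.8), (0, 0, 1), True),        # parallel, well inside
        ((0, 0, 6.5), (0, 0, 1), False),       # distance fail
        ((0, 0, 5.0), (1, 0, 0), False),       # T-shaped, angle 90
        ((0, 0, 5.0), (0, 0, -1), True),       # antiparallel counts
        ((0, 0, 5.99), None, True),            # 19.9 deg tilt at 5.99 A
        ((0, 0, 6.0), (0, 0, 1), False),       # strict <: 6.0 rejected
    ])
    def test_rule_examples(self, center_b, normal_b, expected):
        a = ring((0, 0, 0), (0, 0, 1))
        if normal_b is None:
            t = math.radians(19.9)
            normal_b = (math.sin(t), 0, math.cos(t))
        b = ring(center_b, normal_b, seq=2)
        accepted, _, _ = is_stacking_pair(a, b)
        assert accepted is expected

    @pytest.mark.parametrize("tilt_deg, expected", [(19.9, True), (20.0, True),
                                                    (20.1, False)])
    def test_angle_boundary_is_inclusive(self, tilt_deg, expected):
        t = math.radians(tilt_deg)
        a = ring((0, 0, 0), (0, 0, 1))
        b = ring((0, 0, 5.99), (math.sin(t), 0, math.cos(t)), seq=2)
        accepted, _, angle = is_stacking_pair(a, b)
        assert accepted is expected
        assert angle == pytest.approx(tilt_deg, abs=1e-9)

    def test_symmetry_and_sign_invariance(self, rng):
        a = ring(rng.normal(0, 2, 3), rng.normal(size=3), seq=1)
        b = ring(rng.normal(0, 2, 3), rng.normal(size=3), seq=2)
        base = is_stacking_pair(a, b)
        assert is_stacking_pair(b, a)[0] == base[0]
        flipped = ring(b.centroid, -b.normal_array, seq=2)
        assert is_stacking_pair(a, flipped) == pytest.approx(base)

    def test_folded_angle_range(self, rng):
        for _ in range(50):
            u = rng.normal(size=3)
            v = rng.normal(size=3)
            ang = folded_normal_angle(u / np.linalg.norm(u), v / np.linalg.norm(v))
            assert 0.0 <= ang <= 90.0


class TestFindPairs:
    @pytest.mark.parametrize("n", [0, 1])
    def test_fewer_than_two_rings_yield_no_pairs(self, n):
        rings = [ring((0, 0, 0), (0, 0, 1))][:n]
        assert find_pairs(rings) == []

    def test_collinear_ladder_pairs_consecutive_only(self):
        rings = [ring((0, 0, 4.8 * k), (0, 0, 1), seq=k + 1) for k in range(3)]
        pairs = find_pairs(rings)
        got = {frozenset((p.ring_a.residue_seq, p.ring_b.residue_seq)) for p in pairs}
        assert got == {frozenset((1, 2)), frozenset((2, 3))}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_rings(self, seed):
        rng = np.random.default_rng(seed)
        rings = [
            ring(rng.uniform(-8, 8, 3), rng.normal(size=3), seq=i + 1)
            for i in range(50)
        ]
        cfg = DetectionConfig()
        got = {frozenset((p.ring_a.residue_seq, p.ring_b.residue_seq))
               for p in find_pairs(rings, cfg)}
        want = {
            frozenset((a.residue_seq, b.residue_seq))
            for i, a in enumerate(rings) for b in rings[i + 1:]
            if oracle_pair(a, b, cfg)
        }
        assert got == want

    def test_threshold_monotonicity(self, rng):
        rings = [ring(rng.uniform(-6, 6, 3), rng.normal(size=3), seq=i + 1)
                 for i in range(30)]
        loose = DetectionConfig(distance_threshold=7.5, angle_threshold=30.0)
        tight_pairs = {p.key for p in find_pairs(rings)}
        loose_pairs = {p.key for p in find_pairs(rings, loose)}
        assert tight_pairs <= loose_pairs


class TestAssembleStacks:
    def _pairs_from_edges(self, rings, edges):
        return [StackPair(rings[i], rings[j], 4.8, 0.0) for i, j in edges]

    def _rings(self, n):
        return [ring((0, 0, 10.0 * k), (0, 0, 1), seq=k + 1) for k in range(n)]

    def test_chain_of_two_pairs_is_one_stack_of_three(self):
        rings = self._rings(3)
        stacks = assemble_stacks(self._pairs_from_edges(rings, [(0, 1), (1, 2)]))
        assert [s.size for s in stacks] == [3]

    def test_disjoint_pairs_make_two_stacks(self):
        rings = self._rings(4)
        stacks = assemble_stacks(self._pairs_from_edges(rings, [(0, 1), (2, 3)]))
        assert sorted(s.size for s in stacks) == [2, 2]

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_random_graphs_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        rings = self._rings(n)
        edges = [tuple(sorted(rng.choice(n, 2, replace=False)))
                 for _ in range(60)]
        stacks = assemble_stacks(self._pairs_from_edges(rings, edges))
        got = sorted(sorted(r.residue_seq - 1 for r in s.rings) for s in stacks)
        want = sorted(sorted(c) for c in oracle_components(n, edges))
        assert got == want

    def test_every_paired_ring_in_exactly_one_stack(self, rng):
        rings = self._rings(20)
        edges = [tuple(sorted(rng.choice(20, 2, replace=False))) for _ in range(25)]
        stacks = assemble_stacks(self._pairs_from_edges(rings, edges))
        seen = [r for s in stacks for r in s.rings]
        assert len(seen) == len(set(seen))
        assert set(seen) == {rings[i] for e in edges for i in e}


class TestClassifyAndFilter:
    def _stack(self, chains, sizes_start=1):
        rings = [ring((0, 0, 4.8 * k), (0, 0, 1), chain=c, seq=sizes_start + k)
                 for k, c in enumerate(chains)]
        pairs = [StackPair(rings[k], rings[k + 1], 4.8, 0.0)
                 for k in range(len(rings) - 1)]
        return PiStack(rings=frozenset(rings), pairs=frozenset(pairs))

    def test_single_chain_stack_is_intrachain(self):
        stack = self._stack("AAAA")
        assert not stack.interchain

    def test_chain_spanning_stack_is_interchain(self):
        stack = self._stack("AABB")
        assert stack.interchain
        records = classify_and_filter([stack], INTERCHAIN_PRESET, "fix")
        assert len(records) == 1 and records[0].interchain

    def test_min_rings_filter_counts(self):
        sizes = [2, 2, 3, 4, 5, 6, 7, 12]
        stacks = [self._stack("A" * n) for n in sizes]
        records = classify_and_filter(stacks, DetectionConfig(min_rings_report=6))
        assert len(records) == 3
        assert [r.size for r in records] == [12, 7, 6]

    def test_raising_min_rings_never_adds_records(self):
        stacks = [self._stack("A" * n) for n in (2, 4, 6, 9)]
        for lo, hi in [(2, 4), (4, 6), (6, 9)]:
            n_lo = len(classify_and_filter(stacks, DetectionConfig(min_rings_report=lo)))
            n_hi = len(classify_and_filter(stacks, DetectionConfig(min_rings_report=hi)))
            assert n_hi <= n_lo

    def test_interchain_only_filter(self):
        stacks = [self._stack("AAAAAA"), self._stack("AAABBB")]
        records = classify_and_filter(stacks, DetectionConfig(min_rings_report=6),
                                      interchain_only=True)
        assert len(records) == 1 and records[0].chains == "A,B"


def test_rigid_body_motion_preserves_all_decisions(rng):
    """Rotating + translating every ring changes no pair, stack, or label."""
    rings = [ring(rng.uniform(-7, 7, 3), rng.normal(size=3),
                  chain="AB"[i % 2], seq=i + 1) for i in range(30)]
    rot = random_rotation(rng)
    shift = rng.normal(0, 50, 3)
    moved = [
        AromaticRing(r.chain_id, r.residue_seq, r.residue_name,
                     tuple(rot @ r.centroid_array + shift),
                     tuple(rot @ r.normal_array * (-1 if i % 3 == 0 else 1)),
                     r.source_atoms)
        for i, r in enumerate(rings)
    ]

    def signature(ring_set):
        pairs = find_pairs(ring_set, DetectionConfig())
        stacks = assemble_stacks(pairs)
        return (
            {frozenset((p.ring_a.residue_seq, p.ring_b.residue_seq)) for p in pairs},
            sorted((s.size, s.interchain,
                    tuple(sorted(r.residue_seq for r in s.rings))) for s in stacks),
        )

    assert signature(moved) == signature(rings)


def test_detection_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(distance_threshold=-1)
    with pytest.raises(ValueError):
        DetectionConfig(min_rings_report=1)
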