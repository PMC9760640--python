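import itertools

import numpy as np
import pytest

from biofilm3d.tracking import PARENT, TRACK, CellVertex, LineageEdge, LineageGraph
from biofilm3d.track_metrics import (
    EDGE_ONLY,
    FULL_EQUAL,
    AOGMWeights,
    aogm,
    identity_correspondence,
    match_vertices,
    tra_scores,
)


def make_graph(vertex_keys, edges):
    g = LineageGraph()
    for f, i in vertex_keys:
        g.vertices[(f, i)] = CellVertex(f, i, (0.0, 0.0, float(i)), 1.0, 1.0)
    for src, dst, sem in edges:
        g.edges.append(LineageEdge(src, dst, sem))
    return g


def brute_force_min_edge_cost(est, gt, corr):
    """Exhaustive minimal edit cost on edges, given the vertex correspondence.

    Enumerates every subset of estimated edges to keep; kept edges must map
    onto distinct reference edges (semantics fixable at cost 1), deleted
    edges cost 1, reference edges not covered cost 1.
    """
    gt_edges = {(e.src, e.dst): e.semantics for e in gt.edges}
    est_edges = [(e.src, e.dst, e.semantics) for e in est.edges]
    inv = {v: k for k, v in corr.mapping.items()}  # est key -> gt key
    best = None
    for keep_mask in itertools.product([0, 1], repeat=len(est_edges)):
        cost = 0
        covered = set()
        feasible = True
        for keep, (src, dst, sem) in zip(keep_mask, est_edges):
            if not keep:
                cost += 1  # deletion
                continue
            g_src, g_dst = inv.get(src), inv.get(dst)
            if g_src is None or g_dst is None or (g_src, g_dst) not in gt_edges:
                feasible = False
                break
            if (g_src, g_dst) in covered:
                feasible = False
                break
            covered.add((g_src, g_dst))
            if gt_edges[(g_src, g_dst)] != sem:
                cost += 1  # semantics change
        if not feasible:
            continue
        cost += len(gt_edges) - len(covered)  # additions
        best = cost if best is None else min(best, cost)
    return best


def random_graph_pair(rng):
    """Random small reference lineage + corrupted estimate on shared vertices."""
    n_frames = int(rng.integers(2, 4))
    keys = []
    for f in range(n_frames):
        for i in range(1, int(rng.integers(1, 4)) + 1):
            keys.append((f, i))
    keys = keys[:8]
    gt_edges = []
    for (f, i) in keys:
        if f == 0:
            continue
        prev = [k for k in keys if k[0] == f - 1]
        if prev and rng.random() < 0.8:
            src = prev[int(rng.integers(len(prev)))]
            sem = TRACK if rng.random() < 0.7 else PARENT
            if sum(1 for s, d, _ in gt_edges if d == (f, i)) == 0:
                gt_edges.append((src, (f, i), sem))
    gt = make_graph(keys, gt_edges)
    # corrupt: drop/flip some edges, add a spurious one
    est_edges = []
    for src, dst, sem in gt_edges:
        r = rng.random()
        if r < 0.2:
            continue  # dropped edge
        if r < 0.4:
            sem = PARENT if sem == TRACK else TRACK  # flipped semantics
        est_edges.append((src, dst, sem))
    by_frame = {}
    for k in keys:
        by_frame.setdefault(k[0], []).append(k)
    for f in range(n_frames - 1):
        if rng.random() < 0.3 and by_frame.get(f) and by_frame.get(f + 1):
            src = by_frame[f][int(rng.integers(len(by_frame[f])))]
            dst = by_frame[f + 1][int(rng.integers(len(by_frame[f + 1])))]
            if not any(d == dst for _, d, _ in est_edges) and not any(
                s == src and d == dst for s, d, _ in est_edges
            ):
                est_edges.append((src, dst, TRACK))
    est = make_graph(keys, est_edges)
    return est, gt


class TestMatchVertices:
    def test_identical_frames_bijection(self, two_spheres):
        corr = match_vertices([two_spheres], [two_spheres])
        assert corr.ns == 0 and corr.fn == 0 and corr.fp == 0
        assert len(corr.mapping) == 2

    def test_merge_counts_missed_split(self, two_spheres):
        merged = (two_spheres > 0).astype(np.int32)
        corr = match_vertices([merged], [two_spheres])
        assert corr.ns == 1
        assert corr.fp == 0 and corr.fn == 0

    def test_partial_overlap_equals_coverage_computation(self):
        rng = np.random.default_rng(4)
        gt = np.zeros((8, 12, 12), np.int32)
        gt[2:6, 2:6, 2:6] = 1
        gt[2:6, 7:11, 7:11] = 2
        est = np.zeros_like(gt)
        est[2:6, 3:7, 2:6] = 5  # covers most of gt 1
        est[2:6, 9:11, 7:11] = 7  # covers exactly half of gt 2 -> not >50%
        corr = match_vertices([est], [gt])
        assert corr.mapping == {(0, 1): (0, 5)}
        assert (0, 2) in corr.fn_vertices
        assert (0, 7) in corr.fp_vertices
        _ = rng

    def test_frame_count_mismatch_rejected(self, two_spheres):
        with pytest.raises(ValueError):
            match_vertices([two_spheres], [two_spheres, two_spheres])


class TestAOGM:
    def test_perfect_estimate_tra_one(self, small_colony_frames):
        from biofilm3d.tracking import lineage_from_colony

        gt = lineage_from_colony(small_colony_frames)
        corr = identity_correspondence(gt, gt)
        rep = aogm(gt, gt, corr, FULL_EQUAL)
        assert rep.aogm == 0 and rep.tra == 1.0

    def test_empty_estimate_tra_zero(self):
        keys = [(0, 1), (1, 1), (2, 1)]
        gt = make_graph(keys, [((0, 1), (1, 1), TRACK), ((1, 1), (2, 1), TRACK)])
        est = LineageGraph()
        corr = identity_correspondence(est, gt)
        rep = aogm(est, gt, corr, FULL_EQUAL)
        assert rep.aogm == rep.aogm0 and rep.tra == 0.0

    def test_one_missing_edge_of_ten(self):
        keys = [(0, i) for i in range(1, 11)] + [(1, i) for i in range(1, 11)]
        edges = [((0, i), (1, i), TRACK) for i in range(1, 11)]
        gt = make_graph(keys, edges)
        est = make_graph(keys, edges[:-1])
        rep = aogm(est, gt, identity_correspondence(est, gt), EDGE_ONLY)
        assert rep.EA == 1 and rep.ED == 0
        assert rep.tra == pytest.approx(0.9)

    def test_empty_reference_rejected(self):
        est = make_graph([(0, 1)], [])
        with pytest.raises(ValueError):
            aogm(est, LineageGraph(), identity_correspondence(est, LineageGraph()))

    def test_edge_counts_match_brute_force_search(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(40):
            est, gt = random_graph_pair(rng)
            if not gt.vertices or not gt.edges:
                continue
            corr = identity_correspondence(est, gt)
            rep = aogm(est, gt, corr, EDGE_ONLY)
            oracle = brute_force_min_edge_cost(est, gt, corr)
            assert rep.aogm == oracle
            checked += 1
        assert checked >= 20

    def test_adding_erroneous_edge_never_increases_tra(self):
        keys = [(0, 1), (0, 2), (1, 1), (1, 2)]
        edges = [((0, 1), (1, 1), TRACK)]
        gt = make_graph(keys, edges)
        est1 = make_graph(keys, edges)
        est2 = make_graph(keys, edges + [((0, 2), (1, 2), TRACK)])
        corr1 = identity_correspondence(est1, gt)
        corr2 = identity_correspondence(est2, gt)
        for w in (EDGE_ONLY, FULL_EQUAL):
            assert aogm(est2, gt, corr2, w).tra <= aogm(est1, gt, corr1, w).tra

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            AOGMWeights(w_NS=-1)


class TestTRAScores:
    def test_perfect_tracking(self, small_colony_frames):
        from biofilm3d.tracking import lineage_from_colony

        gt = lineage_from_colony(small_colony_frames)
        assert tra_scores(gt, gt) == (1.0, 1.0)

    def test_fn_vertices_penalize_edges_only_via_ea(self):
        keys = [(0, 1), (1, 1), (2, 1)]
        gt = make_graph(keys, [((0, 1), (1, 1), TRACK), ((1, 1), (2, 1), TRACK)])
        est = make_graph([(0, 1), (1, 1)], [((0, 1), (1, 1), TRACK)])
        rep = aogm(est, gt, identity_correspondence(est, gt), EDGE_ONLY)
        assert rep.EA == 1 and rep.ED == 0 and rep.EC == 0
        assert rep.tra == pytest.approx(0.5)

    def test_ec_share_of_total_errors(self):
        # 20 reference edges; estimate flips semantics on 2 and misses 18
        keys = [(0, i) for i in range(1, 21)] + [(1, i) for i in range(1, 21)]
        gt_edges = [((0, i), (1, i), TRACK) for i in range(1, 21)]
        est_edges = [((0, 1), (1, 1), PARENT), ((0, 2), (1, 2), PARENT)]
        gt = make_graph(keys, gt_edges)
        est = make_graph(keys, est_edges)
        rep = aogm(est, gt, identity_correspondence(est, gt), EDGE_ONLY)
        total_errors = rep.EA + rep.ED + rep.EC
        assert rep.EC == 2 and total_errors == 20
        assert rep.EC / total_errors == pytest.approx(0.10)

    def test_tra_bounds(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            est, gt = random_graph_pair(rng)
            if not gt.vertices:
                continue
            corr = identity_correspondence(est, gt)
            for w in (EDGE_ONLY, FULL_EQUAL):
                if w is EDGE_ONLY and not gt.edges:
                    continue
                rep = aogm(est, gt, corr, w)
                assert 0.0 <= rep.tra <= 1.0
                assert (rep.tra == 1.0) == (rep.aogm == 0.0)
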