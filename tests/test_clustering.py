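"""k-center / k-medoid splitting and the product (combination) scheme."""

import itertools

import numpy as np
import pytest

from solvmsm import k_center, k_medoid, merge_smallest_states, product_split
from solvmsm.clustering import ProductClustering, _ProductState, _build_product
from solvmsm.metrics import DistanceFunction


class EuclideanMetric(DistanceFunction):
    """Plain Euclidean metric on points, for geometry-only tests."""

    def __init__(self, kind="euclid"):
        super().__init__(kind=kind)

    def prepare(self, frames):
        self._pts = np.asarray(frames, dtype=float)

    @property
    def n_frames(self):
        return len(self._pts)

    def dist(self, i, j):
        self.n_evaluations += 1
        return float(np.linalg.norm(self._pts[i] - self._pts[j]))

    def dist_row(self, i):
        self.n_evaluations += len(self._pts)
        return np.linalg.norm(self._pts - self._pts[i], axis=1)


def brute_force_kcenter_radius(points, K):
    """Optimal k-center radius by exhaustive search over center subsets."""
    pts = np.asarray(points, float)
    N = len(pts)
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    best = np.inf
    for centers in itertools.combinations(range(N), K):
        radius = D[list(centers)].min(axis=0).max()
        best = min(best, radius)
    return best


class TestKCenter:
    def test_every_frame_its_own_center_when_K_equals_N(self, rng):
        pts = list(rng.normal(size=(7, 2)))
        cl = k_center(pts, 7, EuclideanMetric(), seed=0)
        assert cl.radius == 0.0
        assert sorted(cl.center_indices.tolist()) == list(range(7))

    def test_K1_radius_is_max_distance_from_first_center(self, rng):
        pts = list(rng.normal(size=(9, 2)))
        metric = EuclideanMetric()
        cl = k_center(pts, 1, metric, seed=5)
        first = cl.center_indices[0]
        expected = np.linalg.norm(np.asarray(pts) - pts[first], axis=1).max()
        assert cl.radius == pytest.approx(expected)

    def test_two_approximation_on_random_instances(self, rng):
        violations = 0
        for trial in range(50):
            N = int(rng.integers(6, 15))
            K = int(rng.integers(2, 5))
            pts = rng.uniform(0, 10, size=(N, 2))
            cl = k_center(list(pts), K, EuclideanMetric(), seed=trial)
            opt = brute_force_kcenter_radius(pts, K)
            if cl.radius > 2 * opt + 1e-9:
                violations += 1
        assert violations == 0

    def test_assignment_is_nearest_center(self, rng):
        pts = rng.normal(size=(20, 2))
        metric = EuclideanMetric()
        cl = k_center(list(pts), 4, metric, seed=2)
        D = np.linalg.norm(pts[:, None] - pts[cl.center_indices][None], axis=-1)
        assigned = D[np.arange(20), cl.labels]
        assert (assigned <= D.min(axis=1) + 1e-12).all()

    def test_evaluation_budget_at_most_KN(self, rng):
        pts = list(rng.normal(size=(30, 2)))
        metric = EuclideanMetric()
        cl = k_center(pts, 5, metric, seed=0)
        assert cl.n_metric_evaluations <= 5 * 30

    def test_seed_determinism(self, rng):
        pts = list(rng.normal(size=(15, 2)))
        a = k_center(pts, 3, EuclideanMetric(), seed=9)
        b = k_center(pts, 3, EuclideanMetric(), seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.center_indices, b.center_indices)

    def test_K_larger_than_N_rejected(self, rng):
        with pytest.raises(ValueError):
            k_center(list(rng.normal(size=(3, 2))), 4, EuclideanMetric(), seed=0)


class TestKMedoid:
    def test_recovers_two_separated_groups(self, rng):
        a = rng.normal(size=(8, 2)) * 0.2
        b = rng.normal(size=(8, 2)) * 0.2 + 50.0
        pts = list(np.vstack([a, b]))
        cl = k_medoid(pts, 2, EuclideanMetric(), seed=1)
        labels = cl.labels
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_objective_not_worse_than_15x_brute_force(self, rng):
        for trial in range(10):
            pts = rng.uniform(0, 5, size=(9, 2))
            cl = k_medoid(list(pts), 2, EuclideanMetric(), seed=trial)
            D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            ours = D[np.arange(9), cl.center_indices[cl.labels]].sum()
            best = min(
                D[:, list(c)].min(axis=1).sum()
                for c in itertools.combinations(range(9), 2)
            )
            assert ours >= best - 1e-9
            assert ours <= 1.5 * best + 1e-9

    def test_objective_trace_monotone_nonincreasing(self, rng):
        pts = list(rng.uniform(0, 5, size=(25, 2)))
        cl = k_medoid(pts, 3, EuclideanMetric(), seed=4)
        trace = cl.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def two_channel_points(rng, n=24):
    """Points with independent 2-valued 'solute' and 'solvent' coordinates."""
    solute_bit = rng.integers(2, size=n)
    solvent_bit = rng.integers(2, size=n)
    solute_pts = solute_bit[:, None] * 10.0 + rng.normal(scale=0.1, size=(n, 1))
    solvent_pts = solvent_bit[:, None] * 10.0 + rng.normal(scale=0.1, size=(n, 1))
    return solute_pts, solvent_pts, solute_bit, solvent_bit


class PairMetric(DistanceFunction):
    """Euclidean metric reading one named component of (solute, solvent) pairs."""

    def __init__(self, which, kind=None):
        super().__init__(kind=kind or which)
        self.which = 0 if which == "solute" else 1

    def prepare(self, frames):
        self._pts = np.asarray([f[self.which] for f in frames], dtype=float)

    @property
    def n_frames(self):
        return len(self._pts)

    def dist(self, i, j):
        self.n_evaluations += 1
        return float(np.linalg.norm(self._pts[i] - self._pts[j]))

    def dist_row(self, i):
        self.n_evaluations += len(self._pts)
        return np.linalg.norm(self._pts - self._pts[i], axis=1)


class TestProductSplit:
    def _frames(self, rng, n=24):
        sp, vp, sb, vb = two_channel_points(rng, n)
        return list(zip(sp, vp)), sb, vb

    def test_K2_equals_1_reproduces_solute_only_clustering(self, rng):
        frames, _, _ = self._frames(rng)
        pc = product_split(
            frames, K=2, K1=2, K2=1,
            solute_metric=PairMetric("solute"),
            solvent_metric=PairMetric("solvent"),
            seed=7,
        )
        # the derived solute seed is the first of two ints drawn from the master
        s1 = int(np.random.default_rng(7).integers(2**31, size=2)[0])
        solo = k_center(frames, 2, PairMetric("solute"), seed=s1)
        assert np.array_equal(pc.labels, solo.labels)

    def test_K1_equals_1_reproduces_solvent_only_clustering(self, rng):
        frames, _, _ = self._frames(rng)
        pc = product_split(
            frames, K=2, K1=1, K2=2,
            solute_metric=PairMetric("solute"),
            solvent_metric=PairMetric("solvent"),
            seed=7,
        )
        s2 = int(np.random.default_rng(7).integers(2**31, size=2)[1])
        solo = k_center(frames, 2, PairMetric("solvent"), seed=s2)
        assert np.array_equal(pc.labels, solo.labels)

    def test_independent_bits_give_four_product_states(self, rng):
        frames, sb, vb = self._frames(rng, n=40)
        pc = product_split(
            frames, K=4, K1=2, K2=2,
            solute_metric=PairMetric("solute"),
            solvent_metric=PairMetric("solvent"),
            seed=3,
        )
        assert pc.K == 4
        # microstate equality iff both hidden bits equal
        pairs = list(zip(sb.tolist(), vb.tolist()))
        for i in range(len(frames)):
            for j in range(len(frames)):
                assert (pc.labels[i] == pc.labels[j]) == (pairs[i] == pairs[j])

    def test_cost_scales_with_K1_plus_K2(self, rng):
        frames, _, _ = self._frames(rng, n=60)
        K1, K2 = 3, 3
        pc = product_split(
            frames, K=4, K1=K1, K2=K2,
            solute_metric=PairMetric("solute"),
            solvent_metric=PairMetric("solvent"),
            seed=0,
        )
        assert pc.n_metric_evaluations <= (pc.solute.K + pc.solvent.K) * len(frames)


class TestMergeSmallestStates:
    def _manual_product(self):
        """6 occupied 1-D states with hand-set populations and centers.

        Centers on a line at x = 0, 1, 2, 10, 11, 30 with populations
        [8, 1, 6, 7, 9, 2].  Both metrics see the same geometry, so the
        combined distance is twice the normalized line distance.
        """
        centers = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 30.0])
        pops = [8, 1, 6, 7, 9, 2]
        frames = [(np.array([c]), np.array([c])) for c in centers]
        sm, vm = PairMetric("solute"), PairMetric("solvent")
        sm.prepare(frames)
        vm.prepare(frames)
        states = [
            _ProductState(
                state_id=i, pairs=[(i, i)], population=pops[i],
                constituents=[(pops[i], i, i, i)],
            )
            for i in range(6)
        ]
        from solvmsm.clustering import Clustering

        sol = Clustering(
            labels=np.arange(6), center_indices=np.arange(6), radius=0.0,
            metric_kind="solute",
        )
        solv = Clustering(
            labels=np.arange(6), center_indices=np.arange(6), radius=0.0,
            metric_kind="solvent",
        )
        labels = np.concatenate([[i] * p for i, p in enumerate(pops)])
        pc = ProductClustering(
            solute=sol, solvent=solv, state_map={(i, i): i for i in range(6)},
            labels=labels, K=6, solute_metric=sm, solvent_metric=vm,
            _states=states,
        )
        return pc, pops

    def test_merge_sequence_matches_hand_trace(self):
        pc, pops = self._manual_product()
        # hand trace of the rule "smallest population merges into the state
        # with minimum normalized combined center distance":
        #  step 1: smallest is state 1 (pop 1, x=1); nearest states 0 (d=1)
        #          and 2 (d=1) tie -> lower id 0 absorbs it  (pop 0 -> 9)
        #  step 2: smallest is state 5 (pop 2, x=30); nearest is state 4
        #          (x=11, d=19) -> 4 absorbs it              (pop 4 -> 11)
        # final populations: {0:9, 2:6, 3:7, 4:11} -> dense relabel by
        # decreasing population: 4->0, 0->1, 3->2, 2->3
        merged = merge_smallest_states(pc, 4)
        assert merged.K == 4
        new_pops = merged.populations()
        assert new_pops.tolist() == [11, 9, 7, 6]
        # state 1's frames went with state 0's; state 5's with state 4's
        lab = merged.labels
        assert len(set(lab[8:9].tolist()) | set(lab[:8].tolist())) == 1
        assert len(set(lab[-2:].tolist()) | set(lab[22:31].tolist())) == 1

    def test_no_merge_when_already_K(self):
        pc, _ = self._manual_product()
        out = merge_smallest_states(pc, 6)
        assert out.K == 6
        # dense relabel by population only
        assert np.array_equal(np.sort(out.populations())[::-1], out.populations())

    def test_merge_below_K_rejected(self):
        pc, _ = self._manual_product()
        with pytest.raises(ValueError):
            merge_smallest_states(pc, 7)
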