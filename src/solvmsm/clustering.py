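"""Geometric splitting of configurations into microstates.

The split step groups all N configurations into K microstates with a fast
geometric clustering algorithm — greedy farthest-point k-center (a
2-approximation of the optimal k-center radius at K·N metric evaluations)
or k-medoid — under either the solute RMSD metric or the solvent signature
metric.

The *combination model* clusters twice independently — K₁ solute clusters
under RMSD and K₂ solvent clusters under the signature metric — and defines
a microstate as a pair (solute cluster, solvent cluster).  Two frames share
a microstate iff they share both cluster labels.  With K₁ = K₂ = ⌈√K⌉ the
split costs O((K₁+K₂)·N) = O(√K·N) metric evaluations instead of O(K·N).
Occupied product states in excess of K are reduced by repeatedly merging
the smallest state into its geometrically nearest neighbour.

The solute-only model is the special case K₂ = 1 and the solvent-only
model is K₁ = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import DistanceFunction, collect_frames

__all__ = [
    "Clustering",
    "ProductClustering",
    "k_center",
    "k_medoid",
    "product_split",
    "merge_smallest_states",
]


@dataclass
class Clustering:
    """Assignment of frames to K clusters around concrete center frames."""

    labels: np.ndarray
    center_indices: np.ndarray
    radius: float
    metric_kind: str
    seed: int | None = None
    n_metric_evaluations: int = 0

    @property
    def K(self) -> int:
        return len(self.center_indices)

    def populations(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


def _as_frames(trajs):
    if isinstance(trajs, (list, np.ndarray)) and trajs and not hasattr(trajs[0], "frames"):
        return list(trajs)
    return collect_frames(trajs)


def k_center(trajs, K: int, metric: DistanceFunction, seed: int = 0) -> Clustering:
    """Greedy farthest-point (Gonzalez) k-center clustering.

    The first center is a seeded-random frame; every subsequent center is
    the frame farthest from all existing centers.  Each frame is assigned
    to its nearest center (ties to the earliest-added center).  Uses at
    most K·N metric evaluations and returns a radius within a factor 2 of
    the optimal k-center radius.
    """
    frames = _as_frames(trajs)
    N = len(frames)
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, {N}], got {K}")
    metric.prepare(frames)
    evals_before = metric.n_evaluations
    rng = np.random.default_rng(seed)
    first = int(rng.integers(N))
    centers = [first]
    dist_to_center = metric.dist_row(first)
    labels = np.zeros(N, dtype=int)
    for k in range(1, K):
        nxt = int(np.argmax(dist_to_center))
        centers.append(nxt)
        row = metric.dist_row(nxt)
        closer = row < dist_to_center
        labels[closer] = k
        dist_to_center = np.where(closer, row, dist_to_center)
    return Clustering(
        labels=labels,
        center_indices=np.array(centers, dtype=int),
        radius=float(dist_to_center.max()),
        metric_kind=metric.kind,
        seed=seed,
        n_metric_evaluations=metric.n_evaluations - evals_before,
    )


def k_medoid(
    trajs,
    K: int,
    metric: DistanceFunction,
    seed: int = 0,
    max_iter: int = 100,
) -> Clustering:
    """Alternating k-medoid refinement from a seeded k-center start.

    The objective (sum of distances to assigned medoids) is non-increasing
    per iteration; stops at a fixed point or after ``max_iter`` sweeps.
    """
    frames = _as_frames(trajs)
    N = len(frames)
    init = k_center(frames, K, metric, seed=seed)
    medoids = list(init.center_indices)
    labels = init.labels.copy()
    evals_before = metric.n_evaluations

    def assign(meds):
        rows = np.vstack([metric.dist_row(m) for m in meds])  # (K, N)
        lab = np.argmin(rows, axis=0)
        return lab, float(rows[lab, np.arange(N)].sum()), rows

    labels, objective, rows = assign(medoids)
    objective_trace = [objective]
    for _ in range(max_iter):
        new_medoids = []
        for k in range(K):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                new_medoids.append(medoids[k])
                continue
            # medoid = member minimizing total distance to the others
            sub = np.array(
                [[metric.dist(i, j) for j in members] for i in members]
            )
            new_medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
        new_labels, new_objective, rows = assign(new_medoids)
        objective_trace.append(new_objective)
        if new_medoids == medoids and np.array_equal(new_labels, labels):
            break
        medoids, labels, objective = new_medoids, new_labels, new_objective
    radius = float(
        max(rows[labels[i], i] for i in range(N))
    )
    result = Clustering(
        labels=labels,
        center_indices=np.array(medoids, dtype=int),
        radius=radius,
        metric_kind=metric.kind,
        seed=seed,
        n_metric_evaluations=metric.n_evaluations - evals_before,
    )
    result.objective_trace = objective_trace
    return result


@dataclass
class _ProductState:
    """One occupied (solute, solvent) product state, possibly merged."""

    state_id: int
    pairs: list
    population: int
    # constituents: list of (population, state_id, solute_center, solvent_center)
    constituents: list = field(default_factory=list)

    def representative(self):
        """Centers of the largest-population constituent (ties: lower id)."""
        best = max(self.constituents, key=lambda c: (c[0], -c[1]))
        return best[2], best[3]


@dataclass
class ProductClustering:
    """Combination of an independent solute and solvent clustering.

    ``state_map`` sends occupied (solute label, solvent label) pairs to
    microstate ids; after merging there are exactly ``K`` microstates and a
    pair may map to a merged id shared with other pairs.
    """

    solute: Clustering
    solvent: Clustering
    state_map: dict
    labels: np.ndarray
    K: int
    solute_metric: DistanceFunction | None = None
    solvent_metric: DistanceFunction | None = None
    _states: list = field(default_factory=list)

    @property
    def n_metric_evaluations(self) -> int:
        return self.solute.n_metric_evaluations + self.solvent.n_metric_evaluations

    def populations(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


def _build_product(solute_cl, solvent_cl, solute_metric, solvent_metric):
    pair_labels = list(zip(solute_cl.labels.tolist(), solvent_cl.labels.tolist()))
    occupied = sorted(set(pair_labels))
    state_map = {pair: i for i, pair in enumerate(occupied)}
    labels = np.array([state_map[p] for p in pair_labels], dtype=int)
    pops = np.bincount(labels, minlength=len(occupied))
    states = []
    for i, (a, b) in enumerate(occupied):
        states.append(
            _ProductState(
                state_id=i,
                pairs=[(a, b)],
                population=int(pops[i]),
                constituents=[
                    (
                        int(pops[i]),
                        i,
                        int(solute_cl.center_indices[a]),
                        int(solvent_cl.center_indices[b]),
                    )
                ],
            )
        )
    return ProductClustering(
        solute=solute_cl,
        solvent=solvent_cl,
        state_map=state_map,
        labels=labels,
        K=len(occupied),
        solute_metric=solute_metric,
        solvent_metric=solvent_metric,
        _states=states,
    )


def product_split(
    trajs,
    K: int,
    K1: int | None = None,
    K2: int | None = None,
    solute_metric: DistanceFunction = None,
    solvent_metric: DistanceFunction = None,
    seed: int = 0,
    mode: str = "global",
    max_increments: int = 5,
) -> ProductClustering:
    """Split into K microstates by combining solute and solvent clusterings.

    Runs k-center twice independently (K₁ clusters under the solute metric,
    K₂ under the solvent metric, seeds derived from the master seed) and
    intersects the labels.  If fewer than K product states are occupied,
    K₁ and K₂ are incremented (up to ``max_increments`` times) and the
    split repeated; more than K occupied states are reduced to exactly K by
    :func:`merge_smallest_states`.

    ``mode="nested"`` clusters solvent separately *within* each solute
    cluster instead of globally.
    """
    frames = _as_frames(trajs)
    N = len(frames)
    if K1 is None:
        K1 = max(1, math.ceil(math.sqrt(K))) if K2 is None else math.ceil(K / K2)
    if K2 is None:
        K2 = math.ceil(K / K1)
    if K1 * K2 < K:
        raise ValueError(f"K1*K2 = {K1 * K2} < K = {K}")
    if K > N:
        raise ValueError(f"K must be <= number of frames ({N})")
    rng = np.random.default_rng(seed)
    s1, s2 = (int(v) for v in rng.integers(2**31, size=2))

    k1, k2 = K1, K2
    for attempt in range(max_increments + 1):
        solute_cl = k_center(frames, min(k1, N), solute_metric, seed=s1)
        if mode == "nested":
            solvent_cl = _nested_solvent(frames, solute_cl, min(k2, N), solvent_metric, s2)
        else:
            solvent_cl = k_center(frames, min(k2, N), solvent_metric, seed=s2)
        pc = _build_product(solute_cl, solvent_cl, solute_metric, solvent_metric)
        if pc.K >= K:
            if pc.K > K:
                pc = merge_smallest_states(pc, K)
            return pc
        k1, k2 = k1 + 1, k2 + 1
    raise RuntimeError(
        f"could not reach {K} occupied product states within "
        f"{max_increments} increments (achieved {pc.K})"
    )


def _nested_solvent(frames, solute_cl, K2, solvent_metric, seed):
    """Per-solute-cluster solvent clustering (the alternate combination)."""
    N = len(frames)
    labels = np.zeros(N, dtype=int)
    centers = []
    radius = 0.0
    evals = 0
    next_label = 0
    for a in range(solute_cl.K):
        members = np.flatnonzero(solute_cl.labels == a)
        sub_frames = [frames[i] for i in members]
        kk = min(K2, len(sub_frames))
        sub = k_center(sub_frames, kk, solvent_metric, seed=seed + a)
        labels[members] = sub.labels + next_label
        centers.extend(members[sub.center_indices].tolist())
        radius = max(radius, sub.radius)
        evals += sub.n_metric_evaluations
        next_label += kk
    return Clustering(
        labels=labels,
        center_indices=np.array(centers, dtype=int),
        radius=radius,
        metric_kind=solvent_metric.kind,
        seed=seed,
        n_metric_evaluations=evals,
    )


def merge_smallest_states(pc: ProductClustering, K: int) -> ProductClustering:
    """Reduce the occupied product states to exactly K by absorbing the
    smallest.

    Repeatedly the occupied state with the smallest population (ties: lower
    state id) is merged into the state minimizing the normalized combined
    center distance d = d_solute/D_solute + d_solvent/D_solvent, where each
    D is the diameter of the respective cluster-center set.  A merged
    state's representative centers are those of its largest constituent.
    Final labels are dense 0..K−1 ordered by decreasing population.
    """
    if pc.K < K:
        raise ValueError(f"occupied states ({pc.K}) < K ({K})")
    states = {s.state_id: s for s in pc._states}
    sm, vm = pc.solute_metric, pc.solvent_metric

    def diameter(metric, centers):
        cs = sorted(set(centers))
        dmax = 0.0
        for i, a in enumerate(cs):
            for b in cs[i + 1:]:
                dmax = max(dmax, metric.dist(a, b))
        return dmax

    solute_centers = [int(c) for c in pc.solute.center_indices]
    solvent_centers = [int(c) for c in pc.solvent.center_indices]
    D1 = diameter(sm, solute_centers) if sm is not None else 1.0
    D2 = diameter(vm, solvent_centers) if vm is not None else 1.0

    def combined(sa, sb):
        ra1, ra2 = sa.representative()
        rb1, rb2 = sb.representative()
        d1 = sm.dist(ra1, rb1) if (sm is not None and D1 > 0) else 0.0
        d2 = vm.dist(ra2, rb2) if (vm is not None and D2 > 0) else 0.0
        return (d1 / D1 if D1 > 0 else 0.0) + (d2 / D2 if D2 > 0 else 0.0)

    merged_into = {}  # old id -> surviving id
    while len(states) > K:
        smallest = min(states.values(), key=lambda s: (s.population, s.state_id))
        others = [s for s in states.values() if s.state_id != smallest.state_id]
        dest = min(others, key=lambda s: (combined(smallest, s), s.state_id))
        dest.pairs.extend(smallest.pairs)
        dest.population += smallest.population
        dest.constituents.extend(smallest.constituents)
        merged_into[smallest.state_id] = dest.state_id
        del states[smallest.state_id]

    def resolve(i):
        while i in merged_into:
            i = merged_into[i]
        return i

    survivors = sorted(
        states.values(), key=lambda s: (-s.population, s.state_id)
    )
    new_id = {s.state_id: r for r, s in enumerate(survivors)}
    state_map = {
        pair: new_id[resolve(old)] for pair, old in pc.state_map.items()
    }
    labels = np.array(
        [new_id[resolve(int(l))] for l in pc.labels], dtype=int
    )
    new_states = []
    for s in survivors:
        ns = _ProductState(
            state_id=new_id[s.state_id],
            pairs=list(s.pairs),
            population=s.population,
            constituents=list(s.constituents),
        )
        new_states.append(ns)
    return ProductClustering(
        solute=pc.solute,
        solvent=pc.solvent,
        state_map=state_map,
        labels=labels,
        K=K,
        solute_metric=sm,
        solvent_metric=vm,
        _states=new_states,
    )
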