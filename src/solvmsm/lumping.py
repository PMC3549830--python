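"""Lumping microstates into macrostates by metastability maximization.

Given a K×K microstate count matrix, the lump step searches for an
assignment of the K microstates to L macrostates maximizing the
metastability Q = Σₐ Tₐₐ of the lumped model.  Q of a candidate assignment
is evaluated by aggregating the micro counts into an L×L macro count
matrix and column-normalizing it — aggregation weights each microstate by
its observed occupancy, exactly the estimator a macro-level model built
from the same trajectories would use.

The optimizer is simulated annealing: per step a microstate is picked
uniformly at random and proposed a uniform random macrostate; moves that
would empty a macrostate are rejected outright; uphill moves are always
accepted and downhill moves with probability exp((Q′−Q)/T) at temperature
T = 1/step (reset each restart).  The best assignment over all restarts is
returned.  For small problems :func:`exhaustive_lump` enumerates every
surjective assignment and serves as the exact reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msm import metastability, transition_matrix

__all__ = [
    "LumpingResult",
    "lump_counts",
    "lump_labels",
    "anneal_lump",
    "exhaustive_lump",
]


@dataclass
class LumpingResult:
    """Best macrostate assignment found, its Q, and the search record."""

    assignment: np.ndarray
    Q: float
    L: int
    trace: list = field(default_factory=list)  # per-restart best Q
    seed: int | None = None
    method: str = "anneal"

    def normalized_Q(self) -> float:
        return self.Q / self.L


def lump_counts(counts: np.ndarray, assignment: np.ndarray, L: int) -> np.ndarray:
    """Aggregate a K×K micro count matrix into L×L macro counts.

    ``macro[a, b] = Σ_{i∈a, j∈b} counts[i, j]``; the total count is
    conserved.  Every macrostate must be non-empty.
    """
    counts = np.asarray(counts)
    assignment = np.asarray(assignment, dtype=int)
    if assignment.min() < 0 or assignment.max() >= L:
        raise ValueError("assignment values must lie in [0, L)")
    if np.unique(assignment).size != L:
        raise ValueError("every macrostate must contain at least one microstate")
    macro = np.zeros((L, L), dtype=counts.dtype)
    np.add.at(macro, (assignment[:, None], assignment[None, :]), counts)
    return macro


def lump_labels(labels: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Map a microstate label sequence through a lumping assignment."""
    return np.asarray(assignment, dtype=int)[np.asarray(labels, dtype=int)]


def _lumped_Q(counts, assignment, L) -> float:
    macro = lump_counts(counts, assignment, L)
    col = macro.sum(axis=0).astype(float)
    diag = np.diag(macro).astype(float)
    # empty source column => self-loop convention, contributes 1
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(col > 0, diag / np.where(col > 0, col, 1.0), 1.0)
    return float(q.sum())


class _AnnealState:
    """Incremental Q bookkeeping for single-microstate moves.

    Maintains the macro count matrix and its column sums; moving microstate
    i between macrostates touches one row and one column, so an update
    costs O(K + L) instead of the O(K²) full aggregation.
    """

    def __init__(self, counts: np.ndarray, assignment: np.ndarray, L: int):
        self.counts = np.asarray(counts, dtype=float)
        self.K = counts.shape[0]
        self.L = L
        self.assignment = np.asarray(assignment, dtype=int).copy()
        self.sizes = np.bincount(self.assignment, minlength=L)
        self.macro = lump_counts(self.counts, self.assignment, L).astype(float)
        self.col = self.macro.sum(axis=0)

    def Q(self) -> float:
        diag = np.diag(self.macro)
        q = np.where(self.col > 0, diag / np.where(self.col > 0, self.col, 1.0), 1.0)
        return float(q.sum())

    def move(self, i: int, b: int) -> None:
        a = self.assignment[i]
        if a == b:
            return
        mask = np.arange(self.K) != i
        in_from = np.bincount(
            self.assignment[mask], weights=self.counts[i, mask], minlength=self.L
        )  # transitions into i from each macro (excluding i itself)
        out_to = np.bincount(
            self.assignment[mask], weights=self.counts[mask, i], minlength=self.L
        )  # transitions out of i into each macro
        cii = self.counts[i, i]
        # remove i's contributions from macrostate a, add them to b
        self.macro[a, :] -= in_from
        self.macro[:, a] -= out_to
        self.macro[a, a] -= cii
        self.assignment[i] = b
        self.macro[b, :] += in_from
        self.macro[:, b] += out_to
        self.macro[b, b] += cii
        self.col = self.macro.sum(axis=0)
        self.sizes[a] -= 1
        self.sizes[b] += 1


def _random_surjective(rng, K: int, L: int) -> np.ndarray:
    """Uniform random assignment, redrawn until all L macrostates occupied."""
    while True:
        a = rng.integers(L, size=K)
        if np.unique(a).size == L:
            return a


def anneal_lump(
    counts: np.ndarray,
    L: int,
    steps: int = 10000,
    restarts: int = 100,
    seed: int = 0,
) -> LumpingResult:
    """Simulated-annealing search for the max-metastability lumping.

    Per restart: random surjective initial assignment; ``steps`` proposal
    steps at temperature T = 1/step; proposals emptying a macrostate are
    rejected; acceptance probability min(1, exp((Q′−Q)/T)).  Returns the
    best assignment over all restarts (macrostates relabeled canonically by
    smallest contained microstate).
    """
    counts = np.asarray(counts)
    K = counts.shape[0]
    if not 1 <= L <= K:
        raise ValueError(f"L must be in [1, {K}], got {L}")
    master = np.random.default_rng(seed)
    best_Q = -np.inf
    best_assignment = None
    trace = []
    for _ in range(restarts):
        rng = np.random.default_rng(int(master.integers(2**31)))
        state = _AnnealState(counts, _random_surjective(rng, K, L), L)
        Q = state.Q()
        restart_best_Q = Q
        restart_best = state.assignment.copy()
        for step in range(1, steps + 1):
            i = int(rng.integers(K))
            b = int(rng.integers(L))
            a = state.assignment[i]
            if b == a:
                continue
            if state.sizes[a] == 1:
                continue  # would empty macrostate a
            state.move(i, b)
            Qp = state.Q()
            if Qp >= Q or rng.random() < math.exp((Qp - Q) * step):
                Q = Qp
                if Q > restart_best_Q:
                    restart_best_Q = Q
                    restart_best = state.assignment.copy()
            else:
                state.move(i, a)  # revert
        trace.append(restart_best_Q)
        if restart_best_Q > best_Q:
            best_Q = restart_best_Q
            best_assignment = restart_best
    return LumpingResult(
        assignment=_canonical(best_assignment),
        Q=best_Q,
        L=L,
        trace=trace,
        seed=seed,
        method="anneal",
    )


def _canonical(assignment: np.ndarray) -> np.ndarray:
    """Relabel macrostates by order of first appearance (smallest micro id)."""
    seen = {}
    out = np.empty_like(assignment)
    for i, a in enumerate(assignment):
        if a not in seen:
            seen[a] = len(seen)
        out[i] = seen[a]
    return out


def _partitions_rgs(K: int, L: int):
    """Restricted-growth strings of length K with exactly L blocks."""
    a = np.zeros(K, dtype=int)

    def rec(i, maxval):
        if i == K:
            if maxval == L - 1:
                yield a.copy()
            return
        # prune: remaining positions must still allow reaching L blocks
        if maxval + (K - i) < L - 1:
            return
        for v in range(min(maxval + 1, L - 1) + 1):
            a[i] = v
            yield from rec(i + 1, max(maxval, v))

    yield from rec(1, 0) if K > 0 else iter(())


def _stirling2(K: int, L: int) -> int:
    S = np.zeros((K + 1, L + 1), dtype=object)
    S[0, 0] = 1
    for k in range(1, K + 1):
        for l in range(1, min(k, L) + 1):
            S[k, l] = l * S[k - 1, l] + S[k - 1, l - 1]
    return int(S[K, L])


def exhaustive_lump(counts: np.ndarray, L: int, max_space: int = 10**6) -> LumpingResult:
    """Globally optimal lumping by enumeration of all set partitions.

    Enumerates the S(K, L) partitions of the K microstates into L
    non-empty blocks (Stirling number of the second kind) and returns the
    assignment with the largest lumped Q; ties go to the lexicographically
    smallest canonical assignment.  Refuses search spaces above
    ``max_space``.
    """
    counts = np.asarray(counts)
    K = counts.shape[0]
    if not 1 <= L <= K:
        raise ValueError(f"L must be in [1, {K}]")
    space = _stirling2(K, L)
    if space > max_space:
        raise ValueError(
            f"search space S({K},{L}) = {space} exceeds limit {max_space}"
        )
    best_Q = -np.inf
    best = None
    for assignment in _partitions_rgs(K, L):
        Q = _lumped_Q(counts, assignment, L)
        if Q > best_Q + 1e-15 or (
            abs(Q - best_Q) <= 1e-15 and tuple(assignment) < tuple(best)
        ):
            best_Q = Q
            best = assignment
    return LumpingResult(
        assignment=best, Q=best_Q, L=L, trace=[best_Q], seed=None, method="exhaustive"
    )
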