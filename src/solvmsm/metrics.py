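"""Configuration distances for the split step.

Two metrics are used to cluster configurations:

* ``solute_rmsd`` — the classical RMSD after an optimal rigid-body
  superposition (Kabsch), computed on the designated solute atoms with
  uniform weights and proper rotations only (no reflections);
* ``solvent_signature`` — the Euclidean distance between the Gaussian
  solvent signatures of the two frames, which inherits permutation
  invariance from the signature itself and is a genuine metric on
  signature space.

No combined single-number distance exists here: the combination model
combines *clusterings*, not distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signature import KernelParams, SignatureVector, signature_matrix
from .traj_io import Trajectory

__all__ = [
    "DistanceFunction",
    "SoluteRMSDMetric",
    "SolventSignatureMetric",
    "kabsch_rmsd",
    "signature_distance",
    "pairwise_distances",
    "collect_frames",
]


def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum RMSD between two point sets over proper rotations/translations.

    min over R (det R = +1), t of sqrt((1/m) Σ ‖A_i − (R B_i + t)‖²).

    The optimal rotation comes from the SVD of the cross-covariance of the
    centred sets, with the sign of the smallest singular vector flipped when
    the raw optimum is a reflection.  Degenerate sets (m < 3, collinear
    points) are handled by the same SVD construction, which reduces to the
    pseudoinverse-based optimal rotation.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    m = A.shape[0]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Bc.T @ Ac
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    # exclude reflections
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Ac - Bc @ R.T
    return float(np.sqrt(np.sum(diff * diff) / m))


def signature_distance(a: SignatureVector, b: SignatureVector) -> float:
    """Euclidean distance ‖a − b‖₂ between two signature vectors.

    Signatures computed at different σ live in incomparable spaces, so a σ
    mismatch is an error rather than a number.
    """
    if len(a) != len(b):
        raise ValueError(f"signature length mismatch: {len(a)} vs {len(b)}")
    if a.sigma != b.sigma:
        raise ValueError(f"sigma mismatch: {a.sigma} vs {b.sigma}")
    return float(np.linalg.norm(a.values - b.values))


def collect_frames(trajs) -> list:
    """Flatten one trajectory or a sequence of trajectories into a frame list."""
    if isinstance(trajs, Trajectory):
        return list(trajs.frames)
    frames = []
    for t in trajs:
        if hasattr(t, "frames"):
            frames.extend(t.frames)
        else:
            frames.append(t)  # already a Configuration / frame-like object
    return frames


@dataclass
class DistanceFunction:
    """Base class: a metric over a fixed frame list, with an evaluation counter.

    ``prepare(frames)`` precomputes whatever representation the metric needs
    (e.g. signatures); ``dist_row(i)`` returns distances from frame i to all
    frames and counts N metric evaluations, which is how clustering cost
    bounds (≤ K·N evaluations for k-center) are audited.
    """

    kind: str = "base"
    n_evaluations: int = field(default=0, init=False)

    def prepare(self, frames) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def n_frames(self) -> int:
        raise NotImplementedError

    def dist(self, i: int, j: int) -> float:
        raise NotImplementedError

    def dist_row(self, i: int) -> np.ndarray:
        raise NotImplementedError


@dataclass
class SoluteRMSDMetric(DistanceFunction):
    """Kabsch RMSD on solute coordinates."""

    kind: str = "solute_rmsd"

    def prepare(self, frames) -> None:
        self._coords = [np.asarray(c.solute_coords, dtype=float) for c in frames]

    @property
    def n_frames(self) -> int:
        return len(self._coords)

    def dist(self, i: int, j: int) -> float:
        self.n_evaluations += 1
        return kabsch_rmsd(self._coords[i], self._coords[j])

    def dist_row(self, i: int) -> np.ndarray:
        N = len(self._coords)
        self.n_evaluations += N
        Ai = self._coords[i]
        return np.array([kabsch_rmsd(Ai, self._coords[j]) for j in range(N)])


@dataclass
class SolventSignatureMetric(DistanceFunction):
    """Euclidean distance between solvent signatures at a fixed σ."""

    params: KernelParams = field(default_factory=KernelParams)
    kind: str = "solvent_signature"

    def prepare(self, frames) -> None:
        if self.params.normalized:
            raise ValueError("signatures use the unnormalized kernel")
        self._sig = signature_matrix(frames, self.params)

    @property
    def n_frames(self) -> int:
        return self._sig.shape[0]

    def dist(self, i: int, j: int) -> float:
        self.n_evaluations += 1
        return float(np.linalg.norm(self._sig[i] - self._sig[j]))

    def dist_row(self, i: int) -> np.ndarray:
        self.n_evaluations += self._sig.shape[0]
        return np.linalg.norm(self._sig - self._sig[i], axis=1)


def pairwise_distances(trajs, metric: DistanceFunction) -> np.ndarray:
    """Full symmetric distance matrix between all frames of the trajectories.

    The block structure of this matrix under the solvent metric is what
    makes metastable solvent states visible by eye (small within-state,
    large between-state distances).
    """
    frames = collect_frames(trajs)
    metric.prepare(frames)
    N = len(frames)
    D = np.zeros((N, N))
    for i in range(N):
        row = metric.dist_row(i)
        D[i] = row
    # enforce exact symmetry and zero diagonal against round-off
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D
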