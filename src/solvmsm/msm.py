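"""Transition counting, transition matrices, propagation, metastability.

Conventions, fixed package-wide:

* counts are indexed ``counts[i, j]`` = number of observed j → i
  transitions at the chosen frame lag (destination row, source column);
* the transition matrix is **column-stochastic**: ``T[i, j]`` is the
  probability of moving to state i given the system is in state j, and the
  population vector evolves as ``P(nτ) = T(τ)ⁿ P(0)``.  Many MSM codes are
  row-stochastic; everything here is column-stochastic.
* counting uses a sliding window with stride 1 and never pairs frames
  across trajectory boundaries.

The *metastability* of an L-state model is Q = Σᵢ Tᵢᵢ ∈ [0, L]: the
expected number of states in which a trajectory remains over one lag time.
Random assignment of frames to K states gives E[Q/K] ≈ 1/K, the natural
baseline for any clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransitionModel",
    "count_transitions",
    "transition_matrix",
    "propagate",
    "metastability",
]


@dataclass
class TransitionModel:
    """Count matrix + column-stochastic transition matrix at one lag."""

    counts: np.ndarray
    T: np.ndarray
    lag_time: float = 1.0
    populations: np.ndarray | None = None
    empty_states: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


def _label_arrays(seqs) -> list[np.ndarray]:
    if isinstance(seqs, np.ndarray) and seqs.ndim == 1:
        return [seqs.astype(int)]
    if len(seqs) and np.isscalar(seqs[0]):
        return [np.asarray(seqs, dtype=int)]
    return [np.asarray(s, dtype=int) for s in seqs]


def count_transitions(seqs, K: int, lag_frames: int = 1) -> np.ndarray:
    """Sliding-window transition counts at an integer frame lag.

    ``seqs`` is one label sequence or a list of them (one per trajectory);
    for every trajectory and every t with t+lag in range,
    ``counts[label(t+lag), label(t)]`` is incremented.  No cross-trajectory
    pairs are counted.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be a positive integer")
    counts = np.zeros((K, K), dtype=np.int64)
    for seq in _label_arrays(seqs):
        if seq.size and (seq.min() < 0 or seq.max() >= K):
            raise ValueError(f"labels must lie in [0, {K}), got range "
                             f"[{seq.min()}, {seq.max()}]")
        if seq.size <= lag_frames:
            continue
        src = seq[:-lag_frames]
        dst = seq[lag_frames:]
        np.add.at(counts, (dst, src), 1)
    return counts


def transition_matrix(counts: np.ndarray, lag_time: float = 1.0) -> TransitionModel:
    """Column-normalize a count matrix into a transition model.

    ``T[i, j] = counts[i, j] / Σᵢ counts[i, j]``.  A state never observed
    as a source (empty column) gets a self-loop ``T[j, j] = 1`` with a
    warning: it contributes exactly 1 to the metastability and is reported
    in ``empty_states`` rather than silently dropped, which would
    desynchronize the state ids.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    col_sums = counts.sum(axis=0).astype(float)
    empty = np.flatnonzero(col_sums == 0)
    if empty.size:
        warnings.warn(
            f"states {empty.tolist()} have no outgoing transitions; "
            "assigning self-loops",
            stacklevel=2,
        )
    safe = np.where(col_sums == 0, 1.0, col_sums)
    T = counts / safe
    for j in empty:
        T[j, j] = 1.0
    populations = counts.sum(axis=0)  # times each state is observed as a source
    return TransitionModel(
        counts=counts,
        T=T,
        lag_time=lag_time,
        populations=populations,
        empty_states=empty,
    )


def propagate(model: TransitionModel, P0: np.ndarray, n: int) -> np.ndarray:
    """Evolve a population vector n lag times: P(nτ) = Tⁿ P(0)."""
    P0 = np.asarray(P0, dtype=float)
    if P0.shape != (model.n_states,):
        raise ValueError("P0 has wrong length")
    if (P0 < -1e-12).any() or abs(P0.sum() - 1.0) > 1e-8:
        raise ValueError("P0 must be a probability distribution")
    if n < 0:
        raise ValueError("n must be non-negative")
    P = P0.copy()
    if n == 0:
        return P
    # repeated squaring keeps error growth mild for large n
    return np.linalg.matrix_power(model.T, n) @ P0


def metastability(model_or_T) -> tuple[float, float]:
    """Metastability Q = Σᵢ Tᵢᵢ and its normalized form Q/L.

    Q ∈ [0, L]; Q = L means no state is ever left within one lag time,
    Q = 1 is what a memoryless uniform chain gives.
    """
    T = model_or_T.T if isinstance(model_or_T, TransitionModel) else np.asarray(model_or_T)
    L = T.shape[0]
    Q = float(np.trace(T))
    return Q, Q / L
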