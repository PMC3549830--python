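"""Synthetic trajectory generators with known metastable structure.

Real solvated-MD datasets are large and rarely deposited; these generators
produce small trajectories whose kinetics are known *exactly*, so every
stage of the pipeline — signatures, metrics, splitting, counting, lumping
— can be validated against ground truth.

``simulate_channel`` emulates a water-filled nanopore: a single-file
lattice of ``n_sites`` sites inside a cylindrical shell of "tube" atoms.
Waters enter and leave only at the two ends, so the occupancy is always a
contiguous block anchored at an end; the hidden dynamics is a
discrete-time Markov chain over the 2·n_sites occupancy states (empty,
full, left-anchored k, right-anchored k), whose transition matrix is
available in closed form.  Left-filling and right-filling partial states
cannot interconvert without passing through empty or full, which is the
hallmark kinetic feature of single-file pore hydration.  Bath waters far
outside the tube keep the solvent count realistic (n ≫ waters near the
solute) and exercise permutation invariance and kernel locality.

``simulate_two_basin`` emulates a small solute hopping between two
conformational basins with a solvent cloud whose mean position differs by
basin — the situation where solvent coordinates carry the slow degrees of
freedom.  The hidden basin label follows a symmetric 2-state chain with
known hop probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signature import CylinderRegion
from .traj_io import Configuration, Trajectory

__all__ = [
    "ChannelParams",
    "TwoBasinParams",
    "SyntheticTrajectory",
    "simulate_channel",
    "simulate_two_basin",
    "channel_transition_matrix",
    "channel_state_class",
    "tube_region",
    "write_ground_truth",
]

# occupancy classes
EMPTY, FULL, LEFT, RIGHT = 0, 1, 2, 3
CLASS_NAMES = {EMPTY: "empty", FULL: "full", LEFT: "left", RIGHT: "right"}


@dataclass(frozen=True)
class ChannelParams:
    """Single-file channel model parameters.

    ``p_enter``/``p_exit`` are per-frame probabilities that an end-adjacent
    empty site fills / filled site empties, per end; the empty state can
    fill from either end (total leave probability 2·p_enter) and the full
    state can drain from either end.  Lengths are in coordinate units.
    """

    n_sites: int = 6
    p_enter: float = 0.02
    p_exit: float = 0.02
    site_spacing: float = 1.0
    tube_radius: float = 1.0
    n_bath: int = 50
    atoms_per_ring: int = 8
    seed: int = 0
    start: str = "empty"  # "empty", "full", or an explicit state index

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not (0 <= self.p_enter <= 0.5 and 0 <= self.p_exit <= 0.5):
            raise ValueError("p_enter and p_exit must lie in [0, 0.5]")
        if self.p_enter + self.p_exit > 1:
            raise ValueError("p_enter + p_exit must not exceed 1")
        if self.site_spacing <= 0 or self.tube_radius <= 0:
            raise ValueError("lengths must be positive")
        if self.n_bath < 0:
            raise ValueError("n_bath must be non-negative")

    @property
    def n_states(self) -> int:
        return 2 * self.n_sites


@dataclass(frozen=True)
class TwoBasinParams:
    """Two-basin solute + shifted-solvent-cloud model parameters.

    The hidden basin label hops with symmetric per-frame probability
    ``hop_probability``; solute coordinates are the basin's reference
    structure plus isotropic Gaussian noise; the solvent cloud is a fixed
    base cloud plus a per-basin mean shift plus noise.  The ratio
    ‖solvent_shift‖ / solvent_noise sets how separable the basins are in
    signature space.
    """

    basin_centers: tuple = None
    hop_probability: float = 0.01
    solute_noise: float = 0.1
    n_solvent: int = 100
    solvent_shift: tuple = (5.0, 0.0, 0.0)
    solvent_noise: float = 1.0
    cloud_spread: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hop_probability < 0.5:
            raise ValueError("hop_probability must lie in (0, 0.5)")
        if self.solute_noise < 0 or self.solvent_noise <= 0:
            raise ValueError("noise scales must be positive")
        if self.basin_centers is None:
            # default: a 5-atom straight chain vs. a zig-zag chain
            straight = np.array([[i, 0.0, 0.0] for i in range(5)])
            zigzag = np.array([[i, (-1.0) ** i, 0.0] for i in range(5)])
            object.__setattr__(self, "basin_centers", (straight, zigzag))
        a, b = self.basin_centers
        if np.asarray(a).shape != np.asarray(b).shape:
            raise ValueError("basin centers must have the same shape")


@dataclass
class SyntheticTrajectory:
    """A generated trajectory plus its hidden ground-truth labels."""

    trajectory: Trajectory
    hidden_states: np.ndarray           # per-frame generator state index
    hidden_classes: np.ndarray | None = None  # channel occupancy class
    params: object = None


# ---------------------------------------------------------------------------
# channel model

def channel_state_class(state: int, n_sites: int) -> int:
    """Map a chain state index to its occupancy class.

    State encoding: 0 = empty; 1..n−1 = left-anchored block of k sites;
    n = full; n+k (k = 1..n−1) = right-anchored block of k sites.
    """
    n = n_sites
    if state == 0:
        return EMPTY
    if state == n:
        return FULL
    if 1 <= state < n:
        return LEFT
    if n < state < 2 * n:
        return RIGHT
    raise ValueError(f"invalid state {state} for n_sites={n}")


def channel_transition_matrix(params: ChannelParams) -> np.ndarray:
    """Closed-form column-stochastic transition matrix of the hidden chain.

    ``T[dest, src]``: from empty the block starts growing at either end
    (p_enter each); a partial block grows at its free inner end (p_enter)
    or shrinks at the same end (p_exit); from full a water leaves at the
    left or right end (p_exit each), anchoring the remaining block at the
    opposite end.
    """
    n = params.n_sites
    pe, px = params.p_enter, params.p_exit
    S = params.n_states
    T = np.zeros((S, S))

    def left(k):  # left-anchored block of k sites
        return k

    def right(k):
        return n + k

    # from empty
    T[left(1), 0] += pe
    T[right(1), 0] += pe
    T[0, 0] = 1.0 - 2.0 * pe
    # from full
    T[right(n - 1), n] += px  # water leaves at left end
    T[left(n - 1), n] += px   # water leaves at right end
    T[n, n] = 1.0 - 2.0 * px
    # partial blocks
    for k in range(1, n):
        for enc in (left, right):
            s = enc(k)
            grow = n if k + 1 == n else enc(k + 1)
            shrink = 0 if k - 1 == 0 else enc(k - 1)
            T[grow, s] += pe
            T[shrink, s] += px
            T[s, s] += 1.0 - pe - px
    assert np.allclose(T.sum(axis=0), 1.0)
    return T


def _occupied_sites(state: int, n_sites: int) -> np.ndarray:
    n = n_sites
    cls = channel_state_class(state, n)
    if cls == EMPTY:
        return np.array([], dtype=int)
    if cls == FULL:
        return np.arange(n)
    if cls == LEFT:
        return np.arange(state)            # sites 0..k-1
    return np.arange(n - (state - n), n)   # right-anchored k = state - n


def tube_region(params: ChannelParams) -> CylinderRegion:
    """Default water-number integration region for the channel.

    Spans the first to the last site center at the tube's inner radius, so
    in the full state the two end waters sit exactly on the flat faces and
    contribute ≈ 1/2 each (full-state water number ≈ n_sites − 1).
    """
    n, d = params.n_sites, params.site_spacing
    return CylinderRegion(
        axis_start=np.array([0.0, 0.0, 0.0]),
        axis_end=np.array([0.0, 0.0, (n - 1) * d]),
        radius=params.tube_radius,
    )


def _bath_positions(rng, n, center, r_in, r_out):
    """Uniform points in a spherical shell (the distant bath)."""
    if n == 0:
        return np.empty((0, 3))
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.random(n)
    r = (u * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
    return center + v * r[:, None]


def simulate_channel(params: ChannelParams, n_frames: int) -> SyntheticTrajectory:
    """Simulate the channel chain and render it as a Trajectory.

    The solute is a fixed cylindrical shell (``atoms_per_ring`` tube atoms
    per site ring); the solvent has a constant count of
    ``n_sites + n_bath`` molecules: site waters sit at their site center
    while their site is occupied and are parked in the distant bath
    otherwise, and bath waters are redrawn in the bath shell every frame.
    Deterministic for a given (params, n_frames).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    n, d = params.n_sites, params.site_spacing
    rng = np.random.default_rng(params.seed)
    T = channel_transition_matrix(params)
    S = params.n_states

    if params.start == "empty":
        state = 0
    elif params.start == "full":
        state = n
    else:
        state = int(params.start)

    # fixed tube shell: one ring of atoms per site
    angles = 2.0 * np.pi * np.arange(params.atoms_per_ring) / params.atoms_per_ring
    rings = []
    for j in range(n):
        ring = np.column_stack(
            [
                params.tube_radius * np.cos(angles),
                params.tube_radius * np.sin(angles),
                np.full(params.atoms_per_ring, j * d),
            ]
        )
        rings.append(ring)
    solute = np.vstack(rings)

    tube_center = np.array([0.0, 0.0, 0.5 * (n - 1) * d])
    tube_len = (n - 1) * d
    r_in, r_out = 3.0 * (tube_len + d), 4.0 * (tube_len + d)

    site_pos = np.column_stack(
        [np.zeros(n), np.zeros(n), np.arange(n) * d]
    )

    states = np.empty(n_frames, dtype=int)
    frames = []
    for t in range(n_frames):
        states[t] = state
        occ = _occupied_sites(state, n)
        n_parked = n - occ.size
        solvent = np.vstack(
            [
                site_pos[occ],
                _bath_positions(rng, n_parked, tube_center, r_in, r_out),
                _bath_positions(rng, params.n_bath, tube_center, r_in, r_out),
            ]
        )
        frames.append(
            Configuration(solute_coords=solute, solvent_coords=solvent, frame_index=t)
        )
        state = int(rng.choice(S, p=T[:, state]))

    traj = Trajectory(frames=frames, trajectory_id=f"channel-seed{params.seed}")
    classes = np.array([channel_state_class(s, n) for s in states])
    return SyntheticTrajectory(
        trajectory=traj, hidden_states=states, hidden_classes=classes, params=params
    )


# ---------------------------------------------------------------------------
# two-basin model

def simulate_two_basin(params: TwoBasinParams, n_frames: int) -> SyntheticTrajectory:
    """Simulate the two-basin solute + shifted-solvent model.

    The hidden basin label follows a symmetric 2-state Markov chain; frame
    t renders solute = basin center + N(0, solute_noise²) and solvent =
    base cloud + basin · solvent_shift + N(0, solvent_noise²).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(params.seed)
    centers = [np.asarray(c, dtype=float) for c in params.basin_centers]
    shift = np.asarray(params.solvent_shift, dtype=float)

    # fixed base solvent cloud: compact Gaussian centred on the solute, so a
    # per-basin mean shift genuinely redistributes solvent across the solute
    centroid = np.vstack(centers).reshape(-1, 3).mean(axis=0)
    base = centroid + rng.normal(scale=params.cloud_spread,
                                 size=(params.n_solvent, 3))

    basin = int(rng.integers(2))
    labels = np.empty(n_frames, dtype=int)
    frames = []
    for t in range(n_frames):
        labels[t] = basin
        solute = centers[basin] + rng.normal(
            scale=params.solute_noise, size=centers[basin].shape
        )
        solvent = (
            base
            + basin * shift
            + rng.normal(scale=params.solvent_noise, size=base.shape)
        )
        frames.append(
            Configuration(solute_coords=solute, solvent_coords=solvent, frame_index=t)
        )
        if rng.random() < params.hop_probability:
            basin = 1 - basin

    traj = Trajectory(frames=frames, trajectory_id=f"twobasin-seed{params.seed}")
    return SyntheticTrajectory(trajectory=traj, hidden_states=labels, params=params)


def write_ground_truth(result: SyntheticTrajectory, path: str | Path) -> None:
    """Write per-frame hidden labels as TSV (frame_index, hidden label[, class])."""
    import pandas as pd

    data = {"frame_index": np.arange(len(result.hidden_states)),
            "hidden_state": result.hidden_states}
    if result.hidden_classes is not None:
        data["occupancy_class"] = [CLASS_NAMES[c] for c in result.hidden_classes]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
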