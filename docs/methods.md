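# Methods

This note records the models implemented in `solvmsm`, their assumptions,
the numerical choices made where the design was genuinely open, and what
the synthetic generators do and do not emulate.

## Solvent signatures

A frame is reduced to two point sets: solute atoms X (m×3) and one point
per water molecule — its oxygen — Y (n×3).  The solvent signature
f(X, Y) assigns each solute atom the kernel-weighted count of nearby
waters, f(x, Y) = Σᵢ exp(−‖x−yᵢ‖²/2σ²).  Three properties motivate this
construction: it is continuous in all coordinates (the kernel gradient is
bounded by e^{−1/2}/σ, so a perturbation of every water by δ moves each
entry by at most n·(δ/σ)·e^{−1/2} to first order); it is symmetric in
the waters, so the physically meaningless solvent ordering cannot
influence anything downstream; and waters beyond a few σ of the solute
are exponentially negligible.  Matching-based alternatives (minimum-cost
flow, Hungarian assignment) achieve permutation invariance at O(n³);
the signature costs O(mn).

Implementation detail: per-atom kernel terms are summed in sorted order,
which makes every signature-derived quantity *bit-identical* — not merely
equal to round-off — under solvent permutations.  This is cheap
(O(n log n) per atom) and turns the invariance into an exactly testable
contract.

**Bandwidth σ** is a free parameter in coordinate units.  It should match
the length scale of the solvent structure of interest: of the order of a
site spacing for pore occupancy (we use σ = 1/3 of a site spacing in the
channel examples), of the order of the solvent-cloud scale for
basin-discrimination (σ = 2, the cloud spread, in the two-basin
examples).  Signatures computed at different σ are incomparable and the
metric refuses to mix them.

## Water number

For a concave solute with a pore, the occupancy observable is the
integral of the solvent density over a user-supplied cylinder V, with
the *normalized* kernel (2πσ²)^{−3/2}·exp(−‖x−y‖²/2σ²).  The
normalization constant is the unique choice integrating to 1 over ℝ³,
which is required for the σ→0 limit ∫_V K(x, yᵢ)dx → 1(yᵢ ∈ V); a
molecule exactly on a flat face of V contributes 1/2 in that limit.
V is always supplied by the user: the method itself offers no principled
way to infer a region of interest, which is exactly why the signature
(which needs no region) exists.

Per molecule the integral factorizes along the cylinder axis:

* axial factor — 1-D Gaussian mass between the two faces, a difference
  of Gaussian CDFs;
* radial factor — mass of an offset isotropic 2-D Gaussian inside a
  disk, evaluated by adaptive quadrature of the Rice density
  (u/σ²)·exp(−(u−ρ)²/2σ²)·I₀(uρ/σ²) written with the exponentially
  scaled Bessel function for stability, to 10⁻¹⁰ absolute tolerance,
  over the window |u−ρ| ≤ 8σ outside which the integrand is negligible.

The tests cross-check this against two independent routes: the
noncentral-χ² CDF identity ((r/σ)² of the offset Gaussian is χ²₂ with
noncentrality (ρ/σ)²) and a seeded Monte-Carlo volume integral.

## Metrics and splitting

Two frame distances drive the split step: Kabsch RMSD on the solute
atoms (uniform weights, proper rotations only; degenerate point sets
fall back to the same SVD construction with the determinant correction)
and the Euclidean distance between solvent signatures.  No combined
scalar distance is defined — the combination model combines
*clusterings*, not metrics; the only combined distance appears in the
tie-break rule when merging product states.

Splitting uses greedy farthest-point k-center: seeded-random first
center, then repeatedly the frame farthest from all centers.  This is
the classical 2-approximation of the optimal k-center radius and costs
exactly K·N metric evaluations; it was preferred over k-medoid (also
provided) because it yields clusters of approximately equal radius.
Metric objects count their evaluations, so cost claims are audited by
the test suite rather than asserted.

The combination model runs k-center twice — K₁ clusters under RMSD, K₂
under the signature metric, seeds derived from the master seed — and
takes occupied (solute, solvent) label pairs as microstates, at
O((K₁+K₂)·N) cost; K₁ = K₂ = ⌈√K⌉ by default.  If fewer than K product
states are occupied (strongly correlated solute and solvent labels),
K₁ and K₂ are incremented, at most five times, before failing loudly.
Excess states are reduced to exactly K by repeatedly merging the
smallest-population state (ties: lower id) into the state minimizing
d_solute/D_solute + d_solvent/D_solvent, where d's are distances between
the states' representative cluster centers and D's are the diameters of
the center sets.  A merged state is represented by the centers of its
largest constituent.  The destination rule and tie-breaks are this
package's choice — the merge step itself only requires "smallest first" —
and geometric coherence was preferred over arbitrary absorption.  A
nested variant (per-solute-cluster solvent clustering) is available
behind `mode="nested"`.

## Transition estimation and metastability

Counts use a sliding window at integer frame lag with stride 1, never
across trajectory boundaries, with no symmetrization or detailed-balance
enforcement.  The transition matrix is **column-stochastic**
(T[i,j] = P(j→i)); note many MSM packages are row-stochastic.  States
never observed as a source get a self-loop and a warning rather than
silent removal, which would desynchronize state ids; such states
contribute exactly 1 to Q and are reported.  Metastability is
Q = Σᵢ Tᵢᵢ ∈ [0, L]; uniform random assignment of frames to K states
gives E[Q/K] ≈ 1/K, the baseline used throughout.  (The finite-sample
estimator of Q/K under random labels is biased low by O(1/N); baseline
comparisons use sequences long enough — 10⁴ frames — for the bias to be
well inside the Monte-Carlo error.)

## Lumping

A candidate lumping's Q is evaluated by aggregating the micro count
matrix into macro counts and column-normalizing.  This is the key
interpretive decision: aggregation weights microstates by observed
occupancy, which is the estimator a macro-level model built from the
same trajectories would use (the alternative — averaging micro T
entries — weights all microstates equally regardless of population).

The annealer follows the classic recipe: per restart a random surjective
initial assignment (rejection-sampled); per step a uniformly random
microstate is proposed a uniformly random macrostate; moves emptying a
macrostate are rejected; uphill moves are always accepted, downhill with
probability exp((Q′−Q)/T) at T = 1/step (equal Q counts as uphill,
exp(0)=1); the temperature resets each restart and the best assignment
over all restarts wins.  Moves are applied via O(K)-incremental
bookkeeping of the macro count matrix, verified in tests against the
naive aggregate-and-normalize route.  Defaults are 10000 steps and 100
restarts; the validation suite uses 20 restarts, which already attains
the exhaustive optimum on essentially every small random instance.
`exhaustive_lump` enumerates all S(K, L) set partitions
(restricted-growth strings) and refuses search spaces above 10⁶.

## Synthetic generators

**Channel model.**  A single-file lattice of `n_sites` sites (default 6)
inside a cylindrical shell of tube atoms.  Occupancy is always a
contiguous block anchored at an end; the hidden state space is
{empty, full, left-anchored k, right-anchored k} (2·n_sites states) with
per-frame enter/exit probabilities at the ends (defaults
p_enter = p_exit = 0.02), giving a closed-form transition matrix.  The
defining kinetic feature — left-filling and right-filling configurations
interconvert only via empty or full — is exactly representable and is
recovered by the pipeline as a near-zero left↔right macro transition
probability.  To keep the solvent count constant across frames, waters
not currently in the tube are parked in a distant bath shell (redrawn
every frame; 50 bath waters by default so n greatly exceeds the waters
near the solute, exercising permutation invariance and kernel locality).
The default integration region spans the first to the last site center,
so in the full state the two end waters sit exactly on the faces and the
water number reads n_sites − 1 (interior sites plus two halves).  Unlike
the physical pore it emulates, the chain's partial states are not
especially transient — with uniform enter/exit probabilities every
occupancy state is long-lived — so state populations are roughly
uniform rather than concentrated in empty/full.

**Two-basin model.**  A small solute hops between two reference
structures (default: straight vs zig-zag 5-atom chain) with symmetric
per-frame hop probability 0.01; solute coordinates add isotropic noise
(0.1).  The solvent is a fixed compact Gaussian cloud (spread 2.0,
100 waters) centred on the solute, displaced per basin by a mean shift
(5.0 along x) plus per-frame noise (1.0) — a shift/noise ratio of 5,
at which signature clustering separates the basins essentially
perfectly.  Hidden labels are returned for ground-truth evaluation.

What passing tests on these generators show: the estimators recover
known kinetics, the clustering recovers known structure, and every
invariant holds under realistic permutation/noise conditions.  What they
do not show: behaviour under force-field physics — hydrogen-bond
networks, realistic water packing, box periodicity artefacts, or
thermostat effects are not modelled.

## Trajectory I/O and units

Multi-frame XYZ and multi-model PDB (via biotite) are supported;
coordinates are taken verbatim from the file and all lengths (σ,
cylinder dimensions) are interpreted in the file's units (Å for PDB by
convention).  No periodic boundary treatment is applied by default; an
optional orthorhombic box switches all signature displacement
computations to the minimum-image convention, since explicit-solvent MD
is periodic and ignoring wrap-around would corrupt signatures near box
edges.  Water selection in PDB files defaults to atoms named O/OW in
residues HOH/WAT/SOL/TIP3, overridable by explicit indices.

## Problem sizes and determinism

The validation suite works at desk scale: channel and two-basin
recovery use 20 000-frame simulations, the model-comparison experiment
2 000 frames with K = 16 microstates and L = 4 macrostates
(annealing 2 000 steps × 10 restarts), the annealer–oracle comparison
20 random instances with K ≤ 8 at the full 10 000-step schedule with 20
restarts, and stochastic checks use 3-standard-error bands.  Every
stochastic component takes an explicit seed; identical seeds reproduce
trajectories, clusterings and lumpings bit-for-bit.

## Known limitations

* k-center is outlier-sensitive by construction; a single aberrant frame
  can become a cluster center.
* The annealer's 1/step cooling is aggressive; hard instances may need
  restarts rather than longer schedules.
* The water-number cylinder is a fixed region; no automatic region
  inference is attempted.
* No reversible (detailed-balance) estimator, implied-timescale or
  Chapman–Kolmogorov diagnostics, or Bayesian uncertainty — the package
  implements split–lump construction, not model validation.
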