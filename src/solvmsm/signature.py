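"""Gaussian solvent signatures, the water-number observable, and PCA.

The solvent signature of a configuration ``{X, Y}`` is the length-m vector

    f(X, Y) = ( f(x_1, Y), ..., f(x_m, Y) ),   f(x, Y) = Σ_i K(x, y_i),

where ``K(x, y) = exp(−‖x−y‖² / 2σ²)`` is an (unnormalized) Gaussian
kernel.  Summing kernels over all solvent molecules makes the signature
invariant under their permutation, continuous in every coordinate, and
insensitive to solvent far from the solute — the three properties needed to
compare solvent distributions without solving an assignment problem.

For concave solutes (a nanopore), the *water number* is the integral of the
solvent density over a cylindrical region V using the **normalized** kernel
``(2πσ²)^{−3/2} exp(−‖x−y‖²/2σ²)``:

    w(V) = Σ_i ∫_V K(x, y_i) dx .

As σ → 0 each term tends to the indicator 1(y_i ∈ V), so w counts the
molecules inside V, except that it is continuous: a molecule sitting
exactly on a flat face contributes 1/2.  The normalization constant is
(2πσ²)^{−3/2}, the unique choice for which the 3-D kernel integrates to 1
and hence for which the δ-function limit holds.

The per-molecule integral factorizes along the cylinder axis: the axial
factor is a difference of Gaussian CDFs between the two faces; the radial
factor is the mass of an offset isotropic 2-D Gaussian inside a disk,
evaluated by adaptive quadrature of the Rice density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special
from scipy.stats import norm

from .traj_io import Configuration, minimum_image_displacement

__all__ = [
    "KernelParams",
    "SignatureVector",
    "CylinderRegion",
    "gaussian_kernel",
    "point_signature",
    "signature_vector",
    "signature_matrix",
    "water_number",
    "pca_signatures",
]


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel bandwidth σ (coordinate units) and normalization flag.

    Signatures use the unnormalized kernel (values in (0, 1] per molecule);
    the water number uses the normalized kernel (a probability density).
    The flag exists so the two cannot be mixed accidentally.
    """

    sigma: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def norm_const(self) -> float:
        return (2.0 * np.pi * self.sigma**2) ** -1.5 if self.normalized else 1.0


@dataclass(frozen=True)
class SignatureVector:
    """Per-solute-atom solvent density summary for one frame."""

    values: np.ndarray
    sigma: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("signature values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CylinderRegion:
    """A finite cylinder: axis segment from ``axis_start`` to ``axis_end``,
    of the given radius.  This is the integration volume V of the water
    number; it is always user-supplied, never inferred from the solute."""

    axis_start: np.ndarray
    axis_end: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        a = np.asarray(self.axis_start, dtype=float).ravel()
        b = np.asarray(self.axis_end, dtype=float).ravel()
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("axis endpoints must be 3-vectors")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if np.allclose(a, b):
            raise ValueError("degenerate cylinder: axis_start == axis_end")
        object.__setattr__(self, "axis_start", a)
        object.__setattr__(self, "axis_end", b)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.axis_end - self.axis_start))

    @property
    def axis_unit(self) -> np.ndarray:
        d = self.axis_end - self.axis_start
        return d / np.linalg.norm(d)


def gaussian_kernel(x: np.ndarray, y: np.ndarray, params: KernelParams) -> float:
    """K(x, y) = c · exp(−‖x−y‖²/2σ²), c = 1 or (2πσ²)^{−3/2}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d2 = float(np.sum((x - y) ** 2))
    return params.norm_const * float(np.exp(-d2 / (2.0 * params.sigma**2)))


def point_signature(
    x: np.ndarray,
    Y: np.ndarray,
    params: KernelParams,
    box: np.ndarray | None = None,
) -> float:
    """f(x, Y) = Σ_i K(x, y_i); the empty sum is 0.

    Invariant under permutation of the rows of Y by construction.  With a
    periodic ``box``, displacements use the minimum-image convention.
    """
    Y = np.asarray(Y, dtype=float).reshape(-1, 3)
    if Y.shape[0] == 0:
        return 0.0
    delta = minimum_image_displacement(Y - np.asarray(x, dtype=float), box)
    d2 = np.sort(np.einsum("ij,ij->i", delta, delta))
    # summing in sorted order makes the result bit-identical under any
    # permutation of the solvent rows, not merely equal up to round-off
    return params.norm_const * float(np.exp(-d2 / (2.0 * params.sigma**2)).sum())


def signature_vector(conf: Configuration, params: KernelParams) -> SignatureVector:
    """Signature vector f(X, Y) of one configuration (O(m·n) kernel evals)."""
    X = conf.solute_coords
    Y = conf.solvent_coords
    if Y.shape[0] == 0:
        vals = np.zeros(X.shape[0])
    else:
        delta = minimum_image_displacement(
            Y[None, :, :] - X[:, None, :], conf.box
        )  # (m, n, 3)
        d2 = np.sort(np.einsum("ijk,ijk->ij", delta, delta), axis=1)
        # sorted summation: bit-identical under solvent permutation
        vals = params.norm_const * np.exp(-d2 / (2.0 * params.sigma**2)).sum(axis=1)
    return SignatureVector(values=vals, sigma=params.sigma, frame_index=conf.frame_index)


def signature_matrix(frames, params: KernelParams) -> np.ndarray:
    """Stack signature vectors of many frames into an (N, m) array."""
    return np.vstack([signature_vector(c, params).values for c in frames])


# ---------------------------------------------------------------------------
# water number

def _radial_disk_mass(rho: float, r: float, sigma: float) -> float:
    """Mass of an isotropic 2-D Gaussian (std σ, centred at distance ρ from
    the disk centre) inside a disk of radius r.

    Integrand is the Rice density written with the exponentially scaled
    Bessel function for stability:
        u/σ² · exp(−(u−ρ)²/2σ²) · i0e(uρ/σ²).
    Adaptive quadrature to 1e-10 absolute tolerance; equivalently
    1 − Q₁(ρ/σ, r/σ) with the Marcum Q-function.
    """
    if r <= 0:
        return 0.0
    s2 = sigma * sigma

    def integrand(u: float) -> float:
        return (u / s2) * np.exp(-((u - rho) ** 2) / (2.0 * s2)) * special.i0e(
            u * rho / s2
        )

    # Integrate only where the Gaussian has support: the density is
    # negligible outside |u − ρ| > 8σ.
    lo = max(0.0, rho - 8.0 * sigma)
    hi = min(r, rho + 8.0 * sigma)
    if hi <= lo:
        # Disk entirely outside (or inside) the Gaussian support window.
        return 0.0 if rho > r else 1.0
    val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-10, limit=200)
    return min(max(val, 0.0), 1.0)


def water_number(
    conf: Configuration, region: CylinderRegion, sigma: float
) -> float:
    """Continuous count of solvent molecules inside the cylinder.

    Returns Σ_i ∫_V K(x, y_i) dx with the normalized kernel; the value lies
    in [0, n] and is continuous in every coordinate.  Per molecule the
    integral separates into (axial factor) × (radial factor): the 1-D
    Gaussian mass between the two faces (difference of error functions)
    times the 2-D Gaussian mass inside the disk at the molecule's radial
    offset.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    Y = conf.solvent_coords
    if Y.shape[0] == 0:
        return 0.0
    a = region.axis_start
    u = region.axis_unit
    L = region.length
    rel = Y - a
    t = rel @ u                                   # axial coordinate in [0, L] if inside
    radial_vec = rel - np.outer(t, u)
    rho = np.linalg.norm(radial_vec, axis=1)

    axial = norm.cdf((L - t) / sigma) - norm.cdf(-t / sigma)
    radial = np.array([_radial_disk_mass(p, region.radius, sigma) for p in rho])
    # sorted summation keeps the value bit-identical under solvent permutation
    return float(np.sort(axial * radial).sum())


# ---------------------------------------------------------------------------
# PCA of signatures

def pca_signatures(signatures, n_components: int):
    """Principal components of a set of signature vectors.

    Parameters
    ----------
    signatures : sequence of :class:`SignatureVector` or an (N, m) array.
    n_components : number of components to keep (≤ m).

    Returns
    -------
    components : (n_components, m) orthonormal rows, by decreasing variance.
    projections : (N, n_components) mean-centred data on those axes.
    explained_variance : per-component variance (covariance eigenvalues).

    Mean-centring only, no variance scaling; the sign of each component is
    fixed by making its largest-magnitude loading positive, so output is
    deterministic across runs.
    """
    if hasattr(signatures, "ndim"):
        data = np.asarray(signatures, dtype=float)
    else:
        sigs = list(signatures)
        if len(sigs) and isinstance(sigs[0], SignatureVector):
            data = np.vstack([s.values for s in sigs])
        else:
            data = np.asarray(sigs, dtype=float)
    N, m = data.shape
    if N < 2:
        raise ValueError("PCA requires at least 2 signatures")
    if not 1 <= n_components <= m:
        raise ValueError(f"n_components must be in [1, {m}]")

    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    projections = pca.fit_transform(data)
    components = pca.components_.copy()
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            projections[:, k] *= -1.0
    return components, projections, pca.explained_variance_.copy()
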