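"""Gaussian solvent signatures, the water number, and signature PCA."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import ncx2

from solvmsm import (
    Configuration,
    CylinderRegion,
    KernelParams,
    gaussian_kernel,
    pca_signatures,
    point_signature,
    signature_matrix,
    signature_vector,
    water_number,
)
from solvmsm.signature import _radial_disk_mass

from conftest import random_configuration


class TestKernel:
    def test_zero_distance_unnormalized_is_one(self):
        p = KernelParams(sigma=0.7)
        assert gaussian_kernel([1, 2, 3], [1, 2, 3], p) == 1.0

    def test_closed_form_at_sigma_sqrt2(self):
        sigma = 0.9
        x = np.zeros(3)
        y = np.array([sigma * np.sqrt(2), 0, 0])
        val = gaussian_kernel(x, y, KernelParams(sigma=sigma))
        assert val == pytest.approx(np.exp(-1), abs=1e-12)

    def test_normalized_kernel_integrates_to_one(self):
        # quadrature oracle over a generous bounding box
        sigma = 0.5
        p = KernelParams(sigma=sigma, normalized=True)
        y = np.array([0.3, -0.2, 0.1])
        val, _ = integrate.tplquad(
            lambda z, yy, xx: gaussian_kernel(np.array([xx, yy, z]), y, p),
            y[0] - 6 * sigma, y[0] + 6 * sigma,
            y[1] - 6 * sigma, y[1] + 6 * sigma,
            y[2] - 6 * sigma, y[2] + 6 * sigma,
            epsabs=1e-8,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            KernelParams(sigma=0.0)


class TestPointSignature:
    def test_empty_solvent_gives_zero(self):
        assert point_signature(np.zeros(3), np.empty((0, 3)), KernelParams()) == 0.0

    def test_two_copies_of_x_gives_two(self):
        x = np.array([1.0, 1.0, 1.0])
        Y = np.vstack([x, x])
        assert point_signature(x, Y, KernelParams(sigma=2.0)) == 2.0

    def test_bitwise_permutation_invariance(self, rng):
        x = rng.normal(size=3)
        Y = rng.normal(size=(40, 3))
        p = KernelParams(sigma=0.8)
        ref = point_signature(x, Y, p)
        for _ in range(20):
            perm = rng.permutation(40)
            assert point_signature(x, Y[perm], p) == ref


class TestSignatureVector:
    def test_single_atom_reduces_to_point_signature(self, rng):
        conf = random_configuration(rng, m=1, n=9)
        p = KernelParams(sigma=1.3)
        sv = signature_vector(conf, p)
        assert sv.values[0] == point_signature(
            conf.solute_coords[0], conf.solvent_coords, p
        )

    def test_distant_solvent_contributes_nothing(self, rng):
        sigma = 0.5
        X = rng.normal(size=(3, 3))
        Y = rng.normal(size=(7, 3)) + 100.0  # all farther than 10 sigma
        conf = Configuration(X, Y)
        sv = signature_vector(conf, KernelParams(sigma=sigma))
        assert (sv.values < 3 * 7 * np.exp(-50)).all()

    def test_continuity_bound_under_small_perturbation(self, rng):
        # kernel gradient magnitude is at most e^{-1/2}/sigma, so moving
        # every solvent point by delta changes each entry by at most
        # n * (delta/sigma) * e^{-1/2} to first order
        sigma, n = 1.0, 25
        p = KernelParams(sigma=sigma)
        conf = random_configuration(rng, m=4, n=n, spread=2.0)
        delta = sigma / 10
        for _ in range(10):
            step = rng.normal(size=(n, 3))
            step *= delta / np.linalg.norm(step, axis=1, keepdims=True)
            moved = Configuration(conf.solute_coords, conf.solvent_coords + step)
            change = np.abs(
                signature_vector(moved, p).values - signature_vector(conf, p).values
            )
            bound = n * (delta / sigma) * np.exp(-0.5) * 1.01
            assert (change <= bound).all()

    def test_entries_bounded_by_solvent_count(self, rng):
        conf = random_configuration(rng, m=5, n=11)
        sv = signature_vector(conf, KernelParams(sigma=3.0))
        assert (sv.values >= 0).all() and (sv.values <= 11).all()


class TestWaterNumber:
    region = CylinderRegion(
        axis_start=np.array([0.0, 0.0, 0.0]),
        axis_end=np.array([0.0, 0.0, 10.0]),
        radius=2.0,
    )

    def _conf(self, points):
        return Configuration(np.zeros((1, 3)), np.asarray(points, dtype=float))

    def test_centered_molecule_counts_as_one(self):
        conf = self._conf([[0, 0, 5.0]])
        w = water_number(conf, self.region, sigma=self.region.radius / 20)
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_molecule_on_flat_face_contributes_half(self):
        conf = self._conf([[0, 0, 0.0]])
        for sigma in (0.1, 0.02):
            assert water_number(conf, self.region, sigma) == pytest.approx(
                0.5, abs=1e-6
            )

    def test_radial_disk_mass_matches_noncentral_chi2(self, rng):
        # independent route: (radius/sigma)^2 of an offset 2-D Gaussian is
        # noncentral chi-square with 2 dof and noncentrality (rho/sigma)^2
        for _ in range(25):
            sigma = float(rng.uniform(0.05, 1.5))
            rho = float(rng.uniform(0, 4))
            r = float(rng.uniform(0.1, 4))
            ours = _radial_disk_mass(rho, r, sigma)
            ref = ncx2.cdf((r / sigma) ** 2, df=2, nc=(rho / sigma) ** 2)
            assert ours == pytest.approx(ref, abs=1e-7)

    def test_matches_monte_carlo_volume_integral(self, rng):
        # MC oracle: w = V * E_{x~U(V)}[sum_i K(x, y_i)]
        sigma = 0.8
        Y = rng.uniform([-1, -1, -1], [1, 1, 11], size=(12, 3))
        conf = self._conf(Y)
        w = water_number(conf, self.region, sigma)
        nsamp = 200_000
        z = rng.uniform(0, 10, nsamp)
        r = self.region.radius * np.sqrt(rng.uniform(0, 1, nsamp))
        th = rng.uniform(0, 2 * np.pi, nsamp)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        c = (2 * np.pi * sigma**2) ** -1.5
        d2 = ((pts[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
        dens = c * np.exp(-d2 / (2 * sigma**2)).sum(1)
        V = np.pi * self.region.radius**2 * 10
        est, se = V * dens.mean(), V * dens.std(ddof=1) / np.sqrt(nsamp)
        assert abs(w - est) < 3 * se

    def test_bounded_by_solvent_count(self, rng):
        conf = self._conf(rng.uniform(-3, 13, size=(30, 3)))
        w = water_number(conf, self.region, sigma=1.0)
        assert 0.0 <= w <= 30.0

    def test_degenerate_cylinder_rejected(self):
        with pytest.raises(ValueError):
            CylinderRegion(np.zeros(3), np.zeros(3), 1.0)
        with pytest.raises(ValueError):
            CylinderRegion(np.zeros(3), np.ones(3), -1.0)


class TestPCA:
    def test_line_data_fully_explained_by_first_component(self, rng):
        direction = rng.normal(size=6)
        t = rng.normal(size=40)
        data = np.outer(t, direction) + 3.0
        comps, proj, ev = pca_signatures(data, 3)
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_projection_reconstructs_centered_data(self, rng):
        data = rng.normal(size=(30, 5))
        comps, proj, ev = pca_signatures(data, 5)
        recon = proj @ comps
        np.testing.assert_allclose(recon, data - data.mean(0), atol=1e-10)

    def test_explained_variance_matches_eig_oracle(self, rng):
        data = rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6))
        _, _, ev = pca_signatures(data, 6)
        eig = np.sort(np.linalg.eigvalsh(np.cov(data.T)))[::-1]
        np.testing.assert_allclose(ev, eig, rtol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        data = rng.normal(size=(20, 4))
        comps, _, _ = pca_signatures(data, 4)
        for row in comps:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_signatures(rng.normal(size=(10, 3)), 4)
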