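import numpy as np
import pytest
from sklearn.kernel_ridge import KernelRidge

from mesopath.free_energy import (
    MeanForceKRLS,
    UmbrellaWindow,
    bootstrap_profile,
    estimate_mean_force,
    integrate_profile,
    krls_fit,
    profile_from_windows,
)
from mesopath.synthetic import Potential1D, gen_restrained_samples


def gaussian_elimination_solve(A, b):
    """Independent dense solve: partial-pivot elimination, back substitution."""
    A = A.astype(float).copy()
    b = b.astype(float).copy()
    n = len(b)
    for col in range(n):
        piv = col + int(np.argmax(np.abs(A[col:, col])))
        A[[col, piv]] = A[[piv, col]]
        b[[col, piv]] = b[[piv, col]]
        for row in range(col + 1, n):
            m = A[row, col] / A[col, col]
            A[row, col:] -= m * A[col, col:]
            b[row] -= m * b[col]
    x = np.zeros(n)
    for row in range(n - 1, -1, -1):
        x[row] = (b[row] - A[row, row + 1 :] @ x[row + 1 :]) / A[row, row]
    return x


class TestMeanForce:
    def test_symmetric_samples_give_zero(self):
        w = UmbrellaWindow(center=2.0, kappa=10.0, samples=np.array([1.5, 2.5, 1.0, 3.0]))
        f, _ = estimate_mean_force(w)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_linear_potential_recovers_minus_slope(self):
        g, kappa = 1.7, 60.0
        pot = Potential1D(form="linear", params={"g": g})
        samples = gen_restrained_samples(pot, kappa, center=0.0, n_samples=4000, seed=8)
        w = UmbrellaWindow(center=0.0, kappa=kappa, samples=samples)
        f, se = estimate_mean_force(w)
        assert abs(f - (-g)) < 3 * se

    def test_flat_potential_force_is_zero(self):
        pot = Potential1D(form="harmonic", params={"a": 0.0})
        samples = gen_restrained_samples(pot, 25.0, center=1.0, n_samples=4000, seed=3)
        w = UmbrellaWindow(center=1.0, kappa=25.0, samples=samples)
        f, se = estimate_mean_force(w)
        assert abs(f) < 3 * se

    def test_force_samples_route_agrees_in_expectation(self, rng):
        s = rng.normal(1.2, 0.1, size=5000)
        kappa, center = 50.0, 1.0
        w_disp = UmbrellaWindow(center=center, kappa=kappa, samples=s)
        w_force = UmbrellaWindow(
            center=center, kappa=kappa, samples=s, force_samples=kappa * (s - center)
        )
        f1, _ = estimate_mean_force(w_disp)
        f2, _ = estimate_mean_force(w_force)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_too_few_samples_rejected(self):
        w = UmbrellaWindow(center=0.0, kappa=1.0, samples=np.array([1.0]))
        with pytest.raises(ValueError):
            estimate_mean_force(w)


class TestKRLS:
    def test_constant_targets_reproduced(self, rng):
        centers = np.linspace(1, 27, 8)
        model = krls_fit(centers, np.full(8, 3.3), sigma=25.0, lambda_reg=1e-8)
        assert np.allclose(model.predict(centers), 3.3, atol=1e-5)

    def test_dual_coefficients_match_gaussian_elimination(self, rng):
        centers = rng.uniform(0, 10, size=5)
        targets = rng.normal(0, 1, size=5)
        sigma, lam = 2.0, 1e-6
        model = krls_fit(centers, targets, sigma=sigma, lambda_reg=lam)
        K = np.exp(-((centers[:, None] - centers[None, :]) ** 2) / (2 * sigma**2))
        alpha = gaussian_elimination_solve(K + lam * np.eye(5), targets)
        assert np.allclose(model.dual_coef_, alpha, atol=1e-8)

    def test_matches_sklearn_kernel_ridge(self, rng):
        centers = rng.uniform(0, 10, size=12)
        targets = np.sin(centers)
        sigma, lam = 1.5, 1e-4
        ours = krls_fit(centers, targets, sigma=sigma, lambda_reg=lam)
        ref = KernelRidge(kernel="rbf", gamma=1.0 / (2 * sigma**2), alpha=lam)
        ref.fit(centers[:, None], targets)
        grid = np.linspace(0, 10, 50)
        assert np.allclose(ours.predict(grid), ref.predict(grid[:, None]), atol=1e-8)

    def test_interpolation_limit_as_regularization_vanishes(self, rng):
        centers = np.linspace(-1, 1, 7)
        targets = rng.normal(0, 1, size=7)
        err = []
        for lam in (1e-2, 1e-6, 1e-10):
            model = krls_fit(centers, targets, sigma=0.5, lambda_reg=lam)
            err.append(np.abs(model.predict(centers) - targets).max())
        assert err[0] > err[1] > err[2]
        assert err[2] < 1e-6

    def test_duplicate_centers_without_ridge_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            krls_fit([1.0, 1.0, 2.0], [0.0, 0.0, 1.0], sigma=1.0, lambda_reg=0.0)

    def test_estimator_interface(self):
        est = MeanForceKRLS(sigma=5.0)
        assert est.get_params() == {"sigma": 5.0, "lambda_reg": 1e-8}
        est.set_params(lambda_reg=1e-6)
        est.fit(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert est.train_interval_ == (0.0, 2.0)


class TestIntegration:
    def test_zero_force_gives_flat_profile(self):
        model = krls_fit(np.linspace(0, 10, 6), np.zeros(6))
        prof = integrate_profile(model, np.linspace(0, 10, 200))
        assert np.allclose(prof.F, 0.0, atol=1e-9)

    def test_constant_force_integrates_linearly(self):
        model = krls_fit(np.linspace(0, 2, 6), np.full(6, -1.0), sigma=25.0)
        prof = integrate_profile(model, np.linspace(0, 2, 400))
        assert prof.F[0] == 0.0
        assert prof.F[-1] == pytest.approx(2.0, abs=1e-4)

    def test_extrapolation_warns_but_computes(self):
        model = krls_fit(np.linspace(0, 1, 5), np.ones(5))
        with pytest.warns(UserWarning, match="extrapolat"):
            prof = integrate_profile(model, np.linspace(-1, 2, 300))
        assert np.all(np.isfinite(prof.F))

    def test_dense_targets_reduce_reconstruction_error(self):
        """Noise-free mean forces: finer center spacing shrinks the error."""
        pot = Potential1D(form="double_well", params={"h": 3.0, "s0": 8.0, "w": 5.0})
        errs = []
        for n_centers in (9, 17):
            centers = np.linspace(1.0, 15.0, n_centers)
            model = krls_fit(centers, -pot.derivative(centers))
            grid = np.linspace(1.0, 15.0, 800)
            prof = integrate_profile(model, grid)
            diff = prof.F - pot.energy(grid)
            errs.append(np.abs(diff - diff.mean()).max())
        assert errs[1] < errs[0]


class TestBootstrap:
    def make_windows(self, rng, n=7, n_samples=200, noisy=True):
        centers = np.linspace(0.0, 6.0, n)
        windows = []
        for c in centers:
            base = rng.normal(c, 0.15, size=n_samples) if noisy else np.full(n_samples, c)
            windows.append(UmbrellaWindow(center=c, kappa=40.0, samples=base))
        return windows

    def test_zero_variance_windows_zero_band(self, rng):
        windows = self.make_windows(rng, noisy=False)
        prof = bootstrap_profile(windows, np.linspace(0, 6, 150), n_boot=100, seed=1)
        assert np.allclose(prof.band_hi - prof.band_lo, 0.0, atol=1e-12)

    def test_band_shrinks_with_sample_size(self, rng):
        widths = []
        for n_samples in (100, 400):
            windows = self.make_windows(rng, n_samples=n_samples)
            prof = bootstrap_profile(windows, np.linspace(0, 6, 100), n_boot=150, seed=2)
            widths.append(np.mean(prof.band_hi - prof.band_lo))
        # 4x samples should roughly halve the width
        assert widths[1] < 0.75 * widths[0]

    def test_seed_reproducible(self, rng):
        windows = self.make_windows(rng)
        grid = np.linspace(0, 6, 120)
        a = bootstrap_profile(windows, grid, n_boot=100, seed=5)
        b = bootstrap_profile(windows, grid, n_boot=100, seed=5)
        assert np.array_equal(a.band_lo, b.band_lo)
        assert np.array_equal(a.band_hi, b.band_hi)

    def test_band_covers_flat_truth(self, rng):
        """Flat free energy: the 95% band should cover zero almost everywhere."""
        centers = np.linspace(0.0, 6.0, 7)
        windows = [
            UmbrellaWindow(center=c, kappa=40.0, samples=rng.normal(c, 0.16, size=400))
            for c in centers
        ]
        grid = np.linspace(0, 6, 120)
        prof = bootstrap_profile(windows, grid, n_boot=200, seed=4)
        shifted_lo = prof.band_lo - prof.F  # center the band on the estimate
        shifted_hi = prof.band_hi - prof.F
        truth = -prof.F  # distance of flat truth (0) from the estimate
        coverage = np.mean((truth >= shifted_lo) & (truth <= shifted_hi))
        assert coverage >= 0.9

    def test_small_windows_rejected(self):
        w = UmbrellaWindow(center=0.0, kappa=1.0, samples=np.array([1.0]))
        with pytest.raises(ValueError):
            bootstrap_profile([w], np.linspace(0, 1, 100), n_boot=100, seed=0)


class TestTranslationCovariance:
    def test_profile_invariant_under_coordinate_shift(self, rng):
        centers = np.linspace(1.0, 15.0, 8)
        windows = [
            UmbrellaWindow(center=c, kappa=30.0, samples=rng.normal(c + 0.01, 0.18, 300))
            for c in centers
        ]
        grid = np.linspace(1.0, 15.0, 200)
        prof, _, _, _ = profile_from_windows(windows, grid)
        shift = 100.0
        windows_shifted = [
            UmbrellaWindow(center=w.center + shift, kappa=w.kappa, samples=w.samples + shift)
            for w in windows
        ]
        prof2, _, _, _ = profile_from_windows(windows_shifted, grid + shift)
        assert np.allclose(prof.F, prof2.F, atol=1e-8)
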