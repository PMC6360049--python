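import numpy as np
import pytest
import scipy.sparse as sp

from hkemidif.kernel import KernelMatrix, KernelParams, build_mr_kernel
from hkemidif.projector import Geometry, forward_project
from hkemidif.recon import (ReconSettings, SystemModel, em_update,
                            gaussian_postfilter, partition_subsets,
                            poisson_loglik, reconstruct)

IDENTITY_KERNEL_PARAMS = KernelParams(sigma_m=1e12, sigma_p=1e12,
                                      sigma_dm=1e-3, sigma_dp=1e-3)


@pytest.fixture(scope="module")
def toy_problem(small_phantom):
    """16x16 noiseless toy acquisition with attenuation and background."""
    from hkemidif.acquisition import simulate_frame
    from hkemidif.phantom import MuMap
    rng = np.random.default_rng(5)
    geom = Geometry(n_angles=24, grid_shape=(16, 16), voxel_size_mm=1.56)
    activity = np.zeros((16, 16))
    activity[4:12, 4:12] = rng.uniform(5, 20, size=(8, 8))
    mu = MuMap(np.where(activity > 0, 0.0096, 0.0), (1.56, 1.56))
    guidance = (activity > 0).astype(float) + 0.1
    ss = simulate_frame(activity, mu, geom, (0.0, 6.0), counts_scale=100.0,
                        seed=2)
    return geom, activity, mu, guidance, ss


class TestPartitionSubsets:
    def test_interleaved_example(self):
        subsets = partition_subsets(12, 3)
        assert [list(s) for s in subsets] == [[0, 3, 6, 9], [1, 4, 7, 10],
                                             [2, 5, 8, 11]]

    def test_single_subset_is_mlem(self):
        (all_angles,) = partition_subsets(7, 1)
        assert list(all_angles) == list(range(7))

    @pytest.mark.parametrize("n_angles,n_subsets", [(96, 21), (10, 3), (5, 5)])
    def test_partition_is_disjoint_and_covering(self, n_angles, n_subsets):
        subsets = partition_subsets(n_angles, n_subsets)
        flat = np.concatenate(subsets)
        assert len(flat) == n_angles
        assert set(flat) == set(range(n_angles))

    def test_too_many_subsets_rejected(self):
        with pytest.raises(ValueError):
            partition_subsets(8, 9)


class TestEmUpdate:
    def test_fixed_point_for_identity_system(self):
        P = sp.identity(4, format="csr")
        alpha = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = em_update(alpha, P, alpha.ravel(), np.zeros(4))
        assert np.allclose(out, alpha, atol=1e-12)

    def test_one_step_convergence_for_identity_system(self):
        P = sp.identity(2, format="csr")
        alpha = np.ones((1, 2))
        out = em_update(alpha, P, np.array([4.0, 2.0]), np.zeros(2))
        assert np.allclose(out, [[4.0, 2.0]], atol=1e-12)

    def test_matches_dense_matrix_oracle(self, rng):
        geom = Geometry(n_angles=8, grid_shape=(8, 8), voxel_size_mm=1.0)
        system = SystemModel(geom, None, n_subsets=2)
        P_s = system.P_sub[0]
        A = P_s.toarray()
        M = build_mr_kernel(rng.normal(size=(8, 8)), KernelParams()).normalised()
        Md = M.to_sparse().toarray()
        alpha = rng.uniform(0.5, 2.0, size=(8, 8))
        y = rng.uniform(0.0, 10.0, size=P_s.shape[0])
        s = rng.uniform(0.1, 1.0, size=P_s.shape[0])

        got = em_update(alpha, P_s, y, s, kernel=M, bp_ones=system.bp_ones[0])

        ybar = A @ (Md @ alpha.ravel()) + s
        num = Md.T @ (A.T @ (y / ybar))
        den = Md.T @ (A.T @ np.ones(len(y)))
        expected = np.where(den > 0, alpha.ravel() * num / den, 0.0)
        assert np.allclose(got.ravel(), expected, atol=1e-10)

    def test_negative_prompts_rejected(self):
        P = sp.identity(4, format="csr")
        with pytest.raises(ValueError):
            em_update(np.ones((2, 2)), P, np.array([1.0, -1.0, 0, 0]),
                      np.zeros(4))


class TestReconstruct:
    def test_hkem_with_identity_kernel_equals_osem(self, toy_problem):
        geom, _, mu, guidance, ss = toy_problem
        system = SystemModel(geom, mu.values, n_subsets=3)
        lam_osem = reconstruct(ss.prompts, ss.additive, system,
                               ReconSettings(algorithm="osem", n_subsets=3,
                                             n_iterations=4))
        lam_hkem = reconstruct(ss.prompts, ss.additive, system,
                               ReconSettings(algorithm="hkem", n_subsets=3,
                                             n_iterations=4,
                                             kernel_params=IDENTITY_KERNEL_PARAMS),
                               guidance_features=guidance)
        assert np.allclose(lam_hkem, lam_osem, atol=1e-8 * lam_osem.max())

    def test_kem_equals_hkem_without_pet_component_bitwise(self, toy_problem):
        geom, _, mu, guidance, ss = toy_problem
        system = SystemModel(geom, mu.values, n_subsets=3)
        kp = KernelParams(use_pet_component=False)
        lam_kem = reconstruct(ss.prompts, ss.additive, system,
                              ReconSettings(algorithm="kem", n_subsets=3,
                                            n_iterations=3, kernel_params=kp),
                              guidance_features=guidance)
        lam_hkem = reconstruct(ss.prompts, ss.additive, system,
                               ReconSettings(algorithm="hkem", n_subsets=3,
                                             n_iterations=3, kernel_params=kp),
                               guidance_features=guidance)
        assert np.array_equal(lam_kem, lam_hkem)

    def test_mlem_loglikelihood_nondecreasing_over_50_iterations(self):
        rng = np.random.default_rng(3)
        geom = Geometry(n_angles=24, grid_shape=(16, 16), voxel_size_mm=1.0)
        activity = np.zeros((16, 16))
        activity[4:12, 5:11] = rng.uniform(1, 4, size=(8, 6))
        y = rng.poisson(forward_project(activity, geom) * 5.0).astype(float)
        system = SystemModel(geom, None, n_subsets=1)
        P = system.P_sub[0]
        settings = ReconSettings(algorithm="osem", n_subsets=1, n_iterations=1)
        lam = None
        logliks = []
        current = np.full((16, 16), 1.0)
        for _ in range(50):
            current = em_update(current, P, y.ravel(), np.zeros(y.size),
                                bp_ones=system.bp_ones[0])
            logliks.append(poisson_loglik(current, P, y.ravel()))
        diffs = np.diff(logliks)
        assert np.all(diffs >= -1e-8 * np.abs(np.array(logliks[:-1])))

    @pytest.mark.parametrize("algo", ["osem", "osem-g", "kem", "hkem"])
    def test_iterates_nonnegative_for_noisy_data(self, toy_problem, algo):
        geom, _, mu, guidance, _ = toy_problem
        from hkemidif.acquisition import simulate_frame
        rng_act = np.random.default_rng(8)
        activity = np.zeros((16, 16))
        activity[4:12, 4:12] = rng_act.uniform(0.5, 5, size=(8, 8))
        ss = simulate_frame(activity, mu, geom, (0.0, 6.0), counts_scale=0.5,
                            seed=9)
        system = SystemModel(geom, mu.values, n_subsets=3)
        lam = reconstruct(ss.prompts, ss.additive, system,
                          ReconSettings(algorithm=algo, n_subsets=3,
                                        n_iterations=5),
                          guidance_features=guidance)
        assert np.all(lam >= 0)
        assert np.all(np.isfinite(lam))

    def test_reconstruction_is_bitwise_deterministic(self, toy_problem):
        geom, _, mu, guidance, ss = toy_problem
        system = SystemModel(geom, mu.values, n_subsets=3)
        settings = ReconSettings(algorithm="hkem", n_subsets=3, n_iterations=3)
        a = reconstruct(ss.prompts, ss.additive, system, settings,
                        guidance_features=guidance)
        b = reconstruct(ss.prompts, ss.additive, system, settings,
                        guidance_features=guidance)
        assert np.array_equal(a, b)

    def test_kernelised_methods_require_guidance(self, toy_problem):
        geom, _, mu, _, ss = toy_problem
        system = SystemModel(geom, mu.values, n_subsets=3)
        with pytest.raises(ValueError, match="guidance"):
            reconstruct(ss.prompts, ss.additive, system,
                        ReconSettings(algorithm="kem", n_subsets=3))

    def test_slab_reconstruction_matches_slicewise_2d(self, toy_problem):
        geom, _, mu, guidance, ss = toy_problem
        system = SystemModel(geom, mu.values, n_subsets=3)
        prompts = np.stack([ss.prompts, ss.prompts])
        additive = np.stack([ss.additive, ss.additive])
        lam3 = reconstruct(prompts, additive, system,
                           ReconSettings(algorithm="osem", n_subsets=3,
                                         n_iterations=3))
        lam2 = reconstruct(ss.prompts, ss.additive, system,
                           ReconSettings(algorithm="osem", n_subsets=3,
                                         n_iterations=3))
        assert np.allclose(lam3[0], lam2, atol=1e-12)


class TestGaussianPostfilter:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 3.7)
        assert np.allclose(gaussian_postfilter(img, 3.0, 1.56), img, atol=1e-12)

    def test_impulse_response_fwhm_is_three_mm(self):
        spacing = 1.56
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_postfilter(img, 3.0, spacing)
        profile = out[16]
        x = (np.arange(33) - 16) * spacing
        sigma_mm = np.sqrt((profile * x**2).sum() / profile.sum())
        fwhm = 2 * np.sqrt(2 * np.log(2)) * sigma_mm
        assert fwhm == pytest.approx(3.0, rel=0.02)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_postfilter(np.ones((4, 4)), 0.0, 1.0)
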