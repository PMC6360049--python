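"""Iterative reconstruction: OSEM, OSEM + Gaussian postfilter, KEM, HKEM.

All four algorithms share one ordered-subsets EM update on the kernel
coefficients alpha, with the activity image lambda = K alpha:

    alpha <- alpha / (K^T A_s^T 1) * K^T A_s^T ( y_s / (A_s K alpha + s_s) )

where A_s is the attenuated subset projector, y_s the subset prompts and
s_s the additive (randoms + scatter) term, never subtracted from the data.
OSEM is the identity-kernel special case; KEM fixes K to the anatomical
(MR-derived) kernel; HKEM multiplies it by a PET kernel recomputed from the
current iterate every subiteration. The update is multiplicative, so every
iterate stays nonnegative, and there is no hidden randomness: identical
inputs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .kernel import (KernelMatrix, KernelParams, build_mr_kernel,
                     build_pet_kernel, hybrid_kernel)
from .projector import Geometry, attenuation_factors

__all__ = ["ReconSettings", "SystemModel", "partition_subsets", "em_update",
           "reconstruct", "gaussian_postfilter", "poisson_loglik", "ALGORITHMS"]

ALGORITHMS = ("osem", "osem-g", "kem", "hkem")

#: floor applied to the forward-model denominator in the data ratio
RATIO_EPS = 1e-20


@dataclass(frozen=True)
class ReconSettings:
    """Algorithm selection and iteration schedule.

    21 subsets x 10 iterations with a 3 mm FWHM postfilter (OSEM+G only)
    are the clinical-routine defaults used throughout.
    """

    algorithm: str = "hkem"
    n_subsets: int = 21
    n_iterations: int = 10
    postfilter_fwhm_mm: float = 3.0
    kernel_params: KernelParams = field(default_factory=KernelParams)
    initial_value: float = 1.0
    pet_kernel_update: str = "subiteration"  # or "iteration"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.algorithm == "osem-g" and self.postfilter_fwhm_mm <= 0:
            raise ValueError("postfilter FWHM must be > 0")
        if self.initial_value <= 0:
            raise ValueError("initial image value must be positive")
        if self.pet_kernel_update not in ("subiteration", "iteration"):
            raise ValueError("pet_kernel_update must be 'subiteration' or 'iteration'")


def partition_subsets(n_angles: int, n_subsets: int) -> list[np.ndarray]:
    """Interleaved angle partition: subset s gets angles s, s+n_subsets, ..."""
    if not 1 <= n_subsets <= n_angles:
        raise ValueError(f"n_subsets must be in [1, {n_angles}], got {n_subsets}")
    return [np.arange(s, n_angles, n_subsets) for s in range(n_subsets)]


class SystemModel:
    """Attenuated subset projectors and their sensitivity backprojections.

    Folds the per-bin attenuation factors into the system-matrix rows once,
    so each EM subiteration costs two subset-sized sparse matvecs. Reused
    across frames and realisations (attenuation is frame-independent;
    normalisation is identically 1 in simulation).
    """

    def __init__(self, geom: Geometry, mu_map: np.ndarray | None = None,
                 n_subsets: int = 21):
        self.geom = geom
        self.n_subsets = n_subsets
        self.subset_angles = partition_subsets(geom.n_angles, n_subsets)
        att = (np.ones(geom.sino_shape) if mu_map is None
               else attenuation_factors(mu_map, geom))
        self.attenuation = att
        P = geom.matrix
        self.subset_rows: list[np.ndarray] = []
        self.P_sub: list[sp.csr_matrix] = []
        self.bp_ones: list[np.ndarray] = []
        for angles in self.subset_angles:
            rows = (angles[:, None] * geom.n_rad + np.arange(geom.n_rad)).ravel()
            P_s = sp.diags(att.ravel()[rows]) @ P[rows]
            self.subset_rows.append(rows)
            self.P_sub.append(P_s.tocsr())
            self.bp_ones.append(
                np.asarray(P_s.sum(axis=0)).ravel().reshape(geom.grid_shape)
            )


def em_update(
    alpha: np.ndarray,
    P_s: sp.spmatrix,
    y_s: np.ndarray,
    s_s: np.ndarray,
    kernel: KernelMatrix | None = None,
    bp_ones: np.ndarray | None = None,
) -> np.ndarray:
    """One (kernelised) EM subset update of the coefficient image.

    ``P_s`` is the attenuated subset projector on the flattened grid,
    ``y_s``/``s_s`` the matching prompts and additive term (flat),
    ``bp_ones`` an optional precomputed P_s^T 1. Voxels with zero
    sensitivity are pinned to 0 rather than divided by a floor.
    """
    if np.min(y_s) < 0:
        raise ValueError("prompts must be nonnegative")
    shape = alpha.shape
    lam = kernel.apply(alpha) if kernel is not None else alpha
    if lam.ndim == 2:
        ybar = P_s @ lam.ravel() + s_s
        ratio = y_s / np.maximum(ybar, RATIO_EPS)
        back = np.asarray(P_s.T @ ratio).reshape(shape)
    else:  # thin slab: the projector acts slice by slice
        nz = shape[0]
        ybar = (P_s @ lam.reshape(nz, -1).T).T + s_s
        ratio = np.asarray(y_s) / np.maximum(ybar, RATIO_EPS)
        back = np.asarray(P_s.T @ ratio.T).T.reshape(shape)
    if bp_ones is None:
        bp_ones = np.asarray(P_s.T @ np.ones(P_s.shape[0])).reshape(shape[-2:])
    if bp_ones.shape != shape:
        bp_ones = np.broadcast_to(bp_ones, shape)
    if kernel is not None:
        back = kernel.apply_transpose(back)
        sens = kernel.apply_transpose(np.ascontiguousarray(bp_ones))
    else:
        sens = bp_ones
    out = np.zeros(shape)
    np.divide(alpha * back, sens, out=out, where=sens > 0)
    return out


def _iterate_features(lam: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Standardised features of the current iterate.

    A constant iterate (e.g. the uniform initial image) carries no intensity
    information, so its features are all-zero and the PET kernel component
    degenerates to the pure distance factor.
    """
    vals = lam[mask] if mask is not None else lam
    std = vals.std()
    if std == 0:
        return np.zeros_like(lam)
    return (lam - vals.mean()) / std


def reconstruct(
    prompts: np.ndarray,
    additive: np.ndarray,
    system: SystemModel,
    settings: ReconSettings,
    guidance_features: np.ndarray | None = None,
    body_mask: np.ndarray | None = None,
    return_alpha: bool = False,
):
    """Reconstruct one frame's activity image from its sinogram data.

    ``guidance_features`` are the standardised anatomical-image features
    (mandatory for KEM/HKEM); ``body_mask`` is the mask the PET-iterate
    features are standardised over. The HKEM output is lambda = K alpha
    with the kernel used in the final subiteration.
    """
    geom = system.geom
    algo = settings.algorithm
    params = settings.kernel_params
    kernelised = algo in ("kem", "hkem")
    if kernelised and guidance_features is None:
        raise ValueError(f"{algo} requires a guidance image")
    use_pet = algo == "hkem" and params.use_pet_component

    km = None
    if kernelised:
        km = build_mr_kernel(np.asarray(guidance_features, dtype=float), params)
        if params.normalise_rows and not use_pet:
            km = km.normalised()

    slab = prompts.ndim == 3
    y = prompts.reshape(prompts.shape[0], -1) if slab else prompts.ravel()
    s = additive.reshape(additive.shape[0], -1) if slab else additive.ravel()
    grid = (prompts.shape[0], *geom.grid_shape) if slab else geom.grid_shape
    alpha = np.full(grid, float(settings.initial_value))
    kern: KernelMatrix | None = km

    def current_kernel(lam_for_features: np.ndarray) -> KernelMatrix:
        kp = build_pet_kernel(_iterate_features(lam_for_features, body_mask), params)
        k = hybrid_kernel(km, kp)
        return k.normalised() if params.normalise_rows else k

    if use_pet:
        kern = current_kernel(alpha)  # uniform init -> pure distance PET factor

    for it in range(settings.n_iterations):
        for s_idx in range(system.n_subsets):
            rows = system.subset_rows[s_idx]
            alpha = em_update(alpha, system.P_sub[s_idx], y[..., rows],
                              s[..., rows], kernel=kern,
                              bp_ones=system.bp_ones[s_idx])
            if use_pet and settings.pet_kernel_update == "subiteration":
                kern = current_kernel(kern.apply(alpha))
        if use_pet and settings.pet_kernel_update == "iteration":
            kern = current_kernel(kern.apply(alpha))

    lam = kern.apply(alpha) if kern is not None else alpha.copy()
    if algo == "osem-g":
        lam = gaussian_postfilter(lam, settings.postfilter_fwhm_mm,
                                  geom.voxel_size_mm)
    return (lam, alpha) if return_alpha else lam


def gaussian_postfilter(image: np.ndarray, fwhm_mm: float,
                        voxel_size_mm: float | tuple[float, ...]) -> np.ndarray:
    """Separable Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma_voxels = fwhm / (2 sqrt(2 ln 2) * spacing); reflective boundary,
    normalised kernel, so a constant image is unchanged.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be > 0")
    spacing = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (image.ndim,))
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)) * spacing)
    return gaussian_filter(np.asarray(image, dtype=float), sigma=sigma,
                           mode="reflect")


def poisson_loglik(lam: np.ndarray, P: sp.spmatrix, y: np.ndarray,
                   s: np.ndarray | float = 0.0) -> float:
    """Poisson log-likelihood (up to the data-only constant) of an image."""
    ybar = np.asarray(P @ lam.ravel()) + np.asarray(s)
    ybar = np.maximum(ybar, RATIO_EPS)
    return float(np.sum(y * np.log(ybar) - ybar))
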