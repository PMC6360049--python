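"""Voxel-wise hybrid kernel matrix for anatomically guided reconstruction.

The kernelised-EM image model writes the activity image as lambda = K alpha,
where K holds Gaussian similarity weights between each voxel j and the
voxels f of its cubic neighbourhood:

    k_fj = exp(-(v_f - v_j)^2 / (2 sigma_m^2)) * exp(-||x_f - x_j||^2 / (2 sigma_dm^2))

for the anatomical (MR-derived) component, and the same form with
(z^(n), sigma_p, sigma_dp) for the PET component computed from the current
iterate z^(n). The hybrid kernel is their element-wise product, rebuilt
every subiteration; with the PET component switched off the model reduces
to the purely MR-guided kernel (KEM).

Features are scalar per voxel (voxel-wise kernel) and are standardised to
zero mean / unit variance over a body mask so that sigma = 1 is meaningful
for arbitrary image scales. Distances are measured in voxel-index units.
The builder functions return the raw weights exactly as written above;
during reconstruction each voxel's weights are by default normalised to
sum to one (``normalise_rows``), which makes lambda_j a convex combination
of neighbouring coefficients and keeps the iterate-dependent hybrid kernel
stable from one subiteration to the next. The raw, unnormalised mode is
available for comparison.

Weights are stored as per-neighbourhood-offset dense planes and applied by
array shifts, which makes the per-subiteration rebuild cheap; ``to_sparse``
gives the equivalent scipy.sparse operator for cross-checks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["KernelParams", "KernelMatrix", "normalise_features",
           "build_mr_kernel", "build_pet_kernel", "hybrid_kernel"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelParams:
    """Scales of the intensity and distance Gaussians, and neighbourhood size.

    ``neighbourhood`` counts voxels in the cubic neighbourhood including the
    centre: 27 (3x3x3) in 3-D, mapped to 9 (3x3) on single-slice grids.
    ``axial_scale`` optionally stretches axial distances by the slice/pixel
    spacing ratio on anisotropic grids (1.0 = plain voxel-index units).
    """

    sigma_m: float = 1.0
    sigma_p: float = 1.0
    sigma_dm: float = 3.0
    sigma_dp: float = 3.0
    neighbourhood: int = 27
    use_pet_component: bool = True
    normalise_rows: bool = True
    axial_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_m", "sigma_p", "sigma_dm", "sigma_dp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.neighbourhood not in _RADIUS_FOR:
            raise ValueError(
                f"neighbourhood must be one of {sorted(_RADIUS_FOR)}, "
                f"got {self.neighbourhood}"
            )

    def radius(self, ndim: int) -> int:
        return _RADIUS_FOR[self.neighbourhood]


#: supported odd-cube neighbourhood sizes -> radius (9/27: 3-cubes, 125: 5-cube)
_RADIUS_FOR = {9: 1, 27: 1, 125: 2}


def _offsets(ndim: int, radius: int) -> tuple[tuple[int, ...], ...]:
    return tuple(itertools.product(range(-radius, radius + 1), repeat=ndim))


def _slice_pair(shape, offset):
    """(dst, src) index slices with src = dst + offset, both in bounds."""
    dst, src = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            dst.append(slice(0, n - d))
            src.append(slice(d, n))
        else:
            dst.append(slice(-d, n))
            src.append(slice(0, n + d))
    return tuple(dst), tuple(src)


def normalise_features(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Standardise an image to zero mean, unit variance over a body mask.

    The statistics come from the masked voxels but the affine transform is
    applied everywhere, so the result is invariant to affine rescaling of
    the input. A constant image has no defined scale and is rejected.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    vals = image[mask]
    std = vals.std()
    if std == 0:
        raise ValueError("constant image: feature standard deviation undefined")
    return (image - vals.mean()) / std


@dataclass(frozen=True)
class KernelMatrix:
    """Sparse neighbourhood weights k_fj stored per offset.

    ``weights[k]`` holds k_{(j + offsets[k]), j} on the grid of voxels j;
    entries whose neighbour falls outside the image are zero. The image
    model is applied as lambda_j = sum_f alpha_f k_fj.
    """

    offsets: tuple[tuple[int, ...], ...]
    weights: np.ndarray  # (n_offsets, *grid_shape)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.weights.shape[1:]

    @classmethod
    def identity(cls, grid_shape: tuple[int, ...]) -> "KernelMatrix":
        zero = (0,) * len(grid_shape)
        return cls((zero,), np.ones((1, *grid_shape)))

    def apply(self, alpha: np.ndarray) -> np.ndarray:
        """lambda_j = sum_f alpha_f k_fj."""
        if alpha.shape != self.grid_shape:
            raise ValueError(f"shape mismatch: {alpha.shape} vs {self.grid_shape}")
        out = np.zeros(self.grid_shape)
        for w, off in zip(self.weights, self.offsets):
            dst, src = _slice_pair(self.grid_shape, off)
            out[dst] += w[dst] * alpha[src]
        return out

    def apply_transpose(self, image: np.ndarray) -> np.ndarray:
        """(K^T y)_f = sum_j k_fj y_j — exact adjoint of :meth:`apply`."""
        if image.shape != self.grid_shape:
            raise ValueError(f"shape mismatch: {image.shape} vs {self.grid_shape}")
        out = np.zeros(self.grid_shape)
        for w, off in zip(self.weights, self.offsets):
            dst, src = _slice_pair(self.grid_shape, off)
            out[src] += w[dst] * image[dst]
        return out

    def multiply(self, other: "KernelMatrix") -> "KernelMatrix":
        """Element-wise (Hadamard) product — the hybrid combination."""
        if self.offsets != other.offsets or self.grid_shape != other.grid_shape:
            raise ValueError("kernel support patterns do not match")
        return KernelMatrix(self.offsets, self.weights * other.weights)

    def normalised(self) -> "KernelMatrix":
        """Optional row-normalised variant: sum_f k_fj = 1 for every j."""
        sums = self.weights.sum(axis=0)
        return KernelMatrix(self.offsets, self.weights / sums)

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    def to_sparse(self) -> sp.csr_matrix:
        """Equivalent (voxels x voxels) operator M with M[j, f] = k_fj."""
        n = int(np.prod(self.grid_shape))
        flat = np.arange(n).reshape(self.grid_shape)
        rows, cols, vals = [], [], []
        for w, off in zip(self.weights, self.offsets):
            dst, src = _slice_pair(self.grid_shape, off)
            rows.append(flat[dst].ravel())
            cols.append(flat[src].ravel())
            vals.append(w[dst].ravel())
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()


def _build(features: np.ndarray, sigma_i: float, sigma_d: float,
           params: KernelParams) -> KernelMatrix:
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    ndim = features.ndim
    if ndim == 2 and params.neighbourhood == 27:
        logger.info("2-D grid: neighbourhood 27 mapped to its in-plane 9-voxel cube")
    radius = params.radius(ndim)
    offsets = _offsets(ndim, radius)
    shape = features.shape
    weights = np.zeros((len(offsets), *shape))
    for k, off in enumerate(offsets):
        scaled = [params.axial_scale * d if (ndim == 3 and ax == 0) else d
                  for ax, d in enumerate(off)]
        dist_factor = np.exp(-sum(d * d for d in scaled) / (2 * sigma_d**2))
        dst, src = _slice_pair(shape, off)
        diff = features[src] - features[dst]
        weights[k][dst] = np.exp(-(diff**2) / (2 * sigma_i**2)) * dist_factor
    # normalise_rows is applied by the reconstruction driver to the combined
    # kernel (normalising the components separately would double-apply it)
    return KernelMatrix(offsets, weights)


def build_mr_kernel(guidance_features: np.ndarray, params: KernelParams) -> KernelMatrix:
    """Anatomical kernel component from standardised guidance-image features."""
    return _build(guidance_features, params.sigma_m, params.sigma_dm, params)


def build_pet_kernel(iterate_features: np.ndarray, params: KernelParams) -> KernelMatrix:
    """PET kernel component from the standardised current-iterate features z^(n)."""
    return _build(iterate_features, params.sigma_p, params.sigma_dp, params)


def hybrid_kernel(km: KernelMatrix, kp: KernelMatrix) -> KernelMatrix:
    """Hybrid kernel: element-wise product of MR and PET components."""
    return km.multiply(kp)
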