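"""Parallel-beam tomographic system model.

A desk-scale 2-D (or thin-slab, slice-by-slice) parallel-beam geometry
stands in for a clinical cylindrical scanner: the kernelised-EM update is
written for a generic system matrix p_ij, so the reconstruction algorithms
are geometry-agnostic and a small exact system model is preferable for
testing. Rays are sampled at half the voxel size with bilinear
interpolation; the whole operator is materialised as a scipy.sparse matrix,
so the back projector is the exact transpose of the forward projector —
a matched pair, which is load-bearing for EM monotonicity.

Conventions: voxel centres at (index + 0.5) * spacing from the grid corner,
projection angles evenly spaced in [0, pi), radial bin k centred at
(k - (n_rad - 1)/2) * radial spacing from the grid centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp

__all__ = ["Geometry", "forward_project", "back_project", "attenuation_factors",
           "system_matrix"]


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry for one transaxial slice."""

    n_angles: int
    grid_shape: tuple[int, int]
    voxel_size_mm: float
    n_rad: int | None = None
    rad_spacing_mm: float | None = None
    ray_step_fraction: float = 0.5  # ray sampling step, fraction of voxel size

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("need at least 2 projection angles")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.rad_spacing_mm is None:
            object.__setattr__(self, "rad_spacing_mm", self.voxel_size_mm)
        if self.n_rad is None:
            ny, nx = self.grid_shape
            diag = math.hypot(ny, nx) * self.voxel_size_mm
            n = int(math.ceil(diag / self.rad_spacing_mm)) + 1
            object.__setattr__(self, "n_rad", n + (n + 1) % 2)  # odd
        fov = self.n_rad * self.rad_spacing_mm
        diag = math.hypot(*self.grid_shape) * self.voxel_size_mm
        if fov < diag - 1e-9:
            raise ValueError("radial field of view must cover the image diagonal")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * math.pi / self.n_angles

    @property
    def sino_shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_rad)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @cached_property
    def matrix(self) -> sp.csr_matrix:
        """Sparse system matrix, rows angle-major (angle, radial bin)."""
        return system_matrix(self)


def system_matrix(geom: Geometry) -> sp.csr_matrix:
    """Materialise line integrals as a sparse matrix (bins x voxels).

    Each ray is sampled along its length at ``ray_step_fraction`` of the
    voxel size; each sample deposits bilinear interpolation weights times
    the step length (mm), so matrix-vector products are line integrals in
    units of image-value x mm.
    """
    ny, nx = geom.grid_shape
    spv = geom.voxel_size_mm
    step = geom.ray_step_fraction * spv
    half_len = math.hypot(ny, nx) * spv / 2
    n_samp = int(math.ceil(2 * half_len / step)) + 1
    t = (np.arange(n_samp) - (n_samp - 1) / 2) * step
    r = (np.arange(geom.n_rad) - (geom.n_rad - 1) / 2) * geom.rad_spacing_mm
    cy, cx = ny * spv / 2, nx * spv / 2

    rows, cols, vals = [], [], []
    for a, theta in enumerate(geom.angles):
        ux, uy = math.cos(theta), math.sin(theta)      # detector axis
        vx, vy = -math.sin(theta), math.cos(theta)     # ray direction
        # sample positions, shape (n_rad, n_samp)
        px = cx + r[:, None] * ux + t[None, :] * vx
        py = cy + r[:, None] * uy + t[None, :] * vy
        fx = px / spv - 0.5
        fy = py / spv - 0.5
        ix = np.floor(fx).astype(np.int64)
        iy = np.floor(fy).astype(np.int64)
        wx = fx - ix
        wy = fy - iy
        bin_idx = np.broadcast_to(
            (a * geom.n_rad + np.arange(geom.n_rad))[:, None], ix.shape
        )
        for dy, dx, w in (
            (0, 0, (1 - wy) * (1 - wx)),
            (0, 1, (1 - wy) * wx),
            (1, 0, wy * (1 - wx)),
            (1, 1, wy * wx),
        ):
            jy, jx = iy + dy, ix + dx
            ok = (jy >= 0) & (jy < ny) & (jx >= 0) & (jx < nx) & (w > 0)
            rows.append(bin_idx[ok])
            cols.append((jy * nx + jx)[ok])
            vals.append(w[ok] * step)

    m = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_angles * geom.n_rad, ny * nx),
    )
    return m.tocsr()


def _check_image(image: np.ndarray, geom: Geometry) -> None:
    if image.shape[-2:] != geom.grid_shape:
        raise ValueError(
            f"image grid {image.shape} does not match geometry {geom.grid_shape}"
        )


def forward_project(image: np.ndarray, geom: Geometry) -> np.ndarray:
    """Line-integral projection of an image (or slab, leading axis = slice)."""
    _check_image(image, geom)
    if image.ndim == 3:
        return np.stack([forward_project(sl, geom) for sl in image])
    y = geom.matrix @ image.ravel()
    return y.reshape(geom.sino_shape)


def back_project(sino: np.ndarray, geom: Geometry) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` (same kernel, transposed)."""
    if sino.shape[-2:] != geom.sino_shape:
        raise ValueError(
            f"sinogram shape {sino.shape} does not match geometry {geom.sino_shape}"
        )
    if sino.ndim == 3:
        return np.stack([back_project(sl, geom) for sl in sino])
    x = geom.matrix.T @ sino.ravel()
    return x.reshape(geom.grid_shape)


def attenuation_factors(mu: np.ndarray, geom: Geometry) -> np.ndarray:
    """Per-bin survival factors exp(-integral of mu), values in (0, 1].

    ``mu`` is the linear attenuation map in 1/mm on the image grid.
    """
    if np.min(mu) < 0:
        raise ValueError("attenuation coefficients must be >= 0")
    return np.exp(-forward_project(np.asarray(mu, dtype=float), geom))
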