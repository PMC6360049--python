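"""File I/O: NIfTI images and the HDF5 sinogram study container.

Images (label maps, guidance, attenuation, reconstructions, ROI masks) go
to NIfTI with the voxel spacing in the header; the simulated projection
data of a full study (per realisation, per frame: prompts / trues /
randoms / scatter) go to one HDF5 container with seeds and configuration
recorded as attributes. Both round-trip voxel data and spacing losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import SinogramSet, StudyRealisation

__all__ = ["write_image", "read_image", "write_study", "read_study"]


def _spacing_for(array: np.ndarray, voxel_size) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in np.atleast_1d(voxel_size))
    if len(spacing) == 1:
        spacing = spacing * array.ndim
    if len(spacing) != array.ndim:
        raise ValueError(f"spacing {spacing} does not match {array.ndim}-d image")
    return spacing


def write_image(path, array: np.ndarray, voxel_size) -> None:
    """Write a 2-D or 3-D voxel grid as NIfTI, spacing (mm) in the header.

    Axis order on disk is reversed relative to the in-memory (z, y, x)
    numpy convention so that the NIfTI fastest-varying axis is x.
    """
    array = np.asarray(array)
    spacing = _spacing_for(array, voxel_size)
    data = np.ascontiguousarray(array.T)
    affine = np.diag(list(spacing[::-1]) + [1.0] * (4 - array.ndim))
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms(spacing[::-1])
    nib.save(img, str(path))


def read_image(path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI image back to (array, voxel spacing), numpy axis order."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # malformed or truncated file
        raise OSError(f"cannot read NIfTI image {path}: {exc}") from None
    zooms = img.header.get_zooms()[: data.ndim]
    return data.T, tuple(float(z) for z in zooms[::-1])


def write_study(path, noiseless: list[SinogramSet],
                realisations: list[StudyRealisation],
                config: dict | None = None) -> None:
    """Write simulated projection data to an HDF5 study container.

    Layout: /noiseless/frame_k/{trues,randoms,scatter} and
    /realisation_r/frame_k/prompts (the noiseless components are shared
    across realisations, so they are stored once); per-frame seeds and the
    full configuration are attributes.
    """
    with h5py.File(path, "w") as fh:
        if config is not None:
            fh.attrs["config_json"] = json.dumps(config, sort_keys=True)
        g0 = fh.create_group("noiseless")
        for k, ss in enumerate(noiseless):
            g = g0.create_group(f"frame_{k:03d}")
            for name in ("trues", "randoms", "scatter"):
                g.create_dataset(name, data=getattr(ss, name))
            g.attrs["frame_start_s"] = ss.frame[0]
            g.attrs["frame_duration_s"] = ss.frame[1]
            g.attrs["counts_scale"] = ss.counts_scale
        for real in realisations:
            gr = fh.create_group(f"realisation_{real.index:02d}")
            gr.attrs["base_seed"] = real.seed
            for k, ss in enumerate(real.frames):
                g = gr.create_group(f"frame_{k:03d}")
                g.create_dataset("prompts", data=ss.prompts)
                g.attrs["seed"] = -1 if ss.seed is None else ss.seed


def read_study(path) -> tuple[list[SinogramSet], list[StudyRealisation], dict | None]:
    """Read a study container back; inverse of :func:`write_study`."""
    with h5py.File(path, "r") as fh:
        config = None
        if "config_json" in fh.attrs:
            config = json.loads(fh.attrs["config_json"])
        g0 = fh["noiseless"]
        frame_keys = sorted(g0.keys())
        noiseless = []
        for k, key in enumerate(frame_keys):
            g = g0[key]
            frame = (float(g.attrs["frame_start_s"]), float(g.attrs["frame_duration_s"]))
            trues = g["trues"][()]
            randoms = g["randoms"][()]
            scatter = g["scatter"][()]
            noiseless.append(SinogramSet(
                trues, randoms, scatter, trues + randoms + scatter,
                frame, float(g.attrs["counts_scale"]), None,
            ))
        realisations = []
        for key in sorted(k for k in fh.keys() if k.startswith("realisation_")):
            gr = fh[key]
            frames = []
            for k, fkey in enumerate(frame_keys):
                base = noiseless[k]
                seed = int(gr[fkey].attrs["seed"])
                frames.append(SinogramSet(
                    base.trues, base.randoms, base.scatter,
                    gr[fkey]["prompts"][()], base.frame, base.counts_scale,
                    None if seed < 0 else seed,
                ))
            realisations.append(StudyRealisation(
                int(key.split("_")[1]), int(gr.attrs["base_seed"]), tuple(frames)
            ))
    return noiseless, realisations, config
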