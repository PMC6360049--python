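"""Aorta ROI extraction and image-derived input function figures of merit.

The ROI is built by masking the reconstructed PET image with the anatomical
aorta segment and keeping only voxels at or above a fraction (default 75%)
of the masked maximum — discarding the rim voxels most affected by the
partial volume effect. One ROI is extracted per (algorithm, realisation)
from that reconstruction's peak-activity frame and then applied unchanged
to every frame. Per frame k the figures of merit are the ROI mean t_k, the
signed percent bias of t_k against the frame-averaged true blood activity
A_k^T, and the percent coefficient of variation (sample SD / mean) of the
ROI voxel values; study summaries pool |bias| and CoV over the
(frame x realisation) grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ROIMask", "IDIFCurve", "MetricsTable", "extract_roi", "roi_mean",
           "percent_bias", "percent_cov", "peak_frame_index", "compute_idif",
           "summarise_study", "summarise_peak_frame"]

DEFAULT_THRESHOLD_FRACTION = 0.75


@dataclass(frozen=True)
class ROIMask:
    """Binary ROI with its extraction provenance."""

    mask: np.ndarray
    threshold_fraction: float
    source_frame: int | None = None
    algorithm: str | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class IDIFCurve:
    """Per-frame ROI means (the IDIF) with frame midpoints in seconds."""

    times_s: np.ndarray
    values: np.ndarray
    algorithm: str | None = None
    realisation: int | None = None

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.values):
            raise ValueError("times and values must have equal length")


@dataclass(frozen=True)
class MetricsTable:
    """Mean/max/min of |bias| (%) and CoV (%) pooled over frames x realisations."""

    algorithm: str
    mean_bias: float
    max_bias: float
    min_bias: float
    mean_cov: float
    max_cov: float
    min_cov: float

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "mean_bias": self.mean_bias, "max_bias": self.max_bias,
            "min_bias": self.min_bias, "mean_cov": self.mean_cov,
            "max_cov": self.max_cov, "min_cov": self.min_cov,
        }


def extract_roi(segment_mask: np.ndarray, pet_image: np.ndarray,
                threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                source_frame: int | None = None,
                algorithm: str | None = None) -> ROIMask:
    """Threshold the segment-masked PET image at a fraction of its maximum.

    Inclusion uses >= (ties at exactly threshold * max are kept).
    """
    segment_mask = np.asarray(segment_mask, dtype=bool)
    if not segment_mask.any():
        raise ValueError("anatomical segment is empty")
    pet_image = np.asarray(pet_image, dtype=float)
    if not np.all(np.isfinite(pet_image)):
        raise ValueError("PET image must be finite")
    masked = np.where(segment_mask, pet_image, 0.0)
    peak = masked.max()
    if peak <= 0:
        raise ValueError(
            "segmented PET values are all <= 0; review the threshold or the "
            "reconstruction before ROI extraction"
        )
    roi = segment_mask & (masked >= threshold_fraction * peak)
    if not roi.any():
        raise ValueError("empty ROI after thresholding; review the threshold")
    return ROIMask(roi, threshold_fraction, source_frame, algorithm)


def roi_mean(roi: ROIMask, image: np.ndarray) -> float:
    """Arithmetic mean of the image over the ROI voxels (t_k)."""
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    return float(np.asarray(image)[roi.mask].mean())


def percent_bias(value: float, true_value: float) -> float:
    """Signed percent deviation 100 (t_k - A_k^T) / A_k^T."""
    if true_value <= 0:
        raise ValueError("true value must be positive")
    return 100.0 * (value - true_value) / true_value


def percent_cov(values: np.ndarray) -> float:
    """Percent coefficient of variation: 100 x sample SD / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CoV needs at least two voxels")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CoV undefined for non-positive mean")
    return 100.0 * values.std(ddof=1) / mean


def peak_frame_index(frames: np.ndarray, segment_mask: np.ndarray) -> int:
    """Frame with the highest mean over the anatomical segment.

    ``frames`` stacks per-frame images along the first axis.
    """
    segment_mask = np.asarray(segment_mask, dtype=bool)
    means = [float(f[segment_mask].mean()) for f in frames]
    return int(np.argmax(means))


def compute_idif(frames: np.ndarray, roi: ROIMask, true_values: np.ndarray,
                 times_s: np.ndarray | None = None,
                 algorithm: str | None = None,
                 realisation: int | None = None,
                 ) -> tuple[IDIFCurve, np.ndarray, np.ndarray]:
    """IDIF, per-frame signed bias (%) and per-frame CoV (%) for one ROI.

    The same ROI is applied to every frame; ``true_values`` holds the
    frame-averaged true blood activity A_k^T.
    """
    frames = np.asarray(frames, dtype=float)
    true_values = np.asarray(true_values, dtype=float)
    if len(frames) != len(true_values):
        raise ValueError("frame stack and truth curve lengths differ")
    means = np.array([roi_mean(roi, f) for f in frames])
    bias = np.array([percent_bias(m, t) for m, t in zip(means, true_values)])
    # CoV is undefined for a degenerate frame (all-zero ROI); record NaN
    cov = np.array([
        percent_cov(f[roi.mask]) if f[roi.mask].mean() > 0 else np.nan
        for f in frames
    ])
    if times_s is None:
        times_s = np.arange(len(frames), dtype=float)
    curve = IDIFCurve(np.asarray(times_s, dtype=float), means, algorithm, realisation)
    return curve, bias, cov


def summarise_study(bias: np.ndarray, cov: np.ndarray,
                    algorithm: str = "") -> MetricsTable:
    """Pool |bias| and CoV over the flat (realisation x frame) grid."""
    bias = np.atleast_2d(np.asarray(bias, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if bias.size == 0 or cov.size == 0:
        raise ValueError("nothing to summarise")
    ab = np.abs(bias).ravel()
    cv = cov.ravel()
    return MetricsTable(
        algorithm,
        float(ab.mean()), float(ab.max()), float(ab.min()),
        float(cv.mean()), float(cv.max()), float(cv.min()),
    )


def summarise_peak_frame(peak_means: np.ndarray, true_value: float) -> dict:
    """Peak-frame summary across realisations.

    ``peak_means`` holds each realisation's ROI mean at the (true-IDIF) peak
    frame; reported are the bias of the realisation-mean and the CoV of the
    realisation means.
    """
    peak_means = np.asarray(peak_means, dtype=float)
    if peak_means.size == 0:
        raise ValueError("no realisations")
    out = {"bias": percent_bias(float(peak_means.mean()), true_value)}
    out["cov"] = (percent_cov(peak_means) if peak_means.size >= 2 else 0.0)
    return out
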