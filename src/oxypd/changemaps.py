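"""Per-voxel pre-to-post change maps: BOLD percent signal change and ΔT2*.

The BOLD level of a session is summarized as the temporal mean of its repeat
series; percent change is 100·(post − pre)/pre per voxel after the post
session has been resampled onto the pre grid.  ΔT2* is the straight
difference of independently fitted T2* maps (ms).  Invalidity is contagious:
a change-map voxel is valid only where both sessions are valid and the
resampled voxel lies inside the post field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registration import AffineTransform, resample
from .relaxometry import INVALID, T2StarMap


@dataclass(frozen=True)
class BoldSeries:
    """Repeat series of a T2-weighted volume; ``repeats`` is (nx, ny, nz, n_repeats)."""

    repeats: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        reps = np.asarray(self.repeats, dtype=float)
        if reps.ndim != 4:
            raise ValueError("repeats must be 4D (x, y, z, repeat)")
        if reps.shape[3] < 2:
            raise ValueError("need at least 2 repeats")
        if not np.all(np.isfinite(reps)):
            raise ValueError("non-finite values in BOLD series")
        object.__setattr__(self, "repeats", reps)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def repeat_count(self) -> int:
        return self.repeats.shape[3]


@dataclass(frozen=True)
class ChangeMap:
    """Per-voxel pre→post change; ``kind`` is ``bold_percent`` (%) or ``delta_t2star`` (ms)."""

    values: np.ndarray
    valid: np.ndarray
    kind: str
    affine: np.ndarray

    def __post_init__(self):
        if self.kind not in ("bold_percent", "delta_t2star"):
            raise ValueError(f"unknown change-map kind {self.kind!r}")


def temporal_mean(series: BoldSeries) -> np.ndarray:
    """Arithmetic mean over repeats, per voxel."""
    return series.repeats.mean(axis=3)


def estimate_background_sigma(volume: np.ndarray, background: np.ndarray) -> float:
    """Noise scale from background (air) voxels of a magnitude image.

    Background magnitude is Rayleigh-distributed with mean sigma*sqrt(pi/2),
    so sigma is recovered from the background mean.
    """
    bg = np.asarray(volume)[np.asarray(background, bool)]
    if bg.size == 0:
        return 0.0
    return float(bg.mean() / np.sqrt(np.pi / 2))


def bold_percent_change(
    pre: BoldSeries,
    post: BoldSeries,
    transform: AffineTransform | None = None,
    signal_floor: float | None = None,
) -> ChangeMap:
    """Percent BOLD signal change per voxel, post relative to pre.

    The post series' temporal mean is resampled onto the pre grid through
    ``transform`` (identity if None).  Voxels whose pre-session mean falls
    below ``signal_floor`` are invalid — this keeps air voxels, where the
    denominator is pure noise, out of the statistics.  When no floor is
    given it defaults to 3x the Rayleigh-estimated background noise of the
    pre mean image (0 if that estimate is degenerate).
    """
    mean_pre = temporal_mean(pre)
    mean_post = temporal_mean(post)
    if transform is None:
        transform = AffineTransform.identity()
    mean_post_res, in_field = resample(
        mean_post, transform, post.affine, pre.affine, pre.repeats.shape[:3]
    )

    if signal_floor is None:
        # crude background = lowest-decile voxels of the pre mean
        thresh = np.quantile(mean_pre, 0.10)
        signal_floor = 3.0 * estimate_background_sigma(mean_pre, mean_pre <= thresh)

    valid = in_field & (mean_pre > signal_floor)
    values = np.full(mean_pre.shape, INVALID)
    np.divide(mean_post_res - mean_pre, mean_pre, out=values, where=valid)
    values[valid] *= 100.0
    values[~valid] = INVALID
    return ChangeMap(values, valid, "bold_percent", pre.affine)


def delta_t2star(
    pre_map: T2StarMap,
    post_map: T2StarMap,
    transform: AffineTransform | None = None,
) -> ChangeMap:
    """ΔT2* = post − pre (ms) per voxel, post resampled onto the pre grid.

    The post T2* map is interpolated only across its own valid voxels: a
    resampled voxel is valid when every voxel its trilinear stencil touches
    was validly fitted and in-field.
    """
    if transform is None:
        transform = AffineTransform.identity()
    post_filled = np.where(post_map.valid, post_map.t2star, 0.0)
    post_res, in_field = resample(
        post_filled, transform, post_map.affine, pre_map.affine, pre_map.shape
    )
    post_valid_res, _ = resample(
        post_map.valid.astype(float), transform, post_map.affine,
        pre_map.affine, pre_map.shape,
    )
    valid = pre_map.valid & in_field & (post_valid_res > 1.0 - 1e-6)
    values = np.full(pre_map.shape, INVALID)
    values[valid] = post_res[valid] - pre_map.t2star[valid]
    return ChangeMap(values, valid, "delta_t2star", pre_map.affine)
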