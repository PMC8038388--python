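"""Voxelwise T2* relaxometry from multi-echo gradient-echo magnitude data.

The effective transverse relaxation time T2* shortens with local
deoxyhemoglobin, so a longer T2* indicates better-oxygenated tissue.  It is
estimated per voxel by fitting the monoexponential decay

    S(TE) = S0 * exp(-TE / T2*)

to the magnitude signal sampled at multiple echo times TE, by
Levenberg-Marquardt nonlinear least squares initialized from a log-linear
(ordinary least squares on ln S vs TE) fit.  Fit failure at a voxel is data,
not an exception: such voxels are flagged invalid and excluded from every
downstream statistic.

No noise-floor offset term or magnitude-bias correction is applied by
default; plain unweighted least squares on the magnitude signal is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Upper bound on physically plausible T2* (ms); fits escaping (0, T2STAR_MAX]
#: (typically air or CSF voxels with runaway decays) are marked invalid.
T2STAR_MAX = 1000.0

#: Sentinel stored in invalid voxels of a T2* map.
INVALID = np.nan


@dataclass(frozen=True)
class EchoSeries:
    """Multi-echo magnitude volumes for one session.

    ``volumes`` has shape ``(nx, ny, nz, n_echoes)``; ``echo_times`` are the
    matching TEs in ms, strictly increasing; ``affine`` maps voxel indices to
    world mm (NIfTI convention).
    """

    volumes: np.ndarray
    echo_times: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        vols = np.asarray(self.volumes, dtype=float)
        tes = np.asarray(self.echo_times, dtype=float)
        if vols.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, echo)")
        if tes.ndim != 1 or tes.size < 2:
            raise ValueError("need at least 2 echo times")
        if np.any(np.diff(tes) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if vols.shape[3] != tes.size:
            raise ValueError("echo count mismatch between volumes and echo_times")
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "echo_times", tes)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]


@dataclass(frozen=True)
class T2StarMap:
    """Per-voxel fit results for one session.

    ``t2star`` (ms), ``s0`` (signal units) and ``rmse`` (residual RMS) hold
    :data:`INVALID` where ``valid`` is False.
    """

    t2star: np.ndarray
    s0: np.ndarray
    rmse: np.ndarray
    valid: np.ndarray
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2star.shape


def loglinear_init(signal: np.ndarray, echo_times: np.ndarray,
                   t2star_max: float = T2STAR_MAX) -> tuple[float, float] | None:
    """Log-linear initialization: OLS of ln(signal) on TE.

    Non-positive samples are excluded from the log fit.  Returns
    ``(s0_init, t2star_init)`` with t2star_init clamped into
    ``(0, t2star_max]``, or ``None`` when fewer than 2 positive samples
    remain or the decay is non-decreasing (slope >= 0).
    """
    signal = np.asarray(signal, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    pos = signal > 0
    if pos.sum() < 2:
        return None
    te, s = echo_times[pos], signal[pos]
    slope, intercept = np.polyfit(te, np.log(s), 1)
    if slope >= 0:
        # non-decaying signal: start from the longest admissible T2*
        return float(np.exp(intercept)), t2star_max
    t2 = -1.0 / slope
    return float(np.exp(intercept)), float(min(t2, t2star_max))


def fit_voxel(signal: np.ndarray, echo_times: np.ndarray,
              t2star_max: float = T2STAR_MAX) -> tuple[float, float, float, bool]:
    """Fit one voxel's decay; returns ``(s0, t2star, rmse, valid)``.

    Minimizes ``sum_e (signal_e - s0 exp(-TE_e / t2star))^2`` by
    Levenberg-Marquardt from the log-linear start.  ``valid`` is False (with
    NaN estimates) when no initialization exists, the solver fails, or the
    solution leaves ``(0, t2star_max]``.
    """
    signal = np.asarray(signal, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    if signal.shape != echo_times.shape:
        raise ValueError("signal and echo_times lengths differ")
    if echo_times.size < 2 or np.any(np.diff(echo_times) <= 0):
        raise ValueError("echo_times must be strictly increasing with length >= 2")

    init = loglinear_init(signal, echo_times, t2star_max)
    if init is None:
        return INVALID, INVALID, INVALID, False
    s0_0, t2_0 = init

    def _decay(p):
        # clamp the exponent: LM may probe negative T2* transiently
        return np.exp(np.clip(-echo_times / p[1], -700.0, 700.0))

    def residuals(p):
        return p[0] * _decay(p) - signal

    def jac(p):
        e = _decay(p)
        return np.column_stack([e, p[0] * e * echo_times / p[1] ** 2])

    try:
        sol = least_squares(residuals, x0=[s0_0, t2_0], jac=jac, method="lm",
                            xtol=1e-12, ftol=1e-10, max_nfev=200)
    except Exception:
        return INVALID, INVALID, INVALID, False
    s0, t2 = sol.x
    if not sol.success or not np.isfinite(t2) or t2 <= 0 or t2 > t2star_max or s0 <= 0:
        return INVALID, INVALID, INVALID, False
    rmse = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
    return float(s0), float(t2), rmse, True


def fit_volume(series: EchoSeries, mask: np.ndarray | None = None,
               t2star_max: float = T2STAR_MAX) -> T2StarMap:
    """Fit every voxel (inside ``mask`` if given) of a multi-echo series.

    Voxels outside the mask, and voxels whose fit fails, are invalid in the
    returned map.  The fraction of valid voxels among those attempted is
    logged.
    """
    shape = series.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {shape}")

    t2star = np.full(shape, INVALID)
    s0 = np.full(shape, INVALID)
    rmse = np.full(shape, INVALID)
    valid = np.zeros(shape, dtype=bool)

    idx = np.argwhere(mask)
    for i, j, k in idx:
        s0v, t2v, rv, ok = fit_voxel(series.volumes[i, j, k], series.echo_times,
                                     t2star_max)
        if ok:
            t2star[i, j, k], s0[i, j, k], rmse[i, j, k] = t2v, s0v, rv
            valid[i, j, k] = True

    n_attempted = len(idx)
    if n_attempted == 0:
        logger.warning("fit_volume: mask selects zero voxels; empty map returned")
    else:
        frac = valid.sum() / n_attempted
        logger.info("fit_volume: %d/%d voxels valid (%.1f%%)",
                    valid.sum(), n_attempted, 100 * frac)
    return T2StarMap(t2star, s0, rmse, valid, series.affine)
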