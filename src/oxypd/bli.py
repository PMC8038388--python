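"""Dynamic bioluminescence reporter quantification.

An oxygen-degradable luciferase reporter (HIF1α ODD fused to firefly
luciferase) emits in proportion to tissue hypoxia: photon flux falls when the
tumor reoxygenates.  After a luciferin injection the flux rises and decays
over tens of minutes, so each session is sampled every 2 min for 25 min and
summarized by its peak.  This module extracts peaks, normalizes them to each
animal's own baseline session and to caliper-derived tumor volume, computes
fold changes, and runs the paired/unpaired Student's t-tests used for group
comparisons.

Dispersion is reported both as SD and as SEM (SD/sqrt(n)); significance
marks follow the convention * p<=0.05, ** p<=0.01, *** p<=0.001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class DegenerateTestError(ValueError):
    """The t statistic is undefined (zero variance with a nonzero effect)."""


@dataclass(frozen=True)
class FluxTimecourse:
    """Ordered (time, photon flux/s) readings for one animal and session."""

    animal_id: str
    session: str
    times_min: np.ndarray
    flux: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        f = np.asarray(self.flux, dtype=float)
        if t.size == 0:
            raise ValueError("timecourse must contain at least one timepoint")
        if t.shape != f.shape:
            raise ValueError("times and flux lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("photon flux cannot be negative")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "flux", f)


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper length/width (mm) with the derived modified-ellipsoid volume."""

    length_mm: float
    width_mm: float

    def __post_init__(self):
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("caliper measurements must be positive")
        if self.width_mm > self.length_mm:
            warnings.warn("width exceeds length; swapping (longer axis is length)")
            l, w = self.width_mm, self.length_mm
            object.__setattr__(self, "length_mm", l)
            object.__setattr__(self, "width_mm", w)

    @property
    def volume_mm3(self) -> float:
        return ellipsoid_volume(self.length_mm, self.width_mm)


@dataclass(frozen=True)
class GroupResult:
    """Outcome of a group comparison with both dispersion conventions."""

    labels: tuple[str, str]
    values_a: np.ndarray
    values_b: np.ndarray
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    significance_mark: str
    test: str


def significance_mark(p: float) -> str:
    """Star convention: * p<=0.05, ** p<=0.01, *** p<=0.001, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def peak_flux(tc: FluxTimecourse) -> tuple[float, float]:
    """Sample maximum of the flux and its earliest attaining time (no smoothing)."""
    i = int(np.argmax(tc.flux))  # argmax returns the first maximum: earliest time
    return float(tc.flux[i]), float(tc.times_min[i])


def normalize_to_baseline(
    peaks: dict[str, tuple[float, float]],
) -> tuple[dict[str, float], dict]:
    """Per-animal treated/baseline peak ratios plus group mean, SD and SEM.

    ``peaks`` maps animal_id -> (baseline peak, treatment peak).  Animals with
    a non-positive baseline cannot be normalized; they are excluded with a
    log entry and listed in the returned stats under ``excluded``.
    """
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    for animal, (base, treat) in peaks.items():
        if base <= 0:
            logger.warning("animal %s: baseline peak %.3g is not positive; "
                           "excluded from normalization", animal, base)
            excluded.append(animal)
            continue
        ratios[animal] = treat / base
    vals = np.array(list(ratios.values()))
    stats_out = {
        "n": int(vals.size),
        "mean": float(vals.mean()) if vals.size else float("nan"),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        "excluded": excluded,
    }
    stats_out["sem"] = (stats_out["sd"] / np.sqrt(vals.size)
                        if vals.size > 1 else float("nan"))
    return ratios, stats_out


def ellipsoid_volume(length_mm: float, width_mm: float) -> float:
    """Modified-ellipsoid tumor volume: length * width^2 / 2 (mm^3).

    The longer caliper axis is the length; swapped inputs are corrected with
    a warning rather than rejected.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper measurements must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; swapping (longer axis is length)")
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 / 2.0


def flux_per_volume(peak_flux_per_s: float, volume_mm3: float) -> float:
    """Photon flux per second per mm^3 of tumor."""
    if volume_mm3 <= 0:
        raise ValueError("tumor volume must be positive")
    return peak_flux_per_s / volume_mm3


def fold_change(treated: float, reference: float) -> float:
    """Ratio of a treated summary value to its reference (reference > 0)."""
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return treated / reference


def _summaries(a: np.ndarray, b: np.ndarray) -> dict:
    def sd(x):
        return float(x.std(ddof=1)) if x.size > 1 else float("nan")
    return dict(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=sd(a), sd_b=sd(b),
        sem_a=sd(a) / np.sqrt(a.size), sem_b=sd(b) / np.sqrt(b.size),
    )


def paired_test(before: np.ndarray, after: np.ndarray,
                labels: tuple[str, str] = ("baseline", "treatment")) -> GroupResult:
    """Two-sided paired Student's t-test on per-animal differences.

    ``before == after`` elementwise is the exact null: t = 0, p = 1.
    Constant nonzero differences leave the t statistic undefined and raise
    :class:`DegenerateTestError`.
    """
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = b - a
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            t, p = 0.0, 1.0
        else:
            raise DegenerateTestError(
                "constant nonzero paired differences: zero variance")
    else:
        t, p = stats.ttest_rel(b, a)
    return GroupResult(labels=labels, values_a=a, values_b=b,
                       t_statistic=float(t), p_value=float(p),
                       significance_mark=significance_mark(float(p)),
                       test="paired t", **_summaries(a, b))


def unpaired_test(group_a: np.ndarray, group_b: np.ndarray,
                  labels: tuple[str, str] = ("group_a", "group_b"),
                  welch: bool = False) -> GroupResult:
    """Two-sided two-sample Student's t-test (equal variance; Welch by flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            t, p = 0.0, 1.0
        else:
            raise DegenerateTestError(
                "both groups constant with different means: zero variance")
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupResult(labels=labels, values_a=a, values_b=b,
                       t_statistic=float(t), p_value=float(p),
                       significance_mark=significance_mark(float(p)),
                       test="welch t" if welch else "student t",
                       **_summaries(a, b))
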