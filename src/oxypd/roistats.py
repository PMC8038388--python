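"""ROI-restricted summaries of change maps.

For each tumor the clinically reported quantities are the median change over
the ROI and the fractional tumor volume whose change exceeds a ladder of
thresholds (strictly greater than: 1, 2, 5, 10 % for BOLD, 1, 2, 5, 10 ms
for T2* by default).  Fractions are taken over *valid* ROI voxels, and the
valid fraction is reported alongside so that masking cannot silently shrink
the denominator.  A cohort of per-patient summaries is ordered into a
waterfall report with a configurable responder rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .changemaps import ChangeMap
from .relaxometry import T2StarMap

#: Threshold ladders reported per tumor (strict ">"), in map units.
DEFAULT_T2STAR_THRESHOLDS_MS = (1.0, 2.0, 5.0, 10.0)
DEFAULT_BOLD_THRESHOLDS_PCT = (1.0, 2.0, 5.0, 10.0)


class EmptyRoiError(ValueError):
    """No valid voxels available inside the ROI."""


@dataclass(frozen=True)
class RoiMask:
    mask: np.ndarray
    affine: np.ndarray
    label: str = "tumor"

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class FractionalVolumeSummary:
    patient_id: str
    dose_mg_per_kg: float
    kind: str
    median_change: float
    fractions: dict[float, float]
    n_valid_voxels: int
    n_roi_voxels: int

    @property
    def valid_fraction(self) -> float:
        return self.n_valid_voxels / self.n_roi_voxels


def _valid_roi_values(change: ChangeMap, roi: RoiMask) -> np.ndarray:
    if roi.mask.shape != change.values.shape:
        raise ValueError("ROI geometry does not match change map")
    sel = roi.mask & change.valid
    return change.values[sel]


def roi_median(change: ChangeMap, roi: RoiMask) -> float:
    """Median change over valid ROI voxels (even count: mean of central pair)."""
    vals = _valid_roi_values(change, roi)
    if vals.size == 0:
        raise EmptyRoiError(f"ROI {roi.label!r} contains no valid voxels")
    return float(np.median(vals))


def fractional_volumes(
    change: ChangeMap,
    roi: RoiMask,
    thresholds: tuple[float, ...] | None = None,
    patient_id: str = "",
    dose_mg_per_kg: float = float("nan"),
) -> FractionalVolumeSummary:
    """Fraction of valid ROI voxels with change strictly greater than each threshold.

    ``thresholds`` must be strictly increasing; defaults to the standard
    ladder for the map's kind.  Fractions are non-increasing in threshold by
    construction; this is asserted on every call.
    """
    if thresholds is None:
        thresholds = (DEFAULT_BOLD_THRESHOLDS_PCT if change.kind == "bold_percent"
                      else DEFAULT_T2STAR_THRESHOLDS_MS)
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) == 0:
        raise ValueError("threshold list is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    vals = _valid_roi_values(change, roi)
    if vals.size == 0:
        raise EmptyRoiError(f"ROI {roi.label!r} contains no valid voxels")
    fractions = {t: float(np.count_nonzero(vals > t)) / vals.size for t in thresholds}
    fr = list(fractions.values())
    assert all(a >= b for a, b in zip(fr, fr[1:])), "fractions not monotone in threshold"
    return FractionalVolumeSummary(
        patient_id=patient_id,
        dose_mg_per_kg=dose_mg_per_kg,
        kind=change.kind,
        median_change=float(np.median(vals)),
        fractions=fractions,
        n_valid_voxels=int(vals.size),
        n_roi_voxels=int(roi.mask.sum()),
    )


def pre_post_histogram(
    pre_map: T2StarMap,
    post_map: T2StarMap,
    roi: RoiMask,
    bin_width_ms: float = 2.0,
) -> pd.DataFrame:
    """Paired pre/post T2* histograms over valid ROI voxels on a shared bin grid.

    Both maps must already live on the ROI geometry.  Returns a DataFrame
    with columns ``bin_left``, ``bin_right``, ``count_pre``, ``count_post``;
    counts sum to each session's valid ROI voxel total.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    pre_vals = pre_map.t2star[roi.mask & pre_map.valid]
    post_vals = post_map.t2star[roi.mask & post_map.valid]
    if pre_vals.size == 0 and post_vals.size == 0:
        raise EmptyRoiError("no valid voxels in ROI for either session")
    allv = np.concatenate([pre_vals, post_vals])
    lo = np.floor(allv.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil(allv.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    count_pre, _ = np.histogram(pre_vals, bins=edges)
    count_post, _ = np.histogram(post_vals, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count_pre": count_pre,
        "count_post": count_post,
    })


def waterfall_summary(
    summaries: list[FractionalVolumeSummary],
    anchor_threshold: float = 5.0,
    responder_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Cohort waterfall: patients sorted by fraction at the anchor threshold.

    Each row carries the patient's dose, median change, the fraction at every
    threshold, and a ``responder`` flag (fraction at anchor >= cutoff — a
    reporting convention, not a clinically validated rule).  Sorting is by
    descending anchor fraction; ties break on patient_id so the order is
    stable across runs.
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    for s in summaries:
        if anchor_threshold not in s.fractions:
            raise ValueError(
                f"anchor threshold {anchor_threshold} missing for patient {s.patient_id!r}")
    rows = []
    for s in summaries:
        row = {
            "patient_id": s.patient_id,
            "dose_mg_per_kg": s.dose_mg_per_kg,
            "kind": s.kind,
            "median_change": s.median_change,
            "n_valid_voxels": s.n_valid_voxels,
            "valid_fraction": s.valid_fraction,
        }
        for t, f in sorted(s.fractions.items()):
            row[f"frac_gt_{t:g}"] = f
        row["anchor_fraction"] = s.fractions[anchor_threshold]
        row["responder"] = s.fractions[anchor_threshold] >= responder_cutoff
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["anchor_fraction", "patient_id"],
                        ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)
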