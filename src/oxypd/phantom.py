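"""Synthetic ground-truth phantoms for the oxygenation pipeline.

No raw imaging data ships with the study this pipeline targets, so every
stage is exercised against digital phantoms with known truth: a tissue
object with spatially varying S0 and T2*, a tumor ROI in which a known
post-dose T2* increment and fractional BOLD change are imposed on a
sub-region (mimicking heterogeneous reoxygenation), monoexponential echo
decay sampled at the acquisition's echo times, Rician noise on every
magnitude sample, and a known rigid misalignment applied to the post-dose
session.  A parallel generator produces rise-then-decay luciferin flux
timecourses for bioluminescence cohorts.

Magnitude MRI noise is Rician: the magnitude of a complex signal whose real
and imaginary channels carry independent Gaussian noise of scale sigma.  In
background (zero signal) this reduces to a Rayleigh distribution with mean
sigma*sqrt(pi/2); at high SNR it approaches Gaussian with mean
sqrt(signal^2 + sigma^2).  A plain Gaussian option is kept for analytic
tests.

All generators are deterministic: a fixed spec (including its seed) yields
bit-identical output on every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changemaps import BoldSeries
from .registration import AffineTransform, resample
from .relaxometry import EchoSeries

#: Echo times of the multi-echo gradient-echo acquisition (ms): 8 echoes, 5-75.
DEFAULT_ECHO_TIMES_MS = tuple(np.linspace(5.0, 75.0, 8))

#: BOLD repeat count per session.
DEFAULT_N_REPEATS = 60

#: Echo time of the T2-weighted BOLD sequence (ms), used to synthesize the
#: per-voxel baseline BOLD level from the tissue's S0 and T2*.
BOLD_TE_MS = 35.0


def rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Apply Rician noise of scale ``sigma`` to noiseless magnitudes."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return np.asarray(noiseless, dtype=float).copy()
    re = noiseless + rng.normal(0.0, sigma, size=np.shape(noiseless))
    im = rng.normal(0.0, sigma, size=np.shape(noiseless))
    return np.hypot(re, im)


def gaussian(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian alternative for analytic tests."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    return noiseless + rng.normal(0.0, sigma, size=np.shape(noiseless))


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic patient (pre and post session).

    Spatial fields are voxel grids of ``grid_shape``; ``voxel_size`` is mm
    per axis.  The post-dose session has effective
    T2* = ``t2star_field + delta_t2star_field`` and BOLD level scaled by
    ``1 + bold_change_field``, and is acquired through ``misalignment``
    (a world-mm transform; its inverse is what registration should recover).
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    s0_field: np.ndarray
    t2star_field: np.ndarray
    roi_mask: np.ndarray
    delta_t2star_field: np.ndarray
    bold_change_field: np.ndarray
    noise_sigma: float = 0.0
    misalignment: AffineTransform = field(default_factory=AffineTransform.identity)
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES_MS
    n_repeats: int = DEFAULT_N_REPEATS
    seed: int = 0
    noise_model: str = "rician"

    def __post_init__(self):
        for name in ("s0_field", "t2star_field", "roi_mask",
                     "delta_t2star_field", "bold_change_field"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != tuple(self.grid_shape):
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid_shape}")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "roi_mask", self.roi_mask.astype(bool))
        tes = np.asarray(self.echo_times, dtype=float)
        if tes.size < 2 or np.any(np.diff(tes) <= 0):
            raise ValueError("echo_times must be strictly increasing with length >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        roi = self.roi_mask
        if roi.any() and (np.any(self.t2star_field[roi] <= 0)
                          or np.any(self.s0_field[roi] <= 0)):
            raise ValueError("ROI voxels must have positive S0 and T2*")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size
        return a

    @property
    def object_mask(self) -> np.ndarray:
        return self.s0_field > 0

    def effective_t2star(self, session: str) -> np.ndarray:
        _check_session(session)
        if session == "post":
            return self.t2star_field + self.delta_t2star_field
        return self.t2star_field

    def bold_level(self, session: str) -> np.ndarray:
        """Noiseless per-voxel BOLD signal level for a session.

        The post level is exactly ``baseline * (1 + bold_change_field)``:
        the imposed fractional change is the whole truth, with no implicit
        coupling to the T2* increment, so percent-change recovery has an
        exact target.
        """
        _check_session(session)
        level = np.zeros(self.grid_shape)
        obj = self.object_mask & (self.t2star_field > 0)
        level[obj] = self.s0_field[obj] * np.exp(-BOLD_TE_MS / self.t2star_field[obj])
        if session == "post":
            level = level * (1.0 + self.bold_change_field)
        return level

    def ground_truth(self) -> dict:
        """JSON-serializable sidecar of everything the pipeline should recover."""
        roi = self.roi_mask
        return {
            "seed": self.seed,
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": list(self.voxel_size),
            "echo_times_ms": [float(t) for t in self.echo_times],
            "n_repeats": self.n_repeats,
            "noise_sigma": self.noise_sigma,
            "noise_model": self.noise_model,
            "misalignment": self.misalignment.to_dict(),
            "registration_truth": self.misalignment.inverse().to_dict(),
            "roi_n_voxels": int(roi.sum()),
            "roi_median_t2star_ms": float(np.median(self.t2star_field[roi])) if roi.any() else None,
            "roi_median_delta_t2star_ms": float(np.median(self.delta_t2star_field[roi])) if roi.any() else None,
            "roi_median_bold_change": float(np.median(self.bold_change_field[roi])) if roi.any() else None,
        }


def _check_session(session: str) -> None:
    if session not in ("pre", "post"):
        raise ValueError(f"session must be 'pre' or 'post', got {session!r}")


def _noise(spec: PhantomSpec, noiseless: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    fn = rician if spec.noise_model == "rician" else gaussian
    return fn(noiseless, spec.noise_sigma, rng)


def _rng(spec_seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, *stream]))


def make_echo_series(spec: PhantomSpec, session: str) -> EchoSeries:
    """Simulate the multi-echo magnitude acquisition of one session.

    The noiseless voxel signal at echo e is ``S0 * exp(-TE_e / T2*)`` (zero
    in background); the post session is resampled through the spec's
    misalignment before noise, and noise of scale ``noise_sigma`` is applied
    to every magnitude sample — so background voxels contain pure noise.
    """
    _check_session(session)
    tes = np.asarray(spec.echo_times, dtype=float)
    t2 = spec.effective_t2star(session)
    obj = spec.object_mask & (t2 > 0)
    vols = np.zeros(spec.grid_shape + (tes.size,))
    with np.errstate(divide="ignore"):
        for e, te in enumerate(tes):
            v = np.zeros(spec.grid_shape)
            v[obj] = spec.s0_field[obj] * np.exp(-te / t2[obj])
            if session == "post":
                v, _ = resample(v, spec.misalignment, spec.affine)
            vols[..., e] = v
    rng = _rng(spec.seed, 0 if session == "pre" else 1)
    vols = _noise(spec, vols, rng)
    return EchoSeries(vols, tes, spec.affine)


def make_bold_series(spec: PhantomSpec, session: str) -> BoldSeries:
    """Simulate one session's BOLD repeat series.

    Each repeat is the session's noiseless BOLD level plus independent noise;
    the temporal mean therefore converges on the baseline level (pre) or
    baseline*(1 + bold_change_field) (post).  The post session is misaligned
    like the echo data.
    """
    _check_session(session)
    if spec.n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    level = spec.bold_level(session)
    if session == "post":
        level, _ = resample(level, spec.misalignment, spec.affine)
    reps = np.repeat(level[..., None], spec.n_repeats, axis=3)
    rng = _rng(spec.seed, 2 if session == "pre" else 3)
    reps = _noise(spec, reps, rng)
    return BoldSeries(reps, spec.affine)


def default_phantom(
    seed: int = 0,
    noise_sigma: float = 0.0,
    delta_t2star_ms: float = 6.0,
    bold_change: float = 0.05,
    misalignment: AffineTransform | None = None,
    t2star_ms: float = 35.0,
    s0: float = 1000.0,
    grid_shape: tuple[int, int, int] = (32, 32, 12),
    voxel_size: tuple[float, float, float] = (1.6, 1.6, 4.0),
) -> PhantomSpec:
    """Standard study phantom: ellipsoidal tissue with an embedded tumor ROI.

    The ROI is an ellipsoid in the object's center; the post-dose change
    (ΔT2* and fractional BOLD change) is imposed on exactly the half of the
    ROI with voxel x-index above the ROI's median x — a crisp sub-region so
    fractional-volume recovery has an exact truth (half the ROI changed).
    """
    shape = tuple(grid_shape)
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape) - 1) / 2.0
    body_radii = np.array([shape[0] * 0.40, shape[1] * 0.40, shape[2] * 0.38])
    roi_radii = body_radii * 0.55

    def ellipsoid(radii):
        d = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        return d <= 1.0

    body = ellipsoid(body_radii)
    roi = ellipsoid(roi_radii)

    s0_field = np.where(body, s0, 0.0)
    t2star_field = np.where(body, t2star_ms, 0.0)

    # changed sub-region: upper half of ROI in x (exactly half by voxel count)
    changed = np.zeros(shape, dtype=bool)
    roi_idx = np.argwhere(roi)
    order = np.lexsort((roi_idx[:, 2], roi_idx[:, 1], roi_idx[:, 0]))
    half = roi_idx[order][len(roi_idx) // 2:]
    changed[tuple(half.T)] = True

    delta = np.where(changed, delta_t2star_ms, 0.0)
    bchange = np.where(changed, bold_change, 0.0)

    return PhantomSpec(
        grid_shape=shape,
        voxel_size=tuple(voxel_size),
        s0_field=s0_field,
        t2star_field=t2star_field,
        roi_mask=roi,
        delta_t2star_field=delta,
        bold_change_field=bchange,
        noise_sigma=noise_sigma,
        misalignment=misalignment or AffineTransform.identity(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bioluminescence flux phantoms


@dataclass(frozen=True)
class FluxPhantomSpec:
    """Cohort of paired baseline/treatment luciferin flux timecourses.

    The kinetic shape is a gamma-variate rise-then-decay
    ``f(t) = peak * (t/tp)^shape * exp(shape * (1 - t/tp))`` peaking at
    ``time_to_peak_min``; readings carry i.i.d. multiplicative lognormal
    noise with coefficient of variation ``noise_cv``.  The treatment session
    scales the peak by ``treatment_fold`` (< 1: reoxygenation quenches the
    hypoxia reporter; > 1: increased hypoxia signal).
    """

    sampling_interval_min: float = 2.0
    duration_min: float = 25.0
    baseline_peak: float = 1e6
    treatment_fold: float = 0.55
    time_to_peak_min: float = 10.0
    shape: float = 2.0
    noise_cv: float = 0.1
    n_animals: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling interval must be positive")
        if self.duration_min < self.sampling_interval_min:
            raise ValueError("duration must cover at least one interval")
        if self.baseline_peak <= 0 or self.treatment_fold <= 0:
            raise ValueError("peaks and folds must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_animals < 1:
            raise ValueError("need at least one animal")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min, self.sampling_interval_min)

    def analytic_flux(self, peak: float) -> np.ndarray:
        """Noiseless flux on the sampling grid for a given peak amplitude."""
        t = self.times_min
        with np.errstate(divide="ignore", invalid="ignore"):
            f = peak * (t / self.time_to_peak_min) ** self.shape \
                * np.exp(self.shape * (1.0 - t / self.time_to_peak_min))
        f[t == 0] = 0.0
        return f


def make_flux_timecourses(spec: FluxPhantomSpec) -> dict[str, dict]:
    """Generate paired baseline/treatment timecourses for each animal.

    Returns ``{animal_id: {"baseline": FluxTimecourse, "treatment":
    FluxTimecourse}}``.  The multiplicative reading noise is lognormal with
    CV ``noise_cv``, independent per reading; because the same noise law acts
    on both sessions, the expected treated/baseline peak ratio stays at
    ``treatment_fold``.
    """
    from .bli import FluxTimecourse

    t = spec.times_min
    sigma_log = np.sqrt(np.log(1.0 + spec.noise_cv ** 2))
    out: dict[str, dict] = {}
    for a in range(spec.n_animals):
        animal = f"m{a + 1:02d}"
        rng = _rng(spec.seed, 10, a)
        courses = {}
        for session, peak in (("baseline", spec.baseline_peak),
                              ("treatment", spec.baseline_peak * spec.treatment_fold)):
            f = spec.analytic_flux(peak)
            if spec.noise_cv > 0:
                f = f * np.exp(rng.normal(-sigma_log ** 2 / 2, sigma_log, size=f.size))
            courses[session] = FluxTimecourse(animal, session, t, f)
        out[animal] = courses
    return out
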