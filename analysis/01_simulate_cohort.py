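#!/usr/bin/env python
"""Simulate the imaging cohort: nine phantom patients, two dose groups.

Each patient is a digital phantom with a tumor ROI in which a post-dose T2*
increment is imposed on half the ROI; the increment varies by patient to
mimic the spread of vasoactive-drug responses (the 1 mg/kg group responds
less than the 2 mg/kg group).  Both sessions of multi-echo and BOLD data,
the ROI mask, and a ground-truth sidecar are written per patient, plus a
cohort YAML consumed by 02_run_imaging_pipeline.py.

Volumes land under scratch/cohort/ (regenerable intermediates); the cohort
config and ground-truth summaries under results/.
"""

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]

from oxypd.io import write_json, write_volume
from oxypd.phantom import default_phantom, make_bold_series, make_echo_series
from oxypd.pipeline import PatientInputs, PipelineConfig
from oxypd.registration import AffineTransform

# (patient, dose mg/kg, imposed ΔT2* ms on half the ROI)
COHORT = [
    ("dog1", 1.0, 1.0), ("dog2", 1.0, 2.0), ("dog3", 1.0, 3.0), ("dog4", 1.0, 7.0),
    ("dog5", 2.0, 3.0), ("dog6", 2.0, 6.0), ("dog7", 2.0, 7.0), ("dog8", 2.0, 8.0),
    ("dog9", 2.0, 10.0),
]

GRID = (32, 32, 12)
NOISE_SIGMA = 2.0


def main(seed: int = 2026) -> None:
    out = ROOT / "scratch" / "cohort"
    patients = []
    truths = {}
    for i, (pid, dose, delta) in enumerate(COHORT):
        # small, patient-specific inter-session motion
        rng = np.random.default_rng(seed + i)
        center = ((np.array(GRID) - 1) / 2) * np.array([1.6, 1.6, 4.0])
        mis = AffineTransform.from_params(
            translation_mm=tuple(rng.uniform(-2.0, 2.0, 3)),
            rotation_deg=(0.0, 0.0, float(rng.uniform(-3, 3))),
            center_mm=tuple(center))
        spec = default_phantom(seed=seed + i, noise_sigma=NOISE_SIGMA,
                               delta_t2star_ms=delta, misalignment=mis,
                               grid_shape=GRID)
        pdir = out / pid
        pre = make_echo_series(spec, "pre")
        post = make_echo_series(spec, "post")
        pre_files, post_files = [], []
        for e in range(pre.echo_times.size):
            pre_files.append(str(write_volume(pdir / f"pre_echo{e}.nii.gz",
                                              pre.volumes[..., e], pre.affine)))
            post_files.append(str(write_volume(pdir / f"post_echo{e}.nii.gz",
                                               post.volumes[..., e], post.affine)))
        pre_b = make_bold_series(spec, "pre")
        post_b = make_bold_series(spec, "post")
        patients.append(PatientInputs(
            patient_id=pid, dose_mg_per_kg=dose,
            pre_echoes=pre_files, post_echoes=post_files,
            pre_bold=str(write_volume(pdir / "pre_bold.nii.gz",
                                      pre_b.repeats, pre_b.affine)),
            post_bold=str(write_volume(pdir / "post_bold.nii.gz",
                                       post_b.repeats, post_b.affine)),
            roi=str(write_volume(pdir / "roi.nii.gz",
                                 spec.roi_mask.astype(float), spec.affine)),
            echo_times_ms=[float(t) for t in spec.echo_times],
        ))
        truths[pid] = spec.ground_truth()
        print(f"{pid}: dose {dose} mg/kg, imposed dT2* {delta} ms on "
              f"{truths[pid]['roi_n_voxels'] // 2} of {truths[pid]['roi_n_voxels']} "
              "ROI voxels")

    config = PipelineConfig(patients=patients,
                            out_dir=str(ROOT / "results" / "imaging"),
                            seed=seed)
    cfg_path = ROOT / "results" / "cohort.yaml"
    cfg_path.parent.mkdir(parents=True, exist_ok=True)
    config.to_yaml(cfg_path)
    write_json(ROOT / "results" / "cohort_ground_truth.json", truths)
    print(f"\nwrote cohort config -> {cfg_path}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2026)
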