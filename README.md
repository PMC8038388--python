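# oxypd

Quantification pipeline for pharmacological modification of tumor
oxygenation, as measured by two complementary readouts:

* **BOLD MRI / T2\* relaxometry.** Blood oxygen level-dependent contrast and
  the effective transverse relaxation time T2\* both lengthen as local
  deoxyhemoglobin falls, so a drug that reoxygenates a tumor raises both.
  The pipeline fits T2\* per voxel from multi-echo gradient-echo magnitude
  data, registers the post-dose session onto the pre-dose session with an
  affine transform, forms per-voxel change maps (ΔT2\* in ms; BOLD percent
  signal change), and summarizes the tumor ROI by its median change and the
  fractional tumor volume whose change exceeds 1, 2, 5 and 10 ms (or %) —
  the waterfall statistic used to compare patients and doses.
* **Dynamic bioluminescence.** An oxygen-degradable luciferase reporter
  (HIF1α ODD fused to firefly luciferase) is quenched when tissue
  reoxygenates. Photon flux after a luciferin injection is sampled every
  2 min for 25 min; the pipeline extracts each animal's peak flux,
  normalizes it to the animal's own baseline session and to caliper tumor
  volume (modified ellipsoid: V = ½·L·W²), and tests group effects with
  paired/unpaired Student's t-tests (marks: \* p≤0.05, \*\* p≤0.01,
  \*\*\* p≤0.001).

The core voxel model is monoexponential decay,

    S(TE) = S0 · exp(−TE / T2*),

fit per voxel by Levenberg–Marquardt least squares from a log-linear start,
at 8 echo times between 5 and 75 ms. No raw animal data are required: a
phantom generator (`oxypd.phantom`) produces multi-echo and 60-repeat BOLD
volumes with Rician magnitude noise, a known ΔT2\*/ΔBOLD field on a
sub-region of the ROI, a known inter-session misalignment, and
rise-then-decay flux kinetics — so every stage is validated against known
ground truth.

## Worked example

The analysis is a sequence of three drivers:

```sh
python analysis/01_simulate_cohort.py        # 9 phantom patients -> scratch/cohort/
python analysis/02_run_imaging_pipeline.py   # fit, register, change maps, waterfall
python analysis/03_bli_quantification.py     # 3 bioluminescence cohorts
```

`02_run_imaging_pipeline.py` prints the cohort waterfall — nine simulated
patients (four at 1 mg/kg with small imposed ΔT2\*, five at 2 mg/kg with
larger ones), sorted by the fraction of tumor with ΔT2\* > 5 ms:

```
patient_id  dose_mg_per_kg  median_change  frac_gt_2  frac_gt_5  frac_gt_10  responder
      dog8           2.000          2.716      0.500      0.492       0.000       True
      dog9           2.000          2.791      0.500      0.492       0.059       True
      dog7           2.000          2.769      0.500      0.412       0.000       True
      dog4           1.000          2.392      0.500      0.408       0.000       True
      dog6           2.000          1.992      0.500      0.158       0.000      False
      ...
dose 1 mg/kg: 1/4 responders (fraction >5 ms above 0.25)
dose 2 mg/kg: 3/5 responders (fraction >5 ms above 0.25)
```

Each phantom imposed its ΔT2\* on exactly half the ROI, so a fully
recovered strong responder shows `frac_gt_5 ≈ 0.5`; attenuation below that
reflects interpolation smoothing at the changed-region boundary after
registration (see docs/methods.md). `03_bli_quantification.py` recovers the
imposed peak-flux folds from six-animal cohorts with 10% reading noise:

```
vasodilator:   imposed fold 0.55, recovered 0.525 +/- 0.024 (SEM, n=6), paired t p=6.14e-05 ***
uncoupler:     imposed fold 1.60, recovered 1.541 +/- 0.060 (SEM, n=6), paired t p=5.50e-05 ***
pdh_activator: imposed fold 1.80, recovered 1.821 +/- 0.081 (SEM, n=6), paired t p=6.59e-05 ***
```

A fold of 0.55 is a 45% drop in hypoxia-reporter flux — the direction
expected when a mitochondrial complex-I inhibitor lowers tumor oxygen
consumption.

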