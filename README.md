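# hepecv

Bolus-only measurement of the hepatic **extracellular volume fraction
(ECV)** from T1 mapping, as a fully simulated and tested pipeline.

Diffuse liver fibrosis expands the extracellular space. ECV imaging
quantifies that expansion from the change in longitudinal relaxation
rate (R1 = 1/T1) of liver tissue relative to blood after a gadolinium
bolus, normalised for haematocrit:

```
ECV = (1/T1_liver_post − 1/T1_liver_pre) / (1/T1_blood_post − 1/T1_blood_pre) · (1 − Hct)
```

The bolus-only technique assumes a *dynamic equilibrium*: some minutes
after a single injection, plasma and interstitial contrast
concentrations settle into a near-constant ratio, so the ECV measured at
5, 15 or 25 min post-injection is nearly the same. This package exists
to exercise that whole measurement chain under controlled conditions,
for method developers and students of quantitative MRI:

- **`hepecv.kinetics`** — two-compartment bolus kinetics (biexponential
  plasma washout, first-order blood↔interstitium exchange, closed-form
  solution), plus a synthetic-cohort generator calibrated to a rat
  CCl₄ fibrosis study (control n=10, 8-week n=10, 16-week n=13).
- **`hepecv.molli`** — MOLLI inversion-recovery simulation: scheme
  parsing (`4(10)10`, `3(6)2(6)8`), TI schedules, the three-parameter
  magnitude signal model, and 2-D digital phantoms with liver and
  aortic regions.
- **`hepecv.t1fit`** — T1 map recovery: polarity restoration,
  three-parameter fitting (multi-start least squares for single
  signals, a vectorised variable-projection solver for whole images)
  and the Look-Locker correction T1 = T1*·(B/A − 1).
- **`hepecv.ecv`** — the ECV equation, circular-ROI extraction with
  validity masking, and per-subject record assembly.
- **`hepecv.stats`** — group summaries, Kruskal-Wallis with Dunn's
  post hoc, Spearman correlations (exact permutation p below n = 10).
- **`hepecv.pipeline` / `hepecv.cli`** — end-to-end orchestration,
  seeded for exact reproducibility, with per-stage subcommands for
  reusing the fitting/ECV/statistics stages on real T1 maps (NIfTI).

## Worked example

Noiseless model behaviour — the heart of the bolus-only claim — from
`python examples/kinetics_drift.py`:

```
group        true v_e   ECV@5  ECV@15  ECV@25  drift (pp)
control         18.38   18.40   18.99   18.99        0.59
ccl4_8wk        25.26   25.29   26.10   26.10        0.81
ccl4_16wk       31.12   31.17   32.16   32.16        1.00
```

Each row is one simulated animal: the measured ECV tracks the true
extracellular fraction at every time point and drifts upward by well
under 2.1 percentage points from 5 to 25 min — the dynamic-equilibrium
signature.

The full imaging chain (`python examples/run_study.py`) simulates all
33 subjects × 4 acquisitions, fits ~29 000 voxel T1 curves and prints
the group table; with master seed 1 it reports 15-min ECV
16.5 ± 3.0 % (control) vs 23.3 ± 4.4 % (8-week) vs 32.7 ± 4.1 %
(16-week), Kruskal-Wallis p ≈ 8e-06, within-group time-stability p of
0.73/0.68/0.47, and Spearman rho ≈ 0.94 (p < 1e-15) between ECV and the
Sirius-red histology score at every time point: ECV rises with fibrosis
severity, is stable over time, and mirrors histology.

Other examples: `fit_single_signal.py` (one MOLLI voxel, polarity
restoration and Look-Locker correction), `compute_ecv.py` (the bare
equation). The same stages are available from the shell:

```sh
hepecv run-all --seed 1 --out results/study
hepecv fit-t1 --in scan.nii.gz --out t1map.nii.gz
hepecv ecv --in t1_values.csv --out ecv.csv
```

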