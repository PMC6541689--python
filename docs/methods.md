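# Methods

## The measurement being modelled

The extracellular volume fraction (ECV) of liver tissue is estimated
from T1 maps acquired before and after a single gadolinium bolus.
Contrast shortens T1 in proportion to its local concentration, so the
change in relaxation rate ΔR1 = 1/T1_post − 1/T1_pre measures
concentration. Because gadolinium distributes only in the extracellular
space, the ratio of tissue to blood enhancement, scaled by the plasma
fraction of blood,

ECV = (ΔR1_liver / ΔR1_blood) · (1 − haematocrit),

estimates the extracellular fraction of the tissue. The estimate is
only meaningful if blood plasma and tissue interstitium are in
(dynamic) equilibrium at the time of measurement; the package's kinetic
model makes that assumption inspectable rather than implicit.

## Two-compartment bolus kinetics

Plasma concentration after the bolus is a biexponential washout
Cp(t) = a_f·e^(−r_f t) + a_s·e^(−r_s t); the interstitial concentration
obeys first-order exchange dCe/dt = k·(Cp − Ce) with Ce(0) = 0, solved
in closed form by superposition (each plasma component contributes
a·k·(e^(−r t) − e^(−k t))/(k − r), with the k → r limit a·k·t·e^(−k t)
substituted near the removable singularity). The noiseless measured ECV
equals v_e·Ce(t)/Cp(t), so its time behaviour — rising toward, and
during slow washout slightly above, the true extracellular fraction
v_e — emerges from the model.

Defaults (all configurable in `KineticsParams`):

| parameter | default | unit | rationale |
|---|---|---|---|
| a_f, a_s | 0.6, 0.4 | mmol/L | fast (mixing/renal α-phase) and slow (β-phase) amplitudes of a 0.1 mmol/kg bolus |
| r_f | 3.0 | 1/min | fast phase essentially complete before the first 5-min acquisition |
| r_s | 0.02 | 1/min | slow renal clearance; ~35 min half-life |
| k | 0.62 | 1/min | blood↔interstitium exchange; see below |
| r1 relaxivity | 5.0 | L·mmol⁻¹·s⁻¹ | typical gadobutrol value at 3 T |

The exchange rate was calibrated once against the qualitative behaviour
the measurement chain must reproduce: with k = 0.62/min the group-mean
measured ECV is monotonically non-decreasing on 5–25 min and spans
about 0.6–1.0 percentage points (≤ 2.1 pp for the most fibrotic group),
i.e. "constant with a slight upward drift". Substantially faster
exchange with a slower bolus decay (e.g. r_f = 0.5, k = 1.5) was
rejected because the surviving fast-washout transient then makes the
5-min reading *over*shoot and the ECV drift downward, contradicting the
behaviour the technique is known for. `instant_equilibration_params()`
(k = 10³/min) gives the lossless limit in which measured ECV equals
v_e exactly; end-to-end recovery tests run in this regime so the
recovery target is the generating group mean itself.

## Synthetic cohorts

Three groups mirror a rat CCl₄ intoxication study: control (n=10),
8-week (n=10) and 16-week (n=13). Per-animal ground truth is drawn from
truncated normal distributions at the published group means/SDs for
native liver T1, Sirius-red positive area, portal pressure and ECV
(the 15-min ECV row supplies the true v_e, since at equilibrium the
measured ECV equals v_e). Haematocrit (0.45 ± 0.03) and blood T1
(1600 ± 50 ms) were measured but not reported in the source study, so
typical rat values are used. Rejected (non-physical) draws are redrawn
with a cap of 1000, after which the spec is reported as hopeless;
redraw-with-cap was chosen over clipping to avoid point masses at the
bounds.

The histology score is coupled to v_e through a Gaussian copula
(latent correlation 0.7) rather than a parametric dose-response curve:
the per-group mean/SD contract must hold for both variables, which a
single monotone map of v_e cannot satisfy. Only the *independent*
component of the histology draw is redrawn on a bound violation, so the
truncation of Sirius red at 0 % (binding for the control group) cannot
bias the v_e marginal — a subtlety that shifts recovered group-mean
ECV by up to +0.7 pp if ignored. Between-group separation plus the
within-group copula reproduces the strong pooled rank correlation
between ECV and histology.

What the generator does **not** emulate: measured covariates are
conditionally independent given the group (no full covariance
structure), there is no dual blood supply or hepatocyte contrast
uptake, no iron/steatosis confounding, and fibrosis enters only through
the scalar v_e. Passing recovery tests therefore demonstrate the
*measurement chain* is unbiased under the stated signal model, not that
the biology is captured.

## MOLLI simulation

Schemes are parsed from the usual n(m)p shorthand (readout counts
outside parentheses, recovery pauses inside; pauses are kept as
seconds, since beat-counting is ill-defined for rodent imaging on a
whole-body system). The pre-contrast scheme is 4(10)10, post-contrast
3(6)2(6)8. The published protocol gives no TI values, so each inversion
group samples an arithmetic ladder TI = 100 + j·1000 ms — groups are
treated as independent inversion experiments and pooled into one fit.

Voxel signals follow the three-parameter model S(TI) = A − B·e^(−TI/T1*)
with A = 1. The apparent T1* is tied to the true T1 by a configurable
readout-perturbation factor T1*/T1 = 0.8 and B = A·(1 + T1/T1*), so the
simulation is exactly self-consistent with the Look-Locker correction
the fitter applies; only that self-consistency (not the vendor's
reconstruction) is claimed. Gaussian noise of SD A/snr is added to the
signed signal before the magnitude operation (Rician available as a
flag); SNR ∞ is the noiseless mode used by exactness tests.

Phantoms are 64×64 grids with a liver disc (radius 14) and an aortic
disc (radius 5) at the kinetics-derived ground-truth T1s; background
voxels carry zero signal and are masked invalid downstream. This size
keeps the full 33-subject × 4-time-point study at a few seconds and the
20-replicate recovery protocols under a minute each on one CPU.

## T1 fitting

Magnitude data lose the sign of pre-null samples. Every candidate flip
count (negating the i earliest-TI samples) is scored by its best-fit
residual and the minimum wins. Because A and B enter the model
linearly, the fit is solved by variable projection: a closed-form
linear solve at fixed T1*, leaving a 1-D search over T1* (coarse
geometric grid 20–8000 ms, then golden-section refinement). For whole
images this is fully vectorised across voxels; only the two best flip
candidates per voxel are refined. Polarity can be exactly ambiguous
when a single sample precedes the null point — both signings then fit
perfectly — and ties (within 1e-14 of the signal energy) resolve to the
fewest flips. A scalar reference path (`fit_ir_three_param`) uses
multi-start Levenberg-style least squares (T1* starts 200/500/1000/2000
ms) and is cross-checked against the vectorised solver in the tests.

Convergence requires A > 0 and B/A > 1 (a physically valid inversion
recovery); voxels failing that, or with residual RMS above 0.15·A
(configurable), are masked invalid. Both paths are deterministic.

## ECV extraction and statistics

A single circular liver ROI (voxel-centre inclusion rule, 0-based
row/col coordinates) excluding invalid voxels and an aortic blood-pool
ROI are propagated unchanged across all of a subject's maps; each
post-contrast record uses its own time point's blood T1. Implausible
records (no T1 shortening, ECV outside (0,1)) are flagged, never
dropped, and a missing time point is logged and skipped.

Statistics mirror the study design: Kruskal-Wallis (tie-corrected,
χ² approximation; the all-identical degenerate case returns H = 0,
p = 1) with Dunn's pairwise z tests Bonferroni-multiplied (the source
analysis used a commercial default; Bonferroni is conservative and
reproducible), and Spearman correlations with mid-ranks everywhere, an
exact permutation p below n = 10 and the t approximation otherwise.
The within-group ECV-over-time test deliberately treats time points as
independent samples — reproducing the study's method rather than
"improving" it to repeated measures.

## Orchestration and reproducibility

One master seed drives everything; per-cohort and per-acquisition seeds
are derived by SHA-256 hashing of (seed, purpose, subject, time label),
so adding a subject never reshuffles another's noise. CSV output is
rendered at six significant digits, making full-run byte-identity a
testable property. The report bundle contains the ground-truth and
ECV-record tables, the group-summary table, group-mean ECV vs time,
correlation scatter tables, a markdown report and a provenance JSON
(config hash, seed, version).

## Known limitations

- No Bloch-level simulation: slice profile, B1, inversion efficiency
  and T2* effects are absent, and flip angle/TR/TE exist only as
  protocol metadata. Agreement with any vendor's MOLLI maps is not
  claimed.
- Noise is per-voxel independent; no motion, partial volume or
  registration error between TIs.
- The kinetic model is minimal (two compartments, one exchange rate);
  it reproduces the qualitative equilibrium behaviour, not measured
  rat pharmacokinetics.
- The TI ladder leaves short-T1 polarity weakly identified (one
  pre-null sample); the tie-break keeps the fit stable but single-voxel
  accuracy at T1 ≲ 250 ms depends on the resolved ambiguity.
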