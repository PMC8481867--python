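# bvkinetics

Subject-specific blood-volume (BV) kinetics modelling and credibility
assessment for hemorrhage / fluid-resuscitation studies.

Decision-support and autonomous fluid-therapy systems need models that
predict an individual subject's blood-volume response to blood loss and
crystalloid infusion — and evidence that those models can be trusted beyond
the data they were fitted to. This package implements a complete
credibility-assessment workflow around a two-compartment BV kinetics model,
exercisable end to end on a synthetic ovine cohort that emulates a
controlled hemorrhage/resuscitation study (25 mL/kg bleed over 15 min,
5 mL/kg bleeds at 50 and 70 min, subject-specific infusion from 30 to
180 min, BV-change measurements every 5–10 min with proportional noise).

## The model

The change in blood volume from normovolemic baseline, ΔV_B(t) (mL), under
infusion rate U(t) and hemorrhage rate V(t) (mL/min) follows

    ΔV̈_B + K_p ΔV̇_B = [U̇ − V̇] + K_p U/(1+α_u) − K_p V/(1+α_v)

with three subject-specific parameters: α_u and α_v, the ratios of volume
gain/loss between the intravascular and interstitial compartments, and K_p
(1/min), the intercompartmental fluid-shift rate. Equivalently, in the
first-order realization used throughout,

    ΔV̇_B = U − V − K_p [ΔV_B − x_T(t)],
    x_T(t) = (1+α_u)⁻¹ ∫₀ᵗ U − (1+α_v)⁻¹ ∫₀ᵗ V .

For piecewise-constant inputs each segment has an exact closed-form
solution; that exact solver is the reference path everywhere (an adaptive
integrator exists only as an independent cross-check).

## The workflow

1. **Structural identifiability** (`model`): the map from (α_u, α_v, K_p)
   to the transfer-function coefficients (K_p, K_p/(1+α_u), K_p/(1+α_v)) is
   an executable bijection — unique parameters from ideal data.
2. **Pre-calibration data quality** (`precalibration`): SVD of the model's
   linear-regression form over nested candidate windows [0, T_c] grades how
   well the data constrain each coefficient and drives the
   calibration/validation split (reference setting T_c = 50 min).
3. **Calibration** (`calibration`): per-subject proportional-error
   Levenberg–Marquardt fits with multistart; staged policy that fixes
   α_u = 3 when the window leaves it unidentifiable for most subjects, and
   excludes subjects whose parameters remain implausible.
4. **Uncertainty quantification** (`uq`): asymptotic confidence
   intervals/ellipses from the weighted Jacobian, cost-contour boundedness
   diagnostics, and Monte-Carlo parameter sampling with implausible-draw
   exclusion.
5. **Validation** (`validation`): uncertainty propagated through the model
   over the held-out window; binary fluid-responsiveness agreement
   (model and experiment both above/below normovolemia) at end of therapy
   and at T*, the time when cumulative infusion first equals cumulative
   hemorrhage.

The `cohort` module generates the synthetic subjects (known ground-truth
parameters, configurable noise), including two model-mismatch phenotypes —
an unrecorded compensatory refill and an asymmetric shift rate — used to
show the pipeline flags subjects the model cannot describe.

## Worked example

```bash
python examples/04_calibrate_and_uq.py
```

```
subject S001: true alpha_v=1.295, K_p=0.226
fit converged: True, RMSNE 9.7% over 10 points

alpha_v  estimate  1.348   95% CI [ 1.147,  1.548]
k_p      estimate  0.214   95% CI [ 0.110,  0.319]

Monte-Carlo draws retained: 10000/10000 (0.00% excluded as implausible: ...)
```

One synthetic subject is generated at 10% proportional measurement noise,
calibrated on the 0–50 min window with α_u fixed at 3, and both generating
parameter values fall inside their 95% intervals; the fit error (RMSNE,
root-mean-squared error normalized by the mean absolute measured response)
is in line with the injected noise. The other examples cover simulation
(`01`), the identifiability round-trip (`02`), the SVD window analysis
(`03`), responsiveness validation (`05`), and the full pipeline with
artifact output (`06`). A thin CLI wraps the same stages:
`bvkin run-all --out results_dir`.

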