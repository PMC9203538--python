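# Methods

This note documents the models, defaults and numerical choices behind
`synaptoquant`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Signal model and the synthetic-data generator

Flow-cytometry event intensities are modelled as multiplicative log-normal:
an event with target geometric mean *m* is drawn as
`x = m · exp(σZ)`, `σ = sqrt(ln(1 + CV²))`, so the cluster geometric mean
converges to *m* and the coefficient of variation is the configured CV
(default 0.30; event-level dispersion of bead/cell acquisitions is rarely
reported, so the CV is an exposed parameter, not an assertion about any
instrument).

For a BSLB in a co-culture the target is
`background + gain · (F/P) · molecules`, where

- `gain` (default 0.5 arbitrary units per fluorochrome) is the instrument
  constant that the MESF ladder also carries, so the calibration chain is a
  true inverse of the generator rather than a shared shortcut;
- `molecules` follows the population's four-parameter logistic transfer
  curve at the given surrogate-antigen density, with dose 0 evaluated as the
  lower asymptote (the antigen-null condition).

Cells hold a conserved marker pool (default twice the transfer plateau, so
NST% saturates at 50%) and lose exactly what their BSLB gains. Transfer is
phenomenological, not mechanistic: the conserved-pool model exists so that
ground-truth NST% is well defined from molecule counts alone and equals the
transfer equation applied to those counts to machine precision.

Default experiment layout: 2-fold titration 0–1000 molec./µm² (9 doses);
three populations with plateaus 20,000/9,000/15,000 molecules per BSLB and
EC50s 250/125/60 molec./µm² (TH/Treg/CTL, hill 1.1–1.3) — saturating curves
with distinct antigen sensitivity, in the spirit of helper/regulatory/
cytotoxic differences; 10⁴ single-cell and 10⁴ single-BSLB events per
condition; 2% cell:BSLB doublets simulated as summed events to exercise
gating; optional linear spillover between marker channels (off by default)
to exercise compensation.

What the generator does **not** emulate: instrument drift and batch effects,
autofluorescence spectra, asymmetric or multimodal event clusters,
acquisition dead time, and the ligand-loading chemistry that maps protein
concentration to bilayer density. Passing tests therefore demonstrate that
the estimators invert the stated signal model at realistic noise, not that
they are robust to every artefact of a real cytometer.

## Gating

Events are classified as debris (forward scatter below a floor, default
1500), single cells (lipid-dye negative), single BSLBs (lipid-positive) or
doublets (lipid-positive with roughly summed scatter). Thresholds may be
set explicitly — in which case re-runs reproduce the partition exactly — or
derived from the data: the lipid threshold by valley detection between the
two dominant modes of the smoothed log-intensity histogram (boundary bins
count as modes so near-noiseless clusters are still split), the doublet
threshold as 2.5× the median forward scatter of lipid-positive events
(≈3 σ above the singlet mode at CV 0.30, while conjugates sit near 4×).
A warning cites the 5×10⁴ single-BSLB acquisition-floor convention when a
class is thinner than the configured minimum.

## MESF calibration

Per-level GMFI is computed from the labelled ladder, the blank (0-MESF)
level is subtracted from every positive level, and cGMFI is regressed on
MESF. The default regression is least squares **through the origin**: the
blank subtraction already anchors zero, and with log-spaced levels
(10³–10⁶) an unweighted free intercept is determined almost entirely by
top-level noise — its sampling error is tens of cGMFI units, which
translates into large relative errors exactly where signals are small (low
doses). The slope-only rule matches standard MESF practice; a free-intercept
fit remains available (`through_origin=False`), and the inverse map always
subtracts whatever intercept the curve carries. Non-positive events are
excluded from geometric means (offsets would distort ratios) and their
count is reported; negative background-corrected values are floored at zero
inside ratio statistics while the raw difference is retained. Background
precedence is isotype control first, antigen-null BSLB second, error if
neither exists. Correction happens before MESF interpolation. The Tmax%
reference series must be declared explicitly (own-series maximum or a named
population); densities use the nominal 5.00 µm bead diameter and the
0.82 µm² patch constant, both treated as opaque geometry.

Uncertainty from the calibration fit is not propagated into molecule counts;
all downstream values are point estimates.

## Dose-response analysis

The logistic is fitted by unweighted least squares (Levenberg–Marquardt on
`[bottom,] top, log EC50, hill`; EC50 on the log scale keeps it positive)
with multi-start initialization: top/bottom from the response range, EC50
from the log-interpolated half-range crossing, hill 1, plus four log-spaced
EC50 restarts across the dose span. Tolerances of 1e-12 recover noiseless
parameters to better than 1e-6. Flat response series are returned as
degenerate fits (EC50 unidentifiable) rather than errors. The
three-parameter variant fixes bottom = 0; `"auto"` chooses between them by
an F test of bottom = 0 at α = 0.05.

Curve comparison is the extra-sum-of-squares F test. The alternative model
fits each group independently; the null model constrains the chosen
parameter set (EC50, Tmax, both, or all) to common values in a joint fit
started from the per-group estimates. Degrees of freedom are
`n_total − parameters`; if the joint optimum numerically edges below the
stacked per-group optimum, the null RSS is clamped to the alternative RSS
(F = 0).

The donor-level study generator (`simulate_dose_response_study`) emulates a
cohort measured along the titration ladder: 10 donors per dose — the upper
end of the donor counts typical of these experiments — with homoscedastic
Gaussian donor scatter of 10% of the plateau. Homoscedasticity is a
deliberate modelling choice: the unweighted F comparison is exact only
under iid Gaussian errors, and multiplicative noise of the same magnitude
measurably inflates its type-I error (to ≈0.10 at nominal 0.05 in our
simulations). Under the default design the EC50 estimator operates at its
Cramér–Rao bound (≈9% median relative error); fewer donors or multiplicative
noise degrade recovery proportionally.

Holm-Šídák multiple t tests compute per-comparison two-tailed p-values
(paired by default) and adjust them by the step-down Šídák rule
`adj_k = max(adj_{k−1}, 1 − (1 − p_k)^(m−k+1))`. Zero-variance comparisons,
where the t statistic is undefined, receive an exact-tie p (1 if means
agree, else 0) with a warning.

## Vesicle sizing

The scatter-to-size map is anchored on the silica standards (default
68/91/113/155 nm; the per-standard statistic is the cluster median, robust
to scatter tails). Interpolation mode draws a piecewise log-log line through
every standard — each knot round-trips exactly — while regression mode fits
one log-log line whose slope recovers the scattering exponent. Beyond the
standard span the end segments extrapolate linearly in log-log space and
every such event is flagged: sub-68 nm medians are reportable but visibly
outside the calibrated range. Only non-positive or non-finite scatter is
unmappable; an acquisition in which nothing is mappable is rejected.
Default bin edges sit at the standards' log-space midpoints. The simulator's
scatter law is a fixed power law of diameter with exponent 4 (a
small-particle heuristic); its exact shape is immaterial because the
calibration is empirical. Concentration estimation assumes the counting
standard and the sample were acquired under matched instrument settings and
scales the known concentration by the event-rate ratio.

## Synapse imaging

Contacts are segmented from the reflection channel as pixels deviating from
the histogram mode by more than `k·MAD` (default k = 3; deviation rather
than darkness, because IRM contrast polarity depends on the optical setup),
followed by hole filling, removal of components below the minimum contact
area (default 2 µm² at the configured pixel size, 0.1 µm default) and
connected-component labelling. On a noiseless image the MAD is zero and any
deviation counts. Fluorescence per contact is `Σ(pixel − background)` over
the mask, floored at zero, with the background defaulting to the per-image
median of pixels outside all masks. Group summaries divide each group's
median by the internal control group's median within the same donor/batch,
so the control normalizes to 1 by construction. Thresholds are declared
defaults, not values inferred from any particular microscope.

## Problem sizes

Default test and acceptance workloads: 5,000 events per MESF level, 10⁴
events per co-culture condition (≈6×10⁵ events per full titration), 500
dose-response recovery cohorts, 500 null and 200 shifted F-test replicates,
10⁴ vesicle events per acquisition, and a five-scene image battery with 1–4
contacts per 256×256 frame. These sizes keep every distributional check
well-resolved while the full suite runs in well under a minute per stage.

## Known limitations

- Single-batch calibration only; no harmonization across instruments or
  days, and no uncertainty propagation from the MESF fit.
- Compensation handles generic linear spillover; full-spectrum unmixing is
  out of scope, and matrix estimation from single-stain controls is a simple
  per-channel slope approximation.
- The gating heuristics assume well-separated lipid/scatter modes; heavily
  overlapping populations need user-set thresholds.
- The F comparison inherits its exactness from homoscedastic Gaussian
  errors; strongly heteroscedastic data call for weighting or
  transformation before comparison.
- FCS support covers list-mode float data, versions 3.0/3.1.
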