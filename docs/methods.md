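# Methods

This note records the models, parameter choices and numerical decisions
behind each analysis stage, what the synthetic data do and do not emulate,
and the known limitations.

## ThT aggregation kinetics

**Model.** F(t) = F_i + (F_f − F_i)/(1 + e^{(t₅₀ − t)/k}). The fit is
plain nonlinear least squares (scipy `curve_fit`, trust-region reflective).
Initialization: F_i and F_f from the means of the first and last 5% of
points, t₅₀ from the first crossing of the midlevel, k from span/20. Only
k > 0 is bounded; F_f ≥ F_i is deliberately not enforced so a decreasing
transition fits with a negative amplitude rather than failing. A fit is
reported non-converged when the optimizer fails, when r² falls below 0.5
(a weak gate — event classification applies its own r² ≥ 0.9), when the
fitted midpoint lands more than one observation span outside the data, or
when the trace is flat (s.d. below the noise floor; reason "no
transition").

**Derived quantities.** The maximal slope is (F_f − F_i)/(4k), the
analytic derivative at t₅₀ (the expression is sometimes misprinted with
F_f twice; the derivative fixes the intent). Two lag constructions are
reported: the tangent intercept with the baseline, t₅₀ − 2k, and the
variant with an explicit baseline term, 4k·F_i/(F_f − F_i) + t₅₀ − 2k.
They are algebraically identical when F_i = 0 and differ by
4k·F_i/(F_f − F_i) otherwise; both are computed, and the baseline-term
form is the default event time so that downstream survival analysis uses
the same convention a Prism-based workflow would. ΔI for % protection is
the fitted amplitude F_f − F_i when the fit converged (raw max − baseline
otherwise); the endpoint is the mean of the final 3 raw points, robust to
a last-cycle artifact, rather than the fitted plateau.

**Event criteria.** "Significant increase in ThT" is operationalized as:
converged fit, amplitude > 10× the s.d. of the first 10 points, r² ≥ 0.9.
The thresholds were chosen so a noiseless synthetic plate is classified
perfectly; they are exposed as CLI flags. Censored wells carry the final
observation time. The baseline window means the method assumes the lag
exceeds ~10 cycles; with 350 s cycles this holds for any assay whose lag
is in hours.

## Survival analysis

Product-limit estimation handles ties by stepping all simultaneous events
together. The Mantel–Cox statistic sums hypergeometric moments over pooled
event times; single-subject risk sets contribute no variance. The hazard
ratio is the observed/expected ratio (O_a/E_a)/(O_b/E_b) with a 95% CI
from se(log HR) = √(1/E_a + 1/E_b), the classic log-rank approximation
used by common survival software; a group with zero events yields HR = ∞,
flagged rather than fabricated. Pairwise tables are Holm-adjusted
(statsmodels); the adjustment is this package's choice, as pairwise
reporting without one inflates family-wise error.

Mean time to failure: the survival staircase (sampled on a 200-point
uniform grid over [0, t_max]) is fit with a decreasing sigmoid whose upper
plateau is fixed at 1 and lower plateau is free, and the onset is the
tangent construction t₅₀ − 2|k|. The baseline-term lag variant is not used
here: with an upper plateau of 1 rather than 0 its baseline term has no
geometric meaning for a survival curve. Fewer than 3 distinct event times
gives a flagged null.

## FRAP

Normalization follows the double-normalization/full-scale scheme used by
ROI-table FRAP tools: background-subtract both signal channels, divide the
ROI by the reference (cancelling acquisition photobleaching and gain),
divide by the pre-bleach mean of that ratio (so the pre-bleach average is
exactly 1 by construction, noise included), then rescale so the first
post-bleach frame — the single gap frame, not an average — is exactly 0.
Recovery is fit on post-bleach frames with a·(1 − e^{−bt}); mobile
fraction = a, t_half = ln 2 / b, both taken from the fitted rate rather
than read off the curve. A single-exponential is the default because
condensate recoveries here are summarized by one half-time; a
two-component option exists (`--model double`), with the half-time then
solved numerically. Flat recoveries return a mobile fraction near 0 with
the rate flagged indeterminate instead of a spurious failure. Spatial
diffusion models (Soumpasis/Axelrod) are out of scope; the geometry of
full- versus half-condensate bleaches is carried as metadata only.

## TCCD

The background of each binned photon trace (default 1 ms bins; the 40 ms
minimum peak separation and 10 ms coincidence window are integer
multiples) is modeled by a least-squares Gaussian on the count histogram.
Histogram bins follow Freedman–Diaconis but are floored at one count and
aligned to half-integers, because sub-integer bins on integer counts
produce empty-bin combs that break the fit. Because bursts occupy a small
fraction of bins and live in the far tail, they shift the fitted mode by
<5% even at 1% burst occupancy (tested). Threshold = P_center + 2·FWHM
with FWHM = 2√(2 ln 2)·σ.

Peak finding uses scipy's local-maxima search with a height threshold and
minimum-distance thinning, which implements exactly the "keep the tallest,
drop neighbours closer than 40 ms" rule. Coincidence matching is greedy
one-to-one by smallest |Δt| within the window, with a channel-symmetric
tie-break; it is optimal whenever candidate pairs do not overlap (always
the case in the dilute regime) and never reuses a peak. No
chance-coincidence correction is applied to the reported percentage; a
Monte-Carlo estimate of expected chance pairs (uniformly re-drawn partner
times) is emitted as a diagnostic column. At the burst densities used in
the recovery checks this chance contribution is a known upward bias of
~2 percentage points.

## Sequence and condensation scalars

Extinction coefficients use the composition rule ε₂₈₀ = 5500·nTrp +
1490·nTyr (+125 per cystine when oxidized). In oxidized mode every
cysteine is assumed disulfide-engaged, so an odd cysteine count still
contributes one full cystine term (ceil(nCys/2)); this matches the
measured 8,605 M⁻¹cm⁻¹ of the single-cysteine HspB1 ACD, whereas a
floor-pairs rule would give 8,480. The bundled construct sequences in
`synthetic_constructs.py` are labelled reconstructions: their
aromatic/cysteine content is pinned exactly by the three measured
coefficients (19,480 / 8,605 / 1,490), while some residues in the
glycine-rich stretches of the TDP-43 LCD may differ from the database
entry. The 19,480 value belongs to the *uncleaved* His6–TEV construct —
the TEV site contributes a tyrosine; the bare domain (residues 267–414,
3 Trp + 1 Tyr) gives 17,990, and both are exposed.

Degree of labeling is the standard molar dye:protein ratio as a
percentage, DOL = 100·(A_dye/ε_dye)/((A₂₈₀ − CF·A_dye)/ε_protein), using
the dye's 280 nm correction factor (0.08 for Cy5). The protein's molecular
weight is accepted as metadata but does not enter this molar-ratio form.
Dilute-phase fractions come from Beer–Lambert with a configurable path
length (default 0.1 cm, a microvolume-spectrophotometer-like value);
fractions above 1.05 are flagged, not clipped. Turbidity ΔOD defaults to
the mean of the final 3 minus the mean of the first 3 points to damp
single-cycle noise; `--literal-endpoint` restores the single final-point
rule.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the estimators assume —
sigmoidal transitions with lognormal per-well midpoints (CV parameter;
nucleation times are right-skewed and strictly positive), Bernoulli
non-aggregating wells, Gaussian instrument noise, exponential FRAP
recovery under mild shared acquisition photobleaching, truncated-normal
photon backgrounds with Gaussian-profile bursts (the width parameter is
the profile σ, intra-channel burst spacing is at least 3× that width, and
coincident bursts carry ±2 ms jitter, inside the 10 ms window), and
saturating turbidity.
They are *not* mechanistic: no nucleation–elongation mass-action kinetics,
no spatial bleach geometry, no photophysics (blinking, crosstalk), no
shot-noise/Poisson detection statistics. Passing recovery tests therefore
demonstrates estimator correctness under the assumed noise model, not
robustness to every instrument pathology. No quantitative instrument noise
magnitudes are published for these assays; the defaults (2% ThT amplitude
noise, 1% relative FRAP noise, background 10 ± 2 counts/ms) are this
package's choices of realistic magnitudes.

## Problem sizes used in the checks

The reproduction script and acceptance tests use 200 synthetic wells for
Boltzmann recovery (181 cycles of 350 s), 1000 random parameter sets for
the lag identity, 200 small datasets plus 2000 null pairs (20 wells per
group, lognormal lags with CV 0.3, censoring at 7200 s) for the survival
stage, 100 FRAP replicates (10 pre- + 526 post-bleach frames at 0.171 s),
and one 240 s two-channel acquisition with 1000 bursts per channel at a
true coincident fraction of 0.5. These sizes give comfortable Monte-Carlo
margins for every stated tolerance while keeping a full run in seconds.

## Known limitations

- Gains differing between plates are carried as metadata; no cross-plate
  normalization is attempted.
- The log-rank HR confidence interval uses the O/E normal approximation;
  for very small event counts a Cox model would be preferable (out of
  scope).
- The TCCD percentage is uncorrected for chance coincidence by design;
  use the diagnostic column when densities differ between conditions.
- The baseline-term lag formula can go negative for large F_i/(F_f − F_i);
  event times are clipped to be positive.
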