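# phasekin

Quantitative analysis of protein aggregation and liquid–liquid phase
separation, built for plate-reader and single-molecule fluorescence data of
the kind produced when studying how small heat-shock proteins (sHsps such as
HspB1 and HspB5) modulate the aggregation and condensation of the TDP-43
low-complexity domain (LCD). The package is aimed at protein biophysicists
who export intensity tables from their instruments and want a reproducible,
scriptable pipeline instead of per-figure spreadsheet fits.

It covers five analysis stages, each usable from Python or the `phasekin`
command line:

1. **ThT aggregation kinetics** (`phasekin.tht`). Each well's thioflavin-T
   time course F(t) is fit to the Boltzmann sigmoid

   F(t) = F_i + (F_f − F_i) / (1 + e^{(t₅₀ − t)/k}),

   giving baseline F_i, plateau F_f, midpoint t₅₀ and slope parameter k.
   Derived summaries: maximal elongation rate (F_f − F_i)/(4k); lag time
   (both the tangent construction t₅₀ − 2k and the baseline-term variant
   4k·F_i/(F_f − F_i) + t₅₀ − 2k, which coincide when F_i = 0); endpoint
   intensity; and chaperone efficacy as
   %Protection = (ΔI − ΔI_chaperone)/ΔI × 100 (negative when the chaperone
   increases the amplitude).
2. **Kaplan–Meier analysis of aggregation events** (`phasekin.survival`).
   Wells that aggregate contribute an event at their lag time, wells that
   never do are right-censored at the assay end; product-limit curves,
   Mantel–Cox log-rank tests with observed/expected hazard ratios and 95%
   CIs, Holm-adjusted pairwise tables, and a mean time to failure from a
   decreasing sigmoid fit to the survival staircase.
3. **FRAP** (`phasekin.frap`). Full-scale normalization of three-ROI
   recovery series (bleached region, whole-condensate reference,
   background) so the pre-bleach mean is 1 and the first post-bleach frame
   is 0, then a single-exponential fit a·(1 − e^{−bt}) giving the mobile
   fraction a and half-time ln 2 / b.
4. **Two-color coincidence detection** (`phasekin.tccd`). Per channel, the
   photon-count histogram is fit with a normal distribution; the detection
   threshold is P_center + 2·FWHM with FWHM = 2√(2 ln 2)·σ. Peaks above
   threshold (minimum separation 40 ms) are matched across channels within
   a 10 ms window; %coincident = coincident peaks / reference-channel peaks
   × 100.
5. **Condensation scalars** (`phasekin.quant`). Sequence-composition
   extinction coefficients (5500·nTrp + 1490·nTyr + 125 per cystine when
   oxidized), degree of labeling of dye conjugates, Beer–Lambert
   dilute-phase fractions after pelleting condensates, and turbidity ΔOD.

Because raw wet-lab exports are instrument-specific, `phasekin.synth`
generates synthetic datasets with known ground truth for every stage
(stochastic per-well lags, censored non-aggregating wells, photobleaching-
corrupted FRAP series, two-channel burst traces with a controlled
coincident fraction, saturating turbidity curves); all tests and the
reproduction script run on these.

## Worked example

Simulate a small plate plus FRAP/TCCD/turbidity datasets, then analyze
them:

```sh
phasekin simulate --config demo_cfg.yaml --out demo --seed 7
phasekin tht --input demo/plate.csv --out demo/tht
phasekin frap --input demo/frap.csv --out demo/frap
phasekin tccd --input-a demo/photons_a.csv --input-b demo/photons_b.csv --out demo/tccd
phasekin condense --input demo/turbidity.csv --out demo/cond
```

with `demo_cfg.yaml` asking for 8 wells, t₅₀ = 14400 s, k = 1000 s, 15%
lag scatter and a 25% non-aggregating fraction. The run prints

```
fit 8 wells; 6 aggregation events
fit 1 series
9 coincident pairs (30.0% of channel a)
dOD(340 nm) = 0.4217
dOD(400 nm) = 0.2909
dOD(600 nm) = 0.1242
```

`demo/tht/tht_fits.csv` holds the per-well parameters — e.g. well A1 fits
F_i = 91.9, F_f = 1098.4, t₅₀ = 13185 s, k = 1019 s (r² = 0.999), an
elongation rate of 0.247 a.u./s and a lag of 11519 s, so it is scored as an
aggregation event at that time; the two censored wells carry the final
assay time. The FRAP table reports a mobile fraction of 0.707 and a
half-time of 5.04 s against generator truth 0.7 / 5.0 s. The TCCD summary
(9 of 30 reference peaks coincident = 30.0%, with 1.89 pairs expected by
chance) reflects the simulated 25% coincident-burst fraction plus chance
overlaps. The ΔOD values are the saturating turbidity amplitudes at the
three wavelengths.

Sequence utilities work the same way:

```sh
$ phasekin quant ext --sequence WGMMGMLASQQNQY
6990 M-1 cm-1
```

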