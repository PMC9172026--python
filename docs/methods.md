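# Methods

## Problem and model

A diurnal expression profile sampled over one 24 h cycle is summarized by
its acrophase — the time at which a fitted periodic waveform attains its
maximum. When the same gene is profiled under two photoperiods (long day
14L:10D vs short day 10L:14D, or the first day of constant darkness after
each), the acrophase generally moves. The analysis asks *which external
reference event the peak tracks*: if the peak keeps a fixed delay after
lights-on, its shift is smallest in Zeitgeber time (ZT); after the midpoint
of the dark period, smallest in midnight-fitting time (MNFT); after
lights-off, smallest in sunset-fitting time (SSFT). The frame of the
minimum shift defines the synchronization mode — Sunrise,
Midnight/Midday, or Sunset — interpreted as the anchor of the underlying
oscillator.

### Circular time frames

For a scheme with light period `L` (hours), on a 24 h circle:

* ZT: identity frame, 0 = lights-on;
* MNFT = (ZT − (12 + L/2)) mod 24 — the midnight anchor is the midpoint of
  the dark period, ZT 19 for L = 14 and ZT 17 for L = 10. The anchor
  formula is a design choice (the obvious geometric definition of
  "midnight"); it reproduces every published MNFT/pMNFT value the test
  suite checks, which is the strongest available validation;
* SSFT = (ZT − L) mod 24.

Constant-darkness conditions use the *projected* frames (pZT/pMNFT/pSSFT)
with the anchors of the preceding entrainment cycle; the arithmetic is
identical.

Shift widths are circular distances, `Δ(a, b) = min(d, 24 − d)` with
`d = |a − b| mod 24`, hence always in [0, 12]. This matters in practice:
peaks straddling the frame origin (e.g. SSFT 23.31 vs 0.46) would otherwise
produce spurious ~23 h shifts.

### Mode classification

All three shift widths are computed at full floating-point precision and
the minimum decides the mode. If two deltas are exactly equal the first
frame in the order (Sunrise, Midnight/Midday, Sunset) wins and the row is
flagged `tie=True`; reported tables round to 2 decimals
(half-away-from-zero), but rounding never decides a mode. When a gene has
an extra peak in only one condition (bimodal under one photoperiod,
unimodal under the other), the unimodal condition's primary peak is reused
as the comparison partner — explicitly, with the row flagged
`partner_reused`, never silently.

## Cosinor fitting

Replicate observations (not time-point means) are regressed on

    y(t) = a0 + sum_{j=1..k} [ a_j sin(2*pi*j*t/24) + b_j cos(2*pi*j*t/24) ]

by least squares with the period fixed at 24 h. Keeping replicates as
independent observations preserves the within-time-point variance that the
F-tests use. The harmonic count `k` is chosen by forward selection:
starting at `k = 1`, harmonic `k+1` (two more parameters) is added while
its incremental F-test has p < `alpha` (default 0.05), up to
`max_harmonics` (default 3) and never beyond what the sampling grid
identifies (`2k+2` distinct time points, ≥ 1 residual degree of freedom).
The rhythmicity p-value is the F-test of the selected model against the
flat mean. Degenerate inputs — fewer than two distinct time points, or
zero variance — return an explicit flat fit (`k = 0`, p = 1) instead of
raising, so batch runs complete.

Acrophases are read off the fitted curve on a dense circular grid
(`grid_step` 0.01 h, matching the 2-decimal reporting precision). The
global maximum is the primary acrophase; every other local maximum whose
prominence — height above the higher adjacent trough, relative to the
fitted peak-to-trough range — exceeds `min_prominence` (default 0.1) is a
secondary peak. The prominence criterion is this package's construct: a
numeric stand-in for the qualitative judgement that a blunted second bump
is still a peak. With two peaks the one nearer (projected) sunrise is
labeled `M` (morning) and the other `E` (evening); an extra peak whose
partner condition is unimodal is labeled `second`. More than three maxima
is logged as a likely overfit.

With forward selection at alpha = 0.05, roughly one noisy series in twenty
picks up a spurious harmonic; that occasionally skews the global maximum by
an hour or two and is the dominant error source in mode recovery (see the
end-to-end test, which requires ≥ 90% recovery over 50 simulated studies).

## ΔΔCt quantification

Per sample, the reference aggregate is the arithmetic mean of the
reference-gene Ct values — equivalent to the geometric mean of reference
abundances at 100% efficiency, the standard multi-reference practice, and
our reading of an otherwise undefined multi-reference "mean"; averaging
reference quantities instead is available via
`NormalizationSpec(aggregate="mean_quantity")`. The calibrator defaults to
the per-gene mean ΔCt across samples, so levels are arbitrary relative
units: downstream analysis uses only profile shape. Efficiency correction
(base `1 + E/100` per gene) is off by default — primers are assumed
validated near 100% — but accepted as input. The transform is exactly
invertible: noise-free Ct tables generated from known fold-changes recover
them to 1e−9 (acceptance test).

## Nonparametric statistics

With 3–5 replicates per time point, normal-theory ANOVA is unreliable, so
time-of-day variation is tested by Kruskal–Wallis across time points with
Dunn pairwise z-tests (midrank ties, tie-corrected rank variance) and
Bonferroni adjustment over all time-point pairs. Averaged expression
between light conditions is compared by a two-sided Mann–Whitney U on the
pooled replicate levels (pooling is the default; per-time-point means are
a config option), with Shapiro–Wilk normality p-values reported per pool.
The exact U null distribution is used when both pools have ≤ 20
observations and no ties; otherwise the normal approximation with tie and
continuity corrections. Significance is p < 0.05 throughout, two-sided; no
multiple-testing correction is applied across genes.

## Synthetic data generator

The generator emulates the study design: 12 time points (ZT1–ZT23, every
2 h), 4 replicates, four conditions (LD, SD, LD-DD, SD-DD). Each simulated
gene has a mode anchor plus offset (so its LD and SD peaks coincide in its
own mode's frame — the signature the classifier must detect), 1–3
harmonics with geometrically decaying weights (ratio 0.5, normalized so
the stated amplitude is the peak deviation from the mesor), an optional
secondary von-Mises-shaped bump (concentration 6, i.e. ~±1.5 h half-width;
against the opposing flank of the fundamental a secondary bump needs an
amplitude comparable to the main oscillation to form a distinct local
maximum, much less near the trough), an optional multiplicative light
boost applied during the light period of non-projected schemes only
(emulating light-driven genes whose daytime peak collapses in darkness;
modeled as an instantaneous factor, not an induction kinetic — sufficient
phenomenology at 2 h resolution), and multiplicative lognormal noise of
unit mean (chosen over additive Gaussian because expression levels are
positive and replicate scatter grows with the mean).

Defaults: mesor 1.0, amplitude 0.7 (a strong ocular clock-gene rhythm;
relative units are arbitrary, only the amplitude:mesor and noise ratios
matter), noise CV 0.2, light boost 1.0. The default study has 12 genes,
four per mode, at anchor offsets −2, 0, 2.5 and 5 h. Ct tables are derived
as `Ct = base_ct − log2(level)` plus Gaussian technical noise (default
base 25, flat reference genes at Ct 20 and 22).

What the generator does *not* emulate: per-animal random effects,
transcription–degradation kinetics, light-history effects beyond the
on/off boost, or inter-gene correlation. Passing tests therefore show that
the pipeline recovers the truth of *this* generative family at realistic
noise, not that real eye samples satisfy its assumptions.

## Numerical choices

* All times are 0-based hours since (projected) lights-on, reduced modulo
  24; intervals half-open `[0, 24)`.
* Report rounding is 2 decimals, half-away-from-zero; internal arithmetic
  is full precision. Golden-table comparisons allow ±0.01 for the
  source's own rounding (whether its deltas were computed from rounded or
  full-precision acrophases is not stated).
* Perfect fits (residual sum of squares ≤ 1e−12 of total) short-circuit
  the F-machinery to p = 0 rather than dividing by zero.
* Random streams derive from a study seed plus CRC32 tags of gene and
  condition names, so datasets are byte-identical across runs and
  independent of generation order.

## Known limitations

* Period is fixed at 24 h; the package does not estimate free-running
  period, acrophase confidence ellipses, or compare against other rhythm
  detectors.
* The prominence threshold for secondary peaks, and the arithmetic-mean
  reading of the multi-reference aggregate, are this package's
  constructions where the original procedure is under-specified; both are
  configurable.
* Raw replicate-level data behind the published tables are not available,
  so figure-level profiles and supplementary p-values cannot be
  reproduced; correctness of those stages rests on the synthetic
  round-trip and oracle tests instead.
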