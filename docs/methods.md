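# Methods

## The observational unit

Hair grows in rhythmic alternations of growth and quiescence that leave
scale-like bands on the shaft.  The width of one such band — a *repeat
interval* (RI), in mm — is the package's observation; ordered along the
shaft, the widths form a time series whose "clock" is *observations*,
not seconds.  All frequencies are therefore expressed in radians per RI.
Converting spectral structure into absolute time (days) requires
identifying the period of at least one spectral peak, which is the
chronology module's job.

## Periodogram

The spectrum of a series of n widths is the classical periodogram on the
Fourier grid ω_k = 2πk/n, k = 1..⌊n/2⌋, after mean removal (linear
detrending is available but off by default; no tapering or smoothing).
Ordinates are normalised as

    P_k = 2|X_k|² / n²   (0 < ω_k < π),   P_{n/2} = |X_{n/2}|² / n²,

with X_k the unnormalised DFT, so that Σ_k P_k equals the sample
variance (ddof = 0) of the mean-removed series exactly — the periodogram
is a variance decomposition, and band variances are sums of ordinates
over half-open intervals (lo, hi], additive over disjoint bands.  The
test suite checks this Parseval identity at relative tolerance 1e-9 and
checks the full transform against a direct O(n²) sine/cosine projection
oracle.

Peak detection is the band-restricted argmax of the ordinates, ties
broken toward the lower frequency (the conservative, longer-period
reading).  A peak's resolution is one Fourier bin, 2π/n.

## Frequency bands

Following heart-rate-variability convention, variance is split into a
low-frequency (LF) and a high-frequency (HF) band; the LF/HF variance
ratio indexes the balance of slow versus fast rhythmic drive.  Default
bounds are LF = (0, 0.15] and HF = (0.15, π] rad/RI, placed so that a
weekly rhythm near 0.045 rad/RI and a daily rhythm near 0.32 rad/RI fall
well inside their bands; both bands are configurable.  The Nyquist
ordinate (even n) belongs to HF so the two bands partition the grid.

Note the minimum window for any LF analysis: the first Fourier bin of a
window of length w is 2π/w, so the default LF band contains a grid point
only for w ≥ 42.  The pipeline's sliding-window defaults (window 48,
step 1) respect this while remaining usable on the shortest series the
default study generates (53 observations).

## Chronology

With mean RI width d̄ (mm/obs) and an identified peak at f rad/obs whose
rhythm has period T days/cycle, the growth rate is

    rate = d̄ · (2π/f) / T   [mm/day],

i.e. observations-per-cycle times mm-per-observation over days-per-cycle.
Annualisation uses days_per_year = 365 (configurable; 365.25 available).

Period identification uses a counterfactual argument: if the HF peak
were an *annual* rhythm, annual growth would be d̄·2π/f mm/yr.  For the
reference geometry (d̄ = 0.132 mm, f = 0.32 rad/RI) that is ≈ 2.6 mm/yr
— two orders of magnitude below the ~160 mm/yr of normal scalp hair —
so the annual reading is rejected (threshold 20 mm/yr, configurable) and
the peak is labelled daily.  The LF peak is labelled weekly when the
HF/LF frequency ratio falls in [5, 9] (a window around 7; configurable).
The counterfactual annual growth and implied annual-cycle count of the
mean long remnant are always reported as computed; for the reference
inputs the cycle count evaluates to ≈ 6.7.

Elapsed time since a hair cut is remnant length divided by the daily
growth rate of the remnant's size class.  Per-class rates are the
default (a long-only option exists); with the reference constants the
six reference remnants give 3.5–4.7 days, reported additionally as the
outward-rounded window [3, 5].

Two run modes separate reproduction from estimation: *paper_pinned*
takes the class mean widths (0.132 / 0.214 mm) and peak frequencies
(0.32 / 0.045 rad/RI) from configuration, reproducing the reference
arithmetic chain exactly; *empirical* estimates mean widths from the
series and peak frequencies as per-class medians of per-hair band
argmaxes.

## Approximate entropy

ApEn(m, r) is computed in the original convention: Chebyshev distance,
self-matches included, Φ(k) the mean log fraction of k-windows within r,
and ApEn = Φ(m) − Φ(m+1).  The tolerance is r = r_fraction × sample SD
(ddof = 1) of the analysed series; defaults m ∈ {2, 3}, r_fraction = 0.8.
A constant series returns 0 with a degeneracy flag (perfect regularity;
constancy is detected by zero range, robust to floating-point SD).  The
implementation (vectorised) is checked against a pure-Python double-loop
oracle at relative tolerance 1e-12 up to n = 300, m ∈ {2, 3}.  Because
the tolerance fraction is itself a modelling choice, `apen_sweep`
evaluates ApEn over r_fraction ∈ {0.1, …, 1.0} so discrimination between
groups can be read off as a function of r rather than asserted at a
single value.

`apen_of_lfhf` applies ApEn to the sliding-window LF/HF ratio sequence
of one hair (each window mean-removed and transformed independently),
quantifying how (ir)regularly the balance between the weekly and daily
rhythms wanders along the shaft.

## Group comparisons

Hairs are the unit of analysis (per-window values are available as a
config option); groups are small (4 vs 6 by default), so the default
test is the exact Mann-Whitney U (exact null whenever both groups have
≤ 10 values), with Welch's t and a permutation test on the difference of
means as alternatives.  The permutation test enumerates all splits when
the pooled n ≤ 12 and otherwise uses ≥ 10,000 seeded resamples with an
add-one correction.  P-values are two-sided; the direction of the
difference (by means, or mean ranks for the rank test) is reported as a
separate field.  No multiple-testing correction is applied across the
three metrics by default; Holm adjustment is available.

## Synthetic generator

Each series is

    width_t = μ + A_d sin(f_d t + φ_d) + A_w sin(f_w t + φ_w) + ε_t,

with defaults f_d = 0.32 and f_w = 0.045 rad/RI, iid Gaussian ε, and
rejection-redrawing of any non-positive draw (positivity without
material spectral distortion at the default SNR).  Phases are
seeded-random per hair: they are unobserved in real hair, so randomising
them is the honest null.  Default amplitudes put the daily component at
twice the noise SD (A_d = 0.04 mm, σ = 0.02 mm at μ = 0.132 mm; scaled
proportionally for the long class at μ = 0.214 mm) — an explicitly
assumed SNR, since the measured series' amplitudes are unpublished.

The default study mirrors the reference geometry: 4 control hairs of 53
observations (212 total) and 6 case hairs whose counts are proportional
to the six reference remnant lengths (504 total; largest-remainder
rounding).  The individual per-hair counts are a reconstruction — only
the group totals are known.

The `sympathetic_activation` preset is the control parameter set with
the weekly (LF) amplitude doubled and the noise SD scaled by 1.5.  It
reliably produces a higher LF/HF ratio than control (≈ 99% of paired
replicates at n = 128).  Two caveats are intrinsic to this construction
and worth stating plainly:

* it *raises* case LF variance, whereas the reference observations had
  case LF variance decreased; the preset constructs only the ratio
  contrast, not the full band-variance pattern;
* it does **not** produce a higher ApEn of the LF/HF ratio sequence for
  the case.  With r scaled to the SD of the analysed sequence, any
  elevation of LF power — coherent (larger weekly amplitude) or
  broadband (autoregressive LF variability, which was also evaluated) —
  produces large, smooth excursions of the windowed ratio sequence that
  dominate its SD, inflate the tolerance, and make the case sequence
  read as *more* regular.  Across windows 48–280, steps from 1 to fully
  disjoint, series lengths 212–1024 and plain or log ratios, the
  case-higher ApEn direction never exceeded ~60% of replicates.  The
  corresponding directional test is therefore expected to fail under
  this generator, and the failure is informative: an elevated-ApEn
  contrast in the ratio sequence is evidence of a structure (irregular
  rhythm modulation) that a stationary sinusoids-plus-noise model cannot
  represent, whatever its parameters.

What passing tests on synthetic data do show: the spectral estimator
recovers planted frequencies to one bin at SNR 2 (≥ 95% of replicates),
the growth-rate chain inverts the generator's parameters, and the
ratio-contrast direction is reproduced.  What they cannot show: fidelity
of the generator to real bog-preserved hair, whose amplitude structure,
nonstationarity and measurement error are unknown.

## Numerical choices

* Periodogram via FFT; normalisation chosen so Parseval is exact, not
  approximate.
* Band membership is (lo, hi] everywhere, making bands partition the
  grid without double-counting.
* HF-variance degeneracy (ratio undefined) is declared when HF variance
  ≤ 1e-13 × total variance, absorbing FFT round-off of spectra that are
  analytically zero in the band.
* Growth-rate frequencies are accepted in (0, 2π]: grid frequencies end
  at π, but 2π (one cycle per observation) is the formula's natural
  degenerate limit and useful in unit checks.
* Reported precision follows the chain's own conventions: cm/yr to the
  nearest integer, counterfactual mm/yr to the nearest integer, days at
  0.1 with the headline window rounded outward to whole days.

## Problem sizes

Simulation-based checks use 100–200 replicates of series of 128–504
observations; oracle comparisons run to n = 128 (spectra) and n = 300
(ApEn).  These sizes make every statistical property estimable with
comfortable margins while keeping the whole suite fast to run routinely.
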