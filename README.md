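# trichron

Chronology, rhythm and regularity analysis of hair growth-line series.

Hair grows in rhythmic alternations of growth and quiescence that leave
scale-like bands on the shaft.  The width of one band — a *repeat
interval* (RI), measured in mm by microscopy — is a record of the
metabolic state of the follicle when it formed.  An ordered sequence of
RI widths along a shaft is therefore a time series whose clock is
"observations", and standard spectral methods from heart-rate-variability
analysis apply to it.  `trichron` is for bioarchaeologists, forensic
scientists and physiologists who want to turn such series into:

* **periodogram spectra** with daily/weekly peak detection
  (frequencies in radians per RI);
* an **absolute chronology**: a spectral peak at `f` rad/obs with an
  identified period of `T` days/cycle converts mean RI width `d̄` into a
  growth rate `d̄·(2π/f)/T` mm/day, and remnant lengths into elapsed
  days since a hair cut;
* a **periodicity assignment by contradiction**: the high-frequency peak
  cannot be annual, because the annual growth it would imply (a few
  mm/yr against ~160 mm/yr for normal scalp hair) is biologically
  implausible — so it is daily, and a low-frequency peak at ~1/7 of its
  frequency is weekly;
* **LF/HF band-variance statistics** (the sympathetic/parasympathetic
  balance index of heart-rate-variability practice, applied to RI
  series) and **approximate entropy** (ApEn) of the widths and of the
  sliding-window LF/HF ratio sequence;
* **case/control comparisons** of these metrics with small-sample exact
  tests;
* a **synthetic generator** (sinusoids plus truncated Gaussian noise)
  that emulates the assumed series structure, so the entire pipeline is
  testable without any microscope.

## Worked example

```python
import trichron as tc

# growth rate from the long-class mean RI width and the daily HF peak
est = tc.growth_rate(0.214, 0.32)
print(f"growth rate: {est.mm_per_day:.1f} mm/day = {est.cm_per_year:.0f} cm/yr")

# label the peaks: could the HF peak be annual?
a = tc.assign_periodicities(0.32, 0.045, ri_mean_mm=0.132, remnant_len_mm=17.4)
print(f"HF label: {a.hf_label.value}  (counterfactual annual growth "
      f"{a.counterfactual_annual_growth_mm:.1f} mm/yr, "
      f"{a.counterfactual_cycle_count:.1f} cycles)")
print(f"LF label: {a.lf_label.value}  (HF/LF ratio {a.freq_ratio:.1f})")

# elapsed time since the cut, per remnant size class
rates = {tc.SizeClass.SHORT_MEDIUM: tc.growth_rate(0.132, 0.32),
         tc.SizeClass.LONG: est}
report = tc.elapsed_days(tc.load_reference_remnants(), rates)
print(f"elapsed days: {report.min_days:.1f}-{report.max_days:.1f} "
      f"(window {report.headline_window[0]}-{report.headline_window[1]} days)")
```

prints

```
growth rate: 4.2 mm/day = 153 cm/yr
HF label: daily  (counterfactual annual growth 2.6 mm/yr, 6.7 cycles)
LF label: weekly  (HF/LF ratio 7.1)
elapsed days: 3.5-4.7 (window 3-5 days)
```

Read top to bottom: a mean RI width of 0.214 mm with a daily rhythm at
0.32 rad/RI means the hair grew 4.2 mm per day — 153 cm/yr, roughly ten
times the ~16 cm/yr of normal scalp hair (hypertrichosis).  The daily
label is forced by contradiction: an annual reading would imply 2.6 mm
of growth per year, absurd for scalp hair.  The low-frequency peak sits
a factor ~7 below the daily one, hence weekly.  Dividing the six
cropped-remnant lengths by their class growth rates dates the hair cut
to 3.5–4.7 days before growth stopped.

## Command line

```bash
trichron generate --seed 1 --out data/            # synthetic study CSVs
trichron analyze --preset sympathetic_activation --seed 1 --out report.json
trichron analyze --ri-csv data/ri_series.csv --remnants-csv data/remnants.csv \
                 --mode empirical --out report.json
trichron sweep-apen --preset control --seed 1 --out sweep.json
```

`analyze` runs ingest → spectra → chronology → entropy → comparisons and
writes a versioned JSON (or CSV) report.  `--mode paper_pinned`
(default) takes class mean widths and peak frequencies from
configuration; `--mode empirical` estimates everything from the series.
All options can also be given in a YAML file via `--config`.

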