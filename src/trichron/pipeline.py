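"""End-to-end analysis: ingest -> spectra -> chronology -> entropy ->
group comparisons -> report.

Every stage's key outputs are gathered into one nested report (see
:func:`trichron.ri_data.write_report`); randomness derives exclusively
from the configured seed, so a rerun with the same configuration is
bitwise-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import statistics
from typing import Any

from . import chronology as chron
from . import entropy as ent
from . import group_stats as gs
from . import spectral as spec
from . import synthetic as synth
from .config import RunConfig
from .errors import TrichronError
from .ri_data import (
    RISeries,
    SizeClass,
    StudyData,
    load_reference_remnants,
    read_remnants_csv,
    read_ri_csv,
    write_report,
)

logger = logging.getLogger("trichron")


def _bands(config: RunConfig) -> tuple[spec.Band, spec.Band]:
    return (
        spec.Band(config.lf_lo, config.lf_hi, name="LF"),
        spec.Band(config.hf_lo, config.hf_hi, name="HF"),
    )


def _load_study(config: RunConfig) -> StudyData:
    if config.preset is not None:
        study = synth.generate_study(seed=config.seed, case_preset=config.preset)
        logger.info(
            "generated synthetic study (preset=%s, seed=%d): %d case obs, %d control obs",
            config.preset, config.seed,
            study.n_case_observations, study.n_control_observations,
        )
        return study
    series = read_ri_csv(config.ri_csv)
    remnants = (
        read_remnants_csv(config.remnants_csv)
        if config.remnants_csv is not None
        else []
    )
    remnant_ids = {r.hair_id for r in remnants}
    cases = [s for s in series if s.hair_id in remnant_ids]
    controls = [s for s in series if s.hair_id not in remnant_ids]
    if not cases:  # no remnant metadata: treat everything as case material
        cases, controls = controls, []
    logger.info("read %d case and %d control series from %s",
                len(cases), len(controls), config.ri_csv)
    return StudyData(cases=cases, case_remnants=remnants, controls=controls,
                     provenance=f"files: {config.ri_csv}")


def _spectra_stage(study: StudyData, config: RunConfig) -> dict[str, Any]:
    lf, hf = _bands(config)
    out: dict[str, Any] = {}
    for group, series_list in (("case", study.cases), ("control", study.controls)):
        for s in series_list:
            spectrum = spec.periodogram(s, detrend=config.detrend)
            hf_peak = spec.find_peak(spectrum, hf)
            lf_peak = spec.find_peak(spectrum, lf)
            summary = spec.lfhf_summary(spectrum, lf, hf)
            out[s.hair_id] = {
                "group": group,
                "size_class": s.size_class.value,
                "n": spectrum.n,
                "mean_width_mm": s.mean_width,
                "hf_peak_rad": hf_peak.frequency,
                "hf_peak_power_mm2": hf_peak.power,
                "lf_peak_rad": lf_peak.frequency,
                "lf_peak_power_mm2": lf_peak.power,
                "bin_width_rad": spectrum.bin_width,
                "lf_variance_mm2": summary.lf_variance,
                "hf_variance_mm2": summary.hf_variance,
                "lfhf_ratio": summary.lfhf_ratio,
            }
    logger.info("spectra computed for %d hairs", len(out))
    return out


def _class_inputs(
    study: StudyData, spectra: dict[str, Any], config: RunConfig
) -> dict[SizeClass, tuple[float, float]]:
    """Per size class: (mean RI width mm, HF peak frequency rad/RI)."""
    if config.mode == "paper_pinned":
        return {
            SizeClass.SHORT_MEDIUM: (config.ri_mean_short_medium, config.pinned_hf_freq),
            SizeClass.LONG: (config.ri_mean_long, config.pinned_hf_freq),
        }
    result = {}
    for cls in SizeClass:
        hairs = [s for s in study.cases if s.size_class is cls]
        if not hairs:
            continue
        mean_width = statistics.fmean(s.mean_width for s in hairs)
        hf_freq = statistics.median(
            spectra[s.hair_id]["hf_peak_rad"] for s in hairs
        )
        result[cls] = (mean_width, hf_freq)
    return result


def _chronology_stage(
    study: StudyData, spectra: dict[str, Any], config: RunConfig
) -> dict[str, Any]:
    per_class = _class_inputs(study, spectra, config)
    out: dict[str, Any] = {"per_class": {}, "mode": config.mode}
    rates: dict[SizeClass, chron.GrowthEstimate] = {}
    for cls, (mean_width, hf_freq) in per_class.items():
        est = chron.growth_rate(
            mean_width, hf_freq, period_days=1.0,
            days_per_year=config.days_per_year,
        )
        rates[cls] = est
        out["per_class"][cls.value] = dataclasses.asdict(est)

    long_remnants = [r for r in study.case_remnants
                     if r.size_class is SizeClass.LONG]
    if long_remnants and SizeClass.LONG in per_class:
        mean_len = statistics.fmean(r.length_mm for r in long_remnants)
        mean_width, hf_freq = per_class[SizeClass.LONG]
        # LF frequency for the assignment: pinned, or the long-class
        # median of per-hair LF peaks
        if config.mode == "paper_pinned":
            lf_freq = config.pinned_lf_freq
        else:
            lf_freq = statistics.median(
                spectra[s.hair_id]["lf_peak_rad"]
                for s in study.cases if s.size_class is SizeClass.LONG
            )
        # the contradiction uses the short/medium width if available
        # (conservative: smallest counterfactual growth), else the long one
        cf_width = per_class.get(SizeClass.SHORT_MEDIUM, (mean_width,))[0]
        assignment = chron.assign_periodicities(
            hf_freq=hf_freq, lf_freq=lf_freq, ri_mean_mm=cf_width,
            remnant_len_mm=mean_len,
            annual_plausibility_mm=config.annual_plausibility_mm,
            weekly_ratio_window=config.weekly_ratio_window,
        )
        out["mean_long_remnant_mm"] = mean_len
        out["periodicity"] = dataclasses.asdict(assignment)

    if study.case_remnants and rates:
        report = chron.elapsed_days(study.case_remnants, rates)
        out["elapsed_days"] = {
            "per_remnant": report.per_remnant_days,
            "min_days": report.min_days,
            "max_days": report.max_days,
            "headline_window_days": list(report.headline_window),
        }
        logger.info(
            "chronology: %.2f-%.2f days elapsed since cut (window %s)",
            report.min_days, report.max_days, report.headline_window,
        )
    return out


def _entropy_stage(study: StudyData, config: RunConfig) -> dict[str, Any]:
    lf, hf = _bands(config)
    out: dict[str, Any] = {}
    for group, series_list in (("case", study.cases), ("control", study.controls)):
        for s in series_list:
            entry: dict[str, Any] = {"group": group}
            for m in config.apen_m_values:
                res = ent.approximate_entropy(s, m=m, r_fraction=config.apen_r_fraction)
                entry[f"apen_widths_m{m}"] = res.value
            try:
                res = ent.apen_of_lfhf(
                    s, window=config.sliding_window, step=config.sliding_step,
                    m=config.apen_m_values[0],
                    r_fraction=config.apen_r_fraction, lf=lf, hf=hf,
                )
                entry["apen_lfhf"] = res.value
            except TrichronError as exc:
                entry["apen_lfhf"] = None
                entry["apen_lfhf_error"] = str(exc)
            if config.apen_sweep:
                entry["sweep"] = {
                    f"{r:.1f}": res.value
                    for r, res in ent.apen_sweep(
                        s, m=config.apen_m_values[0]
                    ).items()
                }
            out[s.hair_id] = entry
    logger.info("entropy computed for %d hairs", len(out))
    return out


def _comparisons_stage(
    study: StudyData, spectra: dict[str, Any], entropy: dict[str, Any],
    config: RunConfig,
) -> dict[str, Any]:
    if not study.cases or not study.controls:
        return {"note": "one group empty; no comparisons performed"}
    out: dict[str, Any] = {}
    comparisons = []

    def values(table: dict[str, Any], key: str, group: str) -> list[float]:
        return [
            row[key] for row in table.values()
            if row["group"] == group and row.get(key) is not None
        ]

    metric_sources = {
        "lfhf_ratio": (spectra, "lfhf_ratio"),
        "lf_variance": (spectra, "lf_variance_mm2"),
        "apen": (entropy, "apen_lfhf"),
    }
    for metric, (table, key) in metric_sources.items():
        ctrl = values(table, key, "control")
        case = values(table, key, "case")
        try:
            comparison = gs.compare_groups(
                ctrl, case, method=config.stats_method, metric=metric,
                seed=config.seed, n_permutations=config.stats_permutations,
            )
        except TrichronError as exc:
            out[metric] = {"error": str(exc)}
            continue
        comparisons.append(comparison)
        out[metric] = dataclasses.asdict(comparison)
    if config.stats_holm and comparisons:
        out["holm_adjusted_p"] = gs.holm_adjust(comparisons)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write the report; returns the report dict.

    On a stage failure the partial report (with an ``error`` section) is
    still written before the exception propagates.
    """
    logging.basicConfig(level=config.log_level)
    logger.info("pipeline start: mode=%s seed=%d", config.mode, config.seed)
    results: dict[str, Any] = {
        "run": {
            "mode": config.mode,
            "seed": config.seed,
            "preset": config.preset,
            "input": config.ri_csv,
        }
    }
    try:
        study = _load_study(config)
        results["run"]["n_case_observations"] = study.n_case_observations
        results["run"]["n_control_observations"] = study.n_control_observations
        spectra = _spectra_stage(study, config)
        results["spectra"] = spectra
        results["chronology"] = _chronology_stage(study, spectra, config)
        entropy = _entropy_stage(study, config)
        results["entropy"] = entropy
        results["comparisons"] = _comparisons_stage(study, spectra, entropy, config)
    except TrichronError as exc:
        results["error"] = {"stage_error": str(exc), "type": type(exc).__name__}
        write_report(results, config.out, format=config.format)
        raise
    write_report(results, config.out, format=config.format)
    logger.info("report written to %s", config.out)
    return results
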