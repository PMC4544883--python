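"""Run configuration for the end-to-end pipeline.

A :class:`RunConfig` can be built directly, from a nested dict, or from a
YAML file.  Exactly one input source must be given: measured CSV files
(``ri_csv`` + ``remnants_csv``) or a synthetic preset name.  Two run
modes exist:

``paper_pinned``
    Mean RI widths and peak frequencies are taken from the configured
    reference constants (0.132 / 0.214 mm; 0.32 and 0.045 rad/RI), so a
    run reproduces the reference arithmetic chain exactly.
``empirical``
    All quantities are estimated from the input series themselves.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .ri_data import DEFAULT_RI_MEAN_MM


@dataclasses.dataclass
class RunConfig:
    # input: exactly one of (ri_csv [+ remnants_csv]) or preset
    ri_csv: str | None = None
    remnants_csv: str | None = None
    preset: str | None = None

    mode: str = "paper_pinned"  # or "empirical"
    seed: int = 0
    out: str = "trichron_report.json"
    format: str = "json"
    log_level: str = "INFO"

    # spectral
    lf_lo: float = 0.0
    lf_hi: float = 0.15
    hf_lo: float = 0.15
    hf_hi: float = math.pi
    detrend: bool = False
    sliding_window: int = 48
    sliding_step: int = 1

    # chronology
    days_per_year: float = 365.0
    ri_mean_short_medium: float = DEFAULT_RI_MEAN_MM["short_medium"]
    ri_mean_long: float = DEFAULT_RI_MEAN_MM["long"]
    pinned_hf_freq: float = 0.32
    pinned_lf_freq: float = 0.045
    weekly_ratio_window: tuple[float, float] = (5.0, 9.0)
    annual_plausibility_mm: float = 20.0

    # entropy
    apen_m_values: tuple[int, ...] = (2, 3)
    apen_r_fraction: float = 0.8
    apen_sweep: bool = False

    # statistics
    stats_method: str = "mann_whitney"
    stats_permutations: int = 10_000
    stats_holm: bool = False

    def __post_init__(self) -> None:
        has_files = self.ri_csv is not None
        has_preset = self.preset is not None
        if has_files == has_preset:
            raise ConfigurationError(
                "exactly one of input files (ri_csv) or a synthetic preset "
                "must be specified"
            )
        if self.mode not in ("paper_pinned", "empirical"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.format not in ("json", "csv"):
            raise ConfigurationError(f"unknown report format {self.format!r}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        """Build from a nested mapping (as parsed from YAML).

        Recognised groups: top-level keys plus ``bands.lf/hf.lo/hi``,
        ``sliding.window/step``, ``chronology.*``, ``apen.*``, ``stats.*``.
        """
        flat: dict[str, Any] = {}
        mapping = {
            ("bands", "lf", "lo"): "lf_lo",
            ("bands", "lf", "hi"): "lf_hi",
            ("bands", "hf", "lo"): "hf_lo",
            ("bands", "hf", "hi"): "hf_hi",
            ("sliding", "window"): "sliding_window",
            ("sliding", "step"): "sliding_step",
            ("chronology", "days_per_year"): "days_per_year",
            ("chronology", "ri_mean", "short_medium"): "ri_mean_short_medium",
            ("chronology", "ri_mean", "long"): "ri_mean_long",
            ("chronology", "pinned_hf_freq"): "pinned_hf_freq",
            ("chronology", "pinned_lf_freq"): "pinned_lf_freq",
            ("chronology", "weekly_ratio_window"): "weekly_ratio_window",
            ("chronology", "annual_plausibility_mm"): "annual_plausibility_mm",
            ("apen", "m_values"): "apen_m_values",
            ("apen", "r_fraction"): "apen_r_fraction",
            ("apen", "sweep"): "apen_sweep",
            ("stats", "method"): "stats_method",
            ("stats", "permutations"): "stats_permutations",
            ("stats", "holm"): "stats_holm",
        }

        def walk(prefix: tuple[str, ...], obj: Any) -> None:
            if isinstance(obj, Mapping):
                for k, v in obj.items():
                    walk(prefix + (str(k),), v)
            else:
                if prefix in mapping:
                    flat[mapping[prefix]] = obj
                elif len(prefix) == 1:
                    flat[prefix[0]] = obj
                else:
                    raise ConfigurationError(
                        f"unknown config key {'.'.join(prefix)!r}"
                    )

        walk((), data)
        field_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - field_names
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("weekly_ratio_window", "apen_m_values"):
            if key in flat and isinstance(flat[key], list):
                flat[key] = tuple(flat[key])
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
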