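"""Synthetic RI series with the rhythmic structure the analysis assumes.

Each generated series is a positive-mean pair of sinusoids plus Gaussian
noise:

    width_t = mean + A_d sin(f_d t + phi_d) + A_w sin(f_w t + phi_w) + eps_t

with a daily (high-frequency) component near 0.32 rad/RI, a weekly
(low-frequency) component near 0.045 rad/RI, and iid Gaussian noise.
Draws that land non-positive are redrawn (rejection truncation), which
preserves strict positivity without materially distorting the spectrum at
the default signal-to-noise ratio.  Phases default to seeded-random per
hair — they are unobserved in real hair, so randomising them is the
honest null.

Presets mirror the reference study's geometry: mean widths of 0.132 mm
(short/medium class) and 0.214 mm (long class), six case hairs whose
observation counts are proportional to the six remnant lengths (504
observations in total), and four control hairs of equal length (212 in
total).  Amplitudes and noise are stated assumptions, not measured
values: the default daily amplitude is twice the noise SD.  The
``sympathetic_activation`` preset doubles the weekly (LF) amplitude and
scales noise by 1.5 relative to ``control``, constructing the direction —
not the magnitude — of an elevated-sympathetic-drive contrast.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import ConfigurationError, DomainError
from .ri_data import (
    HairRemnant,
    RISeries,
    SizeClass,
    Source,
    StudyData,
    load_reference_remnants,
)

DEFAULT_DAILY_FREQ = 0.32  # rad/RI
DEFAULT_WEEKLY_FREQ = 0.045  # rad/RI

#: Study geometry of the reference dataset: total observation counts.
CONTROL_HAIRS = 4
CONTROL_TOTAL_OBS = 212
CASE_TOTAL_OBS = 504


@dataclasses.dataclass(frozen=True)
class SyntheticParams:
    """Parameters of one synthetic RI series."""

    n: int = 128
    mean_width: float = 0.132  # mm
    daily_freq: float = DEFAULT_DAILY_FREQ  # rad/RI
    daily_amp: float = 0.04  # mm
    weekly_freq: float = DEFAULT_WEEKLY_FREQ  # rad/RI
    weekly_amp: float = 0.02  # mm
    noise_sd: float = 0.02  # mm
    phase_daily: float | None = None  # radians; None -> seeded-random
    phase_weekly: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if self.mean_width <= 0:
            raise DomainError(f"mean_width must be positive, got {self.mean_width}")
        if self.daily_amp < 0 or self.weekly_amp < 0 or self.noise_sd < 0:
            raise DomainError("amplitudes and noise_sd must be non-negative")
        if not (0 < self.weekly_freq < self.daily_freq <= math.pi):
            raise DomainError(
                f"need 0 < weekly_freq < daily_freq <= pi, got "
                f"{self.weekly_freq}, {self.daily_freq}"
            )


def generate_ri_series(
    params: SyntheticParams,
    hair_id: str = "synthetic",
    size_class: SizeClass | str = SizeClass.SHORT_MEDIUM,
    rng: np.random.Generator | None = None,
) -> RISeries:
    """Generate one RI series from ``params``; deterministic for a fixed seed.

    Noise draws producing a non-positive width are redrawn at that
    position until positive (rejection truncation).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = np.arange(params.n, dtype=float)
    phase_d = rng.uniform(0, 2 * math.pi) if params.phase_daily is None else params.phase_daily
    phase_w = rng.uniform(0, 2 * math.pi) if params.phase_weekly is None else params.phase_weekly
    signal = (
        params.mean_width
        + params.daily_amp * np.sin(params.daily_freq * t + phase_d)
        + params.weekly_amp * np.sin(params.weekly_freq * t + phase_w)
    )
    if params.noise_sd > 0:
        widths = signal + rng.normal(0.0, params.noise_sd, size=params.n)
        bad = widths <= 0
        while bad.any():  # rejection truncation at zero
            widths[bad] = signal[bad] + rng.normal(0.0, params.noise_sd, size=int(bad.sum()))
            bad = widths <= 0
    else:
        widths = signal
        if np.any(widths <= 0):
            raise DomainError(
                "noiseless parameter set produces non-positive widths; "
                "reduce amplitudes or raise mean_width"
            )
    return RISeries(
        hair_id=hair_id,
        size_class=SizeClass.coerce(size_class),
        widths=widths,
        source=Source.SYNTHETIC,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("control", "zweeloo_short", "zweeloo_long", "sympathetic_activation")


def preset_params(name: str, n: int = 128, seed: int | None = None) -> SyntheticParams:
    """Named parameter presets.

    ``control``: short/medium geometry with baseline amplitudes.
    ``zweeloo_short`` / ``zweeloo_long``: the reference specimen's class
    mean widths (0.132 / 0.214 mm), baseline amplitudes scaled with the
    mean.  ``sympathetic_activation``: ``control`` with weekly (LF)
    amplitude doubled and noise SD scaled by 1.5.
    """
    base = dict(n=n, seed=seed, daily_amp=0.04, weekly_amp=0.02, noise_sd=0.02)
    if name == "control":
        return SyntheticParams(mean_width=0.132, **base)
    if name == "zweeloo_short":
        return SyntheticParams(mean_width=0.132, **base)
    if name == "zweeloo_long":
        # amplitudes scale with the wider RIs of the long class
        return SyntheticParams(
            n=n, seed=seed, mean_width=0.214,
            daily_amp=0.065, weekly_amp=0.032, noise_sd=0.0325,
        )
    if name == "sympathetic_activation":
        return SyntheticParams(
            n=n, seed=seed, mean_width=0.132,
            daily_amp=0.04, weekly_amp=0.04, noise_sd=0.03,
        )
    raise ConfigurationError(
        f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
    )


def _partition_proportional(total: int, weights: np.ndarray) -> np.ndarray:
    """Split ``total`` into integers proportional to ``weights``
    (largest-remainder rounding)."""
    quotas = total * weights / weights.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder < 0 or remainder > len(counts):
        raise ConfigurationError("cannot partition counts")
    order = np.argsort(-(quotas - counts))
    counts[order[:remainder]] += 1
    return counts


def generate_study(
    seed: int | None = None,
    case_preset: str = "sympathetic_activation",
    control_preset: str = "control",
    n_control_hairs: int = CONTROL_HAIRS,
    control_total_obs: int = CONTROL_TOTAL_OBS,
    case_total_obs: int = CASE_TOTAL_OBS,
    remnants: list[HairRemnant] | None = None,
) -> StudyData:
    """Generate a full case/control study with the reference geometry.

    Defaults: 4 control hairs totalling 212 observations (equal split),
    and 6 case hairs whose observation counts are proportional to the six
    reference remnant lengths, totalling 504.  Case hairs of the long
    class use the long-class mean width (0.214 mm); case LF amplitude and
    noise follow ``case_preset``.
    """
    if n_control_hairs < 1:
        raise ConfigurationError("need at least one control hair")
    rng = np.random.default_rng(seed)
    if remnants is None:
        remnants = load_reference_remnants()

    lengths = np.array([r.length_mm for r in remnants])
    case_counts = _partition_proportional(case_total_obs, lengths)
    ctrl_counts = _partition_proportional(
        control_total_obs, np.ones(n_control_hairs)
    )

    case_base = preset_params(case_preset)
    baseline = preset_params("control")
    long_base = preset_params("zweeloo_long")
    cases = []
    for remnant, n_obs in zip(remnants, case_counts):
        if remnant.size_class is SizeClass.LONG:
            params = dataclasses.replace(
                long_base,
                n=int(n_obs),
                # carry the case preset's LF elevation into the long class
                weekly_amp=long_base.weekly_amp * case_base.weekly_amp / baseline.weekly_amp,
                noise_sd=long_base.noise_sd * case_base.noise_sd / baseline.noise_sd,
            )
        else:
            params = dataclasses.replace(case_base, n=int(n_obs))
        cases.append(
            generate_ri_series(params, hair_id=remnant.hair_id,
                               size_class=remnant.size_class, rng=rng)
        )

    ctrl_params = preset_params(control_preset)
    controls = [
        generate_ri_series(
            dataclasses.replace(ctrl_params, n=int(n_obs)),
            hair_id=f"C{i + 1}",
            size_class=SizeClass.SHORT_MEDIUM,
            rng=rng,
        )
        for i, n_obs in enumerate(ctrl_counts)
    ]
    return StudyData(
        cases=cases,
        case_remnants=list(remnants),
        controls=controls,
        provenance=(
            f"synthetic study: case_preset={case_preset}, "
            f"control_preset={control_preset}, seed={seed}"
        ),
    )
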