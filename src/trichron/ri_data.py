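"""Domain types and file I/O for repeat-interval (RI) width series.

A repeat interval is the width, in millimetres, of one scale-like
growth/quiescence band on a hair shaft.  Ordered along the shaft, those
widths form the fundamental time series of the package: one observation
per RI, with "time" measured in observations.  This module defines the
containers (:class:`RISeries`, :class:`HairRemnant`, :class:`StudyData`),
the CSV interchange formats, the machine-readable report writer, and the
packaged reference fixture of cropped-remnant lengths.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    ValidationError,
)

#: Minimum series length accepted by spectral / entropy operations.
MIN_ANALYSIS_LENGTH = 8

#: Schema version stamped into every report.
REPORT_SCHEMA_VERSION = "1.0"

#: Default mean RI width (mm per observation) by hair size class.  These
#: drive the growth-rate formula in "pinned" runs and are configuration,
#: not constants baked into any operation.
DEFAULT_RI_MEAN_MM = {"short_medium": 0.132, "long": 0.214}


class SizeClass(str, enum.Enum):
    """Hair remnant size class; the two classes have distinct mean RI widths."""

    SHORT_MEDIUM = "short_medium"
    LONG = "long"

    @classmethod
    def coerce(cls, value: "SizeClass | str") -> "SizeClass":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(
                f"unknown size_class {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


class Source(str, enum.Enum):
    """Provenance of a series: microscope-measured or generated."""

    MEASURED = "measured"
    SYNTHETIC = "synthetic"


@dataclasses.dataclass(frozen=True)
class RISeries:
    """Ordered RI widths (mm) along one hair.

    Widths must be strictly positive and finite.  Short series (< 8
    observations) are representable — they only fail when handed to a
    spectral or entropy operation, which is where the length requirement
    actually bites.
    """

    hair_id: str
    size_class: SizeClass
    widths: np.ndarray
    source: Source = Source.MEASURED

    def __post_init__(self) -> None:
        widths = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "size_class", SizeClass.coerce(self.size_class))
        object.__setattr__(self, "source", Source(self.source))
        if widths.ndim != 1:
            raise ValidationError(f"hair {self.hair_id!r}: widths must be 1-D")
        if not np.all(np.isfinite(widths)):
            raise ValidationError(f"hair {self.hair_id!r}: non-finite width")
        if np.any(widths <= 0):
            bad = int(np.argmax(widths <= 0))
            raise ValidationError(
                f"hair {self.hair_id!r}: non-positive width at position {bad}"
            )

    def __len__(self) -> int:
        return self.widths.size

    @property
    def mean_width(self) -> float:
        return float(self.widths.mean())


@dataclasses.dataclass(frozen=True)
class HairRemnant:
    """A cropped hair remnant: its measured length and size class."""

    hair_id: str
    length_mm: float
    size_class: SizeClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_class", SizeClass.coerce(self.size_class))
        if not (np.isfinite(self.length_mm) and self.length_mm > 0):
            raise ValidationError(
                f"remnant {self.hair_id!r}: length_mm must be positive, "
                f"got {self.length_mm}"
            )


@dataclasses.dataclass
class StudyData:
    """A case/control study: case series with remnants, and control series."""

    cases: list[RISeries]
    case_remnants: list[HairRemnant]
    controls: list[RISeries]
    provenance: str = ""

    @property
    def n_case_observations(self) -> int:
        return sum(len(s) for s in self.cases)

    @property
    def n_control_observations(self) -> int:
        return sum(len(s) for s in self.controls)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_RI_COLUMNS = ["hair_id", "size_class", "position_index", "width_mm"]
_REMNANT_COLUMNS = ["hair_id", "size_class", "length_mm"]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if frame.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return frame


def read_ri_csv(path: str | Path) -> list[RISeries]:
    """Read RI series from CSV (columns hair_id, size_class, position_index,
    width_mm), one :class:`RISeries` per hair ordered by position_index."""
    frame = _read_table(path, _RI_COLUMNS)
    bad = frame[~(frame["width_mm"] > 0) | ~np.isfinite(frame["width_mm"])]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"{path}: non-positive or non-finite width_mm for hair "
            f"{row['hair_id']!r} at row {int(bad.index[0]) + 2}"
        )
    series = []
    for hair_id, group in frame.groupby("hair_id", sort=False):
        group = group.sort_values("position_index")
        classes = group["size_class"].unique()
        if len(classes) != 1:
            raise ValidationError(
                f"{path}: hair {hair_id!r} has inconsistent size_class values"
            )
        series.append(
            RISeries(
                hair_id=str(hair_id),
                size_class=SizeClass.coerce(classes[0]),
                widths=group["width_mm"].to_numpy(dtype=float),
            )
        )
    return series


def write_ri_csv(series: Iterable[RISeries], path: str | Path) -> Path:
    """Write RI series to the interchange CSV; inverse of :func:`read_ri_csv`."""
    path = Path(path)
    rows = []
    for s in series:
        for i, w in enumerate(s.widths):
            rows.append(
                {
                    "hair_id": s.hair_id,
                    "size_class": s.size_class.value,
                    "position_index": i,
                    "width_mm": repr(float(w)),
                }
            )
    pd.DataFrame(rows, columns=_RI_COLUMNS).to_csv(path, index=False)
    return path


def read_remnants_csv(path: str | Path) -> list[HairRemnant]:
    """Read remnant records from CSV (columns hair_id, size_class, length_mm)."""
    frame = _read_table(path, _REMNANT_COLUMNS)
    return [
        HairRemnant(
            hair_id=str(row.hair_id),
            length_mm=float(row.length_mm),
            size_class=SizeClass.coerce(row.size_class),
        )
        for row in frame.itertuples()
    ]


def write_remnants_csv(remnants: Iterable[HairRemnant], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "hair_id": r.hair_id,
                "size_class": r.size_class.value,
                "length_mm": r.length_mm,
            }
            for r in remnants
        ],
        columns=_REMNANT_COLUMNS,
    ).to_csv(path, index=False)
    return path


def load_reference_remnants() -> list[HairRemnant]:
    """The six cropped scalp-hair remnants of the reference specimen.

    Lengths 10.4, 9.1, 11.4, 12.2 mm (short/medium) and 17.9, 16.8 mm
    (long); these lengths anchor the elapsed-time reconstruction.
    """
    with resources.as_file(
        resources.files("trichron") / "data" / "zweeloo_remnants.csv"
    ) as path:
        return read_remnants_csv(path)


# ---------------------------------------------------------------------------
# Report writer
# ---------------------------------------------------------------------------

_REPORT_SECTIONS = (
    "spectra",
    "chronology",
    "entropy",
    "comparisons",
)


def _to_jsonable(obj):
    if isinstance(obj, enum.Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(
    results: Mapping[str, object],
    path: str | Path,
    format: str = "json",
) -> Path:
    """Write a machine-readable analysis report.

    ``results`` maps section names (``spectra``, ``chronology``, ``entropy``,
    ``comparisons``, plus free-form extras such as ``run``) to
    JSON-serialisable payloads.  JSON output nests by section; CSV output
    writes one flat table per section into ``<stem>_<section>.csv`` plus a
    manifest at ``path``.  Sections absent from ``results`` appear empty, so
    the schema is stable across partial runs.
    """
    path = Path(path)
    payload = {"schema_version": REPORT_SCHEMA_VERSION}
    for section in _REPORT_SECTIONS:
        payload[section] = _to_jsonable(results.get(section, {}))
    for key, value in results.items():
        if key not in _REPORT_SECTIONS:
            payload[key] = _to_jsonable(value)

    if format == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path
    if format == "csv":
        manifest = [["section", "file"]]
        for section in _REPORT_SECTIONS:
            table = _flatten_section(payload[section])
            section_path = path.with_name(f"{path.stem}_{section}.csv")
            with open(section_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerows(table)
            manifest.append([section, section_path.name])
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["schema_version", REPORT_SCHEMA_VERSION])
            writer.writerows(manifest)
        return path
    raise ValueError(f"unknown report format {format!r}")


def _flatten_section(section) -> list[list]:
    """Flatten a (possibly nested) section into one rectangular table."""
    rows = []

    def walk(prefix: str, obj):
        if isinstance(obj, Mapping):
            for k, v in obj.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(obj, list):
            for i, v in enumerate(obj):
                walk(f"{prefix}[{i}]", v)
        else:
            rows.append([prefix, obj])

    walk("", section)
    return [["key", "value"]] + rows
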