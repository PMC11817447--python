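"""Functional ontology and gain-matrix construction.

The regulatory network is described by 14 "factors": seven functional
categories of molecular mechanism (apoptosis, bioenergetics, chemistry,
excitotoxicity, inflammation, oxidative stress, proteomics), each split
into a positively and a negatively regulated subcategory.  Literature
measurements (treated vs. control assay values over a study duration)
are converted to per-day feedback gains and aggregated into a 14x14
gain matrix, entry (target, source) being the per-day influence of the
source factor on the target factor.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalCategory",
    "Polarity",
    "Factor",
    "MeasurementRecord",
    "GainMatrix",
    "InvalidRecordError",
    "MissingEntryError",
    "IncompleteMatrixError",
    "GAIN_TIME_CONSTANT",
    "N_FACTORS",
    "list_factors",
    "factor_by_name",
    "factor_by_index",
    "compute_gain",
    "aggregate_gains",
    "build_gain_matrix",
    "read_records_csv",
    "write_records_csv",
]


class InvalidRecordError(ValueError):
    """A measurement record violates its preconditions."""


class MissingEntryError(ValueError):
    """A gain-matrix entry has no supporting measurements."""


class IncompleteMatrixError(ValueError):
    """An operation requiring a complete gain matrix received missing entries."""


class FunctionalCategory(enum.Enum):
    """The seven functional categories of the ontology."""

    APOPTOSIS = "apoptosis"
    BIOENERGETICS = "bioenergetics"
    CHEMISTRY = "chemistry"
    EXCITOTOXICITY = "excitotoxicity"
    INFLAMMATION = "inflammation"
    OXIDATIVE_STRESS = "oxidative_stress"
    PROTEOMICS = "proteomics"


class Polarity(enum.Enum):
    """Regulatory direction of a subcategory (e.g. pro- vs anti-apoptotic)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class Factor:
    """One of the 14 signed subcategories serving as an ODE state variable."""

    category: FunctionalCategory
    polarity: Polarity
    index: int

    @property
    def name(self) -> str:
        return f"{self.category.value}:{self.polarity.value}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _build_factors() -> tuple[Factor, ...]:
    factors = []
    for cat in FunctionalCategory:
        for pol in (Polarity.POSITIVE, Polarity.NEGATIVE):
            factors.append(Factor(cat, pol, len(factors)))
    return tuple(factors)


#: Canonical factor ordering: categories alphabetically, positive before
#: negative within each category.  Fixed so matrices are comparable across
#: runs and file formats.
FACTORS: tuple[Factor, ...] = _build_factors()
N_FACTORS: int = len(FACTORS)

_BY_NAME = {f.name: f for f in FACTORS}

#: Time constant (days) in the gain formula: a measured treated/control
#: ratio over a study of D days is converted to a per-day gain as
#: ``(3 / D) * (treated/control - 1)``.
GAIN_TIME_CONSTANT: float = 3.0


def list_factors() -> tuple[Factor, ...]:
    """Return the 14 canonical factors in their fixed documented order."""
    return FACTORS


def factor_by_name(name: str) -> Factor:
    """Look up a factor from its ``category:polarity`` string."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown factor {name!r}; expected one of {sorted(_BY_NAME)}"
        ) from None


def factor_by_index(index: int) -> Factor:
    return FACTORS[index]


@dataclass(frozen=True)
class MeasurementRecord:
    """A single literature measurement of one factor's effect on another.

    ``treated`` and ``control`` are assay values in arbitrary (but shared)
    units; ``duration_days`` is the study duration.  Records describe the
    effect of ``source_factor`` on ``target_factor`` (rows of the gain
    matrix are target-major).
    """

    measurement_id: str
    source_factor: Factor
    target_factor: Factor
    treated: float
    control: float
    duration_days: int
    confidence: str = "medium"

    def __post_init__(self) -> None:
        if self.confidence not in ("high", "medium", "low"):
            raise InvalidRecordError(
                f"record {self.measurement_id}: confidence must be "
                f"high/medium/low, got {self.confidence!r}"
            )


def compute_gain(
    treated: float,
    control: float,
    duration_days: float,
    record_id: str | None = None,
) -> float:
    """Per-day gain from a treated/control ratio over a study duration.

    ``gain = (3 / duration_days) * (treated / control - 1)`` in day^-1.
    A ratio of 1 (no effect) maps to zero gain under any duration.
    """
    label = f" (record {record_id})" if record_id else ""
    if not control > 0:
        raise InvalidRecordError(f"control must be positive{label}: {control}")
    if not duration_days >= 1:
        raise InvalidRecordError(
            f"duration_days must be >= 1{label}: {duration_days}"
        )
    return (GAIN_TIME_CONSTANT / duration_days) * (treated / control - 1.0)


def aggregate_gains(gains: Sequence[float]) -> float:
    """Combine several per-day gains for one matrix entry.

    Uses the unweighted arithmetic mean.  Confidence labels are carried on
    records but not used as weights.  An empty sequence signals a missing
    entry rather than a zero gain.
    """
    if len(gains) == 0:
        raise MissingEntryError("no gains to aggregate: entry is missing")
    return float(np.mean(gains))


_PROVENANCE_VALUES = ("measured", "optimized", "missing")


@dataclass
class GainMatrix:
    """14x14 per-day gain matrix with per-entry provenance.

    ``values[t, s]`` is the per-day influence (day^-1) of source factor
    ``s`` on target factor ``t``.  ``provenance`` entries are one of
    ``"measured"``, ``"optimized"`` or ``"missing"``; values are undefined
    (NaN) wherever provenance is missing.
    """

    values: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = N_FACTORS
        if self.values.shape != (n, n):
            raise ValueError(f"gain matrix must be {n}x{n}, got {self.values.shape}")
        if self.provenance is None:
            self.provenance = np.full((n, n), "measured", dtype="<U9")
        else:
            self.provenance = np.asarray(self.provenance, dtype="<U9")
            if self.provenance.shape != (n, n):
                raise ValueError("provenance shape must match values")
        bad = set(np.unique(self.provenance)) - set(_PROVENANCE_VALUES)
        if bad:
            raise ValueError(f"unknown provenance labels: {sorted(bad)}")
        known = self.provenance != "missing"
        if not np.all(np.isfinite(self.values[known])):
            raise ValueError("non-finite gain in a measured/optimized entry")

    @property
    def missing_mask(self) -> np.ndarray:
        return self.provenance == "missing"

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def require_complete(self) -> np.ndarray:
        if not self.is_complete:
            k = int(self.missing_mask.sum())
            raise IncompleteMatrixError(
                f"gain matrix has {k} missing entries; complete it first"
            )
        return self.values

    def copy(self) -> "GainMatrix":
        return GainMatrix(self.values.copy(), self.provenance.copy())

    # ---- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "factors": [f.name for f in FACTORS],
            "orientation": "rows are targets, columns are sources",
            "values": [
                [None if m else v for v, m in zip(row, mrow)]
                for row, mrow in zip(self.values.tolist(), self.missing_mask.tolist())
            ],
            "provenance": self.provenance.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GainMatrix":
        obj = json.loads(Path(path).read_text())
        if obj["factors"] != [f.name for f in FACTORS]:
            raise ValueError("factor ordering in file does not match ontology")
        values = np.array(
            [[np.nan if v is None else v for v in row] for row in obj["values"]],
            dtype=float,
        )
        return cls(values, np.array(obj["provenance"]))

    def to_csv(self, path: str | Path) -> None:
        names = [f.name for f in FACTORS]
        pd.DataFrame(self.values, index=names, columns=names).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GainMatrix":
        df = pd.read_csv(path, index_col=0)
        names = [f.name for f in FACTORS]
        df = df.loc[names, names]
        values = df.to_numpy(dtype=float)
        prov = np.where(np.isnan(values), "missing", "measured")
        return cls(values, prov)


def build_gain_matrix(records: Iterable[MeasurementRecord]) -> GainMatrix:
    """Aggregate measurement records into a partially observed gain matrix.

    Entry (target, source) is the mean per-day gain over its records and is
    marked ``measured``; entries with no supporting records are ``missing``
    with NaN values.
    """
    n = N_FACTORS
    buckets: dict[tuple[int, int], list[float]] = {}
    for rec in records:
        if rec.source_factor not in FACTORS or rec.target_factor not in FACTORS:
            raise InvalidRecordError(
                f"record {rec.measurement_id} references unknown factor"
            )
        g = compute_gain(rec.treated, rec.control, rec.duration_days, rec.measurement_id)
        key = (rec.target_factor.index, rec.source_factor.index)
        buckets.setdefault(key, []).append(g)

    values = np.full((n, n), np.nan)
    prov = np.full((n, n), "missing", dtype="<U9")
    for (t, s), gains in buckets.items():
        values[t, s] = aggregate_gains(gains)
        prov[t, s] = "measured"
    return GainMatrix(values, prov)


_RECORD_COLUMNS = [
    "measurement_id",
    "source_factor",
    "target_factor",
    "treated",
    "control",
    "duration_days",
    "confidence",
]


def write_records_csv(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write measurement records as CSV (factors as category:polarity strings)."""
    rows = [
        {
            "measurement_id": r.measurement_id,
            "source_factor": r.source_factor.name,
            "target_factor": r.target_factor.name,
            "treated": r.treated,
            "control": r.control,
            "duration_days": r.duration_days,
            "confidence": r.confidence,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_records_csv(path: str | Path) -> list[MeasurementRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(_RECORD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"records CSV lacks columns: {sorted(missing_cols)}")
    return [
        MeasurementRecord(
            measurement_id=str(row.measurement_id),
            source_factor=factor_by_name(row.source_factor),
            target_factor=factor_by_name(row.target_factor),
            treated=float(row.treated),
            control=float(row.control),
            duration_days=int(row.duration_days),
            confidence=str(row.confidence),
        )
        for row in df.itertuples()
    ]
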