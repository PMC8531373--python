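"""Martin-system cranial measurements and the craniometric data model.

Linear cranial measurements are identified by their number in Martin's
osteometric system (``M1`` = maximum cranial length, ``M17`` =
basion-bregma height, and so on); all values are in millimetres.  The
analysis battery used throughout this package is the set of 13
measurements that are most consistently observable on fragmentary
crania; it covers vault length/breadth/height, facial breadths and
heights, and orbital and nasal dimensions.

Two kinds of record exist: :class:`CranialSpecimen` holds one
individual's measurements with per-value provenance flags (observed /
estimated / missing), and :class:`PopulationSample` holds a named
group's per-measurement summary (n, mean, SD).  Estimated values are
measurements a source reconstructed (printed in parentheses in the
original tables); they participate in aggregation and all downstream
computation unless explicitly excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "BATTERY_13",
    "MARTIN_LABELS",
    "Flag",
    "CranialSpecimen",
    "PopulationSample",
    "RegressionImputer",
    "M17_IMPUTER",
    "impute_m17",
    "aggregate_specimens",
]

#: Human-readable names of the Martin measurements handled here.
MARTIN_LABELS: dict[str, str] = {
    "M1": "Maximum cranial length",
    "M8": "Maximum cranial breadth",
    "M9": "Minimum frontal breadth",
    "M10": "Maximum frontal breadth",
    "M17": "Basion-bregma height",
    "M43": "Upper facial breadth",
    "M45": "Bizygomatic breadth",
    "M46": "Bimaxillary breadth",
    "M48": "Upper facial height",
    "M51": "Orbital breadth",
    "M52": "Orbital height",
    "M54": "Nasal breadth",
    "M55": "Nasal height",
    # auricular-basion height; not part of the battery, used as the
    # predictor for regression imputation of M17
    "ABH": "Auricular-basion height",
}

#: The canonical 13-measurement analysis battery, in Martin-number order.
BATTERY_13: tuple[str, ...] = (
    "M1", "M8", "M9", "M10", "M17", "M43", "M45",
    "M46", "M48", "M51", "M52", "M54", "M55",
)

# plausibility guard for any linear cranial measurement, in mm
_MIN_MM = 0.0
_MAX_MM = 300.0


class Flag(str, Enum):
    """Provenance of a single measurement value."""

    OBSERVED = "observed"
    ESTIMATED = "estimated"
    MISSING = "missing"


@dataclass
class CranialSpecimen:
    """One individual's cranial measurements.

    Parameters
    ----------
    specimen_id
        Unique identifier (burial or catalogue number).
    site
        Site or locality name.
    sex_label
        Free-text sex assessment (e.g. ``"F"``).
    values
        Mapping of Martin code to measurement in mm.  Codes absent from
        the mapping are missing.
    flags
        Mapping of Martin code to :class:`Flag`.  Codes present in
        ``values`` default to ``OBSERVED``.
    """

    specimen_id: str
    site: str
    sex_label: str = ""
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, Flag] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, v in self.values.items():
            if not (_MIN_MM < v < _MAX_MM):
                raise ValueError(
                    f"specimen {self.specimen_id!r}: {code} = {v} mm is outside "
                    f"the plausible range ({_MIN_MM}, {_MAX_MM})"
                )
            self.flags.setdefault(code, Flag.OBSERVED)
        for code, f in self.flags.items():
            f = Flag(f)
            self.flags[code] = f
            if f is Flag.MISSING and code in self.values:
                raise ValueError(
                    f"specimen {self.specimen_id!r}: {code} flagged missing but has a value"
                )
            if f is not Flag.MISSING and code not in self.values:
                raise ValueError(
                    f"specimen {self.specimen_id!r}: {code} flagged {f.value} without a value"
                )

    def flag(self, code: str) -> Flag:
        return self.flags.get(code, Flag.MISSING)

    def measured_codes(self, include_estimated: bool = True) -> list[str]:
        """Codes with a usable value, in insertion order."""
        return [
            c for c in self.values
            if include_estimated or self.flags.get(c) is not Flag.ESTIMATED
        ]


@dataclass
class PopulationSample:
    """Per-measurement summary statistics for a named skeletal sample.

    ``stats`` maps a Martin code to a ``(n, mean, sd)`` triple; ``sd`` is
    ``None`` when ``n == 1`` (a single cranium carries no dispersion
    information).
    """

    sample_id: str
    group_tag: str = ""
    stats: dict[str, tuple[int, float, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, (n, mean, sd) in self.stats.items():
            if n < 1:
                raise ValueError(f"sample {self.sample_id!r}: {code} has n = {n} < 1")
            if n == 1 and sd is not None:
                raise ValueError(
                    f"sample {self.sample_id!r}: {code} has n = 1 but an SD was given"
                )
            if sd is not None and sd < 0:
                raise ValueError(f"sample {self.sample_id!r}: {code} has negative SD")

    def n(self, code: str) -> int:
        return self.stats[code][0]

    def mean(self, code: str) -> float:
        return self.stats[code][1]

    def sd(self, code: str) -> float | None:
        return self.stats[code][2]

    @property
    def codes(self) -> list[str]:
        return list(self.stats)

    def has_battery(self, battery: Iterable[str] = BATTERY_13) -> bool:
        return all(c in self.stats for c in battery)


@dataclass(frozen=True)
class RegressionImputer:
    """Affine regression used to fill in a missing measurement.

    The packaged instance, :data:`M17_IMPUTER`, predicts basion-bregma
    height (M17) from auricular-basion height (ABH) via
    ``M17 = 1.05 * ABH + 14.26`` — a regression fitted on 24 female
    crania with both measurements preserved.  The full-precision value
    is retained internally; sources conventionally round to whole mm
    for display.
    """

    slope: float = 1.05
    intercept: float = 14.26
    predictor_code: str = "ABH"
    target_code: str = "M17"

    def __call__(self, predictor_mm: float) -> float:
        if not predictor_mm > 0:
            raise ValueError(
                f"{self.predictor_code} must be positive, got {predictor_mm}"
            )
        return self.slope * predictor_mm + self.intercept


#: The packaged M17-from-ABH imputer.
M17_IMPUTER = RegressionImputer()


def impute_m17(abh_mm: float, imputer: RegressionImputer = M17_IMPUTER) -> float:
    """Predict basion-bregma height (mm) from auricular-basion height."""
    if imputer.target_code != "M17":
        raise ValueError("imputer does not target M17")
    return imputer(abh_mm)


def aggregate_specimens(
    specimens: Iterable[CranialSpecimen],
    sample_id: str,
    group_tag: str = "",
    include_estimated: bool = True,
) -> PopulationSample:
    """Summarise individual specimens into a :class:`PopulationSample`.

    Per measurement: ``n`` counts non-missing values, ``mean`` is the
    arithmetic mean, and ``sd`` is the sample standard deviation
    (``n - 1`` denominator) when ``n >= 2`` and absent when ``n == 1``.
    Estimated values are included by default, mirroring how the source
    tables fold reconstructed measurements into their summaries.
    """
    specimens = list(specimens)
    if not specimens:
        raise ValueError("aggregate_specimens needs at least one specimen")
    pooled: dict[str, list[float]] = {}
    for sp in specimens:
        for code in sp.measured_codes(include_estimated=include_estimated):
            pooled.setdefault(code, []).append(sp.values[code])
    stats: dict[str, tuple[int, float, float | None]] = {}
    for code, vals in pooled.items():
        n = len(vals)
        mean = sum(vals) / n
        if n >= 2:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        else:
            sd = None
        stats[code] = (n, mean, sd)
    return PopulationSample(sample_id=sample_id, group_tag=group_tag, stats=stats)
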