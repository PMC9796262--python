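"""Crown formation chronology from enamel incremental growth lines.

Enamel grows by daily appositional increments (cross-striations) whose
spacing along an enamel prism is the daily secretion rate (DSR, µm/day).
Longer-period accentuated lines (striae of Retzius) recur every *P* daily
increments; *P* is the periodicity and is taken as constant over crown
formation.  The crown formation time decomposes as

    T_total = T_cuspal + T_lateral
    T_cuspal  = cuspal enamel thickness / mean cuspal DSR
    T_lateral = T_deciles12 + sum over deciles 3..10 of (stria count x P)

where the crown height is split into ten deciles from cusp tip to cervix and
the first two deciles - where striae are hard to resolve - are timed by
dividing the prism-path length through them by the local DSR.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from statistics import fmean

import pandas as pd

__all__ = [
    "SpacingMeasurement",
    "DSRProfile",
    "RetziusRecord",
    "CrownChronology",
    "CuspalResult",
    "PeriodicityResult",
    "dsr_profile",
    "cuspal_time",
    "periodicity",
    "lateral_time",
    "total_crown_time",
    "spacing_table_to_measurements",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class SpacingMeasurement:
    """One spacing measurement: a span bridging n_crossings daily increments."""

    zone_index: int
    span_um: float
    n_crossings: int

    def __post_init__(self) -> None:
        if self.span_um <= 0:
            raise ValueError(f"span_um must be > 0, got {self.span_um}")
        if self.n_crossings < 3:
            raise ValueError(
                "spacing measurements must bridge at least three "
                f"cross-striations, got {self.n_crossings}"
            )

    @property
    def rate(self) -> float:
        return self.span_um / self.n_crossings


@dataclass(frozen=True)
class DSRProfile:
    """Per-zone daily secretion rates along a prism path, EDJ outward.

    zone_rates holds (zone_index, dsr_um_per_day, n_measurements) with
    contiguous zone indices starting at 0 (the zone touching the EDJ).
    """

    zone_width_um: float
    zone_rates: tuple[tuple[int, float, int], ...]

    def __post_init__(self) -> None:
        idx = [z for z, _, _ in self.zone_rates]
        if idx != list(range(len(idx))):
            raise ValueError(f"zone indices must be contiguous from 0, got {idx}")
        if any(r <= 0 for _, r, _ in self.zone_rates):
            raise ValueError("all zone rates must be > 0")

    @property
    def rates(self) -> list[float]:
        return [r for _, r, _ in self.zone_rates]

    @property
    def coverage_um(self) -> float:
        return self.zone_width_um * len(self.zone_rates)

    def mean_rate(self) -> float:
        if not self.zone_rates:
            raise ValueError("empty DSR profile")
        return fmean(self.rates)


@dataclass(frozen=True)
class RetziusRecord:
    """Stria periodicity and per-decile stria counts for the lateral enamel."""

    periodicity_days: int
    periodicity_counts: tuple[int, ...]
    decile_stria_counts: tuple[int, ...]
    deciles12_prism_length_um: float
    deciles12_local_dsr: float

    def __post_init__(self) -> None:
        if self.periodicity_days < 1:
            raise ValueError("periodicity must be >= 1 day")
        if not self.periodicity_counts:
            raise ValueError("periodicity_counts must be non-empty")
        if len(self.decile_stria_counts) != 10:
            raise ValueError("decile_stria_counts must have 10 entries")
        if any(c < 0 for c in self.decile_stria_counts):
            raise ValueError("stria counts must be non-negative")


@dataclass(frozen=True)
class CuspalResult:
    days: float
    mean_dsr: float

    @property
    def whole_days(self) -> int:
        return round(self.days)


@dataclass(frozen=True)
class PeriodicityResult:
    days: int
    counts: tuple[int, ...]
    unanimous: bool


@dataclass(frozen=True)
class CrownChronology:
    """Crown formation times in days; whole days at report level."""

    cuspal_days: int
    deciles12_days: int
    per_decile_days: tuple[int, ...]
    lateral_days: int = field(init=False)
    total_days: int = field(init=False)
    total_years: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.per_decile_days) != 10:
            raise ValueError("per_decile_days must have 10 entries")
        lateral = self.deciles12_days + sum(self.per_decile_days[2:])
        object.__setattr__(self, "lateral_days", lateral)
        object.__setattr__(self, "total_days", self.cuspal_days + lateral)
        object.__setattr__(
            self, "total_years", round(self.total_days / DAYS_PER_YEAR, 2)
        )

    def to_dict(self) -> dict:
        return {
            "cuspal_days": self.cuspal_days,
            "deciles12_days": self.deciles12_days,
            "per_decile_days": list(self.per_decile_days),
            "lateral_days": self.lateral_days,
            "total_days": self.total_days,
            "total_years": self.total_years,
        }


def spacing_table_to_measurements(table: pd.DataFrame) -> list[SpacingMeasurement]:
    """Parse a `zone_index,span_um,n_crossings` table."""
    required = {"zone_index", "span_um", "n_crossings"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"spacing table missing columns {sorted(missing)}")
    return [
        SpacingMeasurement(int(r.zone_index), float(r.span_um), int(r.n_crossings))
        for r in table.itertuples()
    ]


def dsr_profile(measurements: list[SpacingMeasurement],
                zone_width_um: float = 100.0) -> DSRProfile:
    """Average per-zone daily secretion rate from spacing measurements.

    Each zone's rate is the arithmetic mean over its measurements of
    span/n_crossings.  Zones must cover a contiguous range from the EDJ; a
    gap raises with the list of missing zone indices.
    """
    if not measurements:
        raise ValueError("no spacing measurements supplied")
    by_zone: dict[int, list[float]] = {}
    for m in measurements:
        by_zone.setdefault(m.zone_index, []).append(m.rate)
    n_zones = max(by_zone) + 1
    gaps = sorted(set(range(n_zones)) - set(by_zone))
    if gaps:
        raise ValueError(f"zones without measurements: {gaps}")
    zone_rates = tuple(
        (z, fmean(by_zone[z]), len(by_zone[z])) for z in range(n_zones)
    )
    return DSRProfile(zone_width_um=zone_width_um, zone_rates=zone_rates)


def cuspal_time(cuspal_thickness_um: float, profile: DSRProfile) -> CuspalResult:
    """Cuspal enamel formation time: thickness over the mean cuspal DSR.

    The mean is the unweighted mean of zone means; with equal-width zones
    this coincides with a length-weighted mean except in a partial last zone.
    """
    if cuspal_thickness_um <= 0:
        raise ValueError("cuspal thickness must be > 0")
    mean_dsr = profile.mean_rate()
    return CuspalResult(days=cuspal_thickness_um / mean_dsr, mean_dsr=mean_dsr)


def periodicity(counts_between_striae: list[int]) -> PeriodicityResult:
    """Stria periodicity as the modal cross-striation count between striae.

    Disagreement among sampling locations is reported (``unanimous=False``);
    a tie between modes resolves to the smallest with a warning.
    """
    if not counts_between_striae:
        raise ValueError("need at least one periodicity count")
    if any(c < 1 for c in counts_between_striae):
        raise ValueError("periodicity counts must be >= 1")
    tally = Counter(counts_between_striae)
    top = max(tally.values())
    modes = sorted(k for k, v in tally.items() if v == top)
    if len(modes) > 1:
        warnings.warn(
            f"periodicity tie between {modes}; taking the smallest", stacklevel=2
        )
    return PeriodicityResult(
        days=modes[0],
        counts=tuple(counts_between_striae),
        unanimous=len(tally) == 1,
    )


def lateral_time(record: RetziusRecord) -> tuple[int, tuple[int, ...], int]:
    """Lateral enamel formation time from decile stria counts.

    Deciles 3-10 contribute stria count x periodicity days each; deciles 1-2
    contribute prism-path length / local DSR, rounded to whole days and
    reported jointly (index 0 of the per-decile tuple, index 1 set to 0).
    Returns (deciles12_days, per_decile_days, lateral_days).
    """
    if record.deciles12_local_dsr <= 0:
        raise ValueError("deciles 1-2 local DSR must be > 0")
    d12 = round(record.deciles12_prism_length_um / record.deciles12_local_dsr)
    per_decile = [d12, 0] + [
        c * record.periodicity_days for c in record.decile_stria_counts[2:]
    ]
    lateral = d12 + sum(per_decile[2:])
    return d12, tuple(per_decile), lateral


def total_crown_time(cuspal_days: float, deciles12_days: int,
                     per_decile_days: tuple[int, ...]) -> CrownChronology:
    """Assemble the crown chronology; total = cuspal + lateral."""
    if cuspal_days < 0:
        raise ValueError("cuspal_days must be >= 0")
    return CrownChronology(
        cuspal_days=round(cuspal_days),
        deciles12_days=deciles12_days,
        per_decile_days=tuple(per_decile_days),
    )
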