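"""Before/after/between interval dataset construction.

Each inter-train gap of duration at least three times the interval length
``d`` contributes exactly three disjoint intervals: *after* opens the gap
(the first ``d`` seconds following the preceding train), *before* closes
it (the last ``d`` seconds ahead of the next train), and *between* is
centred on the gap midpoint, maximising distance from both trains so it
can serve as the activity baseline.  Bat passes are assigned to intervals
by their start time, half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_processing import BatPass, InterTrainGap, TrainPass, build_gaps

__all__ = [
    "AnalysisInterval",
    "NightData",
    "NightSummary",
    "make_intervals",
    "count_passes",
    "assemble_dataset",
    "nightly_total",
    "night_summary",
    "INTERVAL_DURATIONS_S",
]

#: interval durations analysed, seconds
INTERVAL_DURATIONS_S = (30, 60, 120, 240, 480)


@dataclass
class AnalysisInterval:
    gap_ref: int
    category: str  # before | after | between
    duration_s: float
    start_s: float
    end_s: float
    bat_count: int = 0

    def __post_init__(self) -> None:
        if self.category not in ("before", "after", "between"):
            raise ValueError("category must be before/after/between")


@dataclass
class NightData:
    """Processed events and covariates for one site-night."""

    site_id: str
    night_id: str
    bat_passes: list[BatPass]
    trains: list[TrainPass]
    gaps: list[InterTrainGap]
    trains_per_hour: float = float("nan")
    weather: dict = field(default_factory=dict)  # wind, humidity, temperature
    date: float = float("nan")  # day of year

    @classmethod
    def from_events(cls, site_id, night_id, bat_passes, trains,
                    recording_window, **kw) -> "NightData":
        gaps = build_gaps(trains, recording_window)
        return cls(site_id=site_id, night_id=night_id, bat_passes=bat_passes,
                   trains=trains, gaps=gaps, **kw)


@dataclass
class NightSummary:
    """Per-night activity totals within inter-train gaps."""

    night_id: str
    site_id: str
    nightly_total: int
    species_totals: dict
    feeding_buzz_total: int
    weather: dict


def night_summary(night: NightData) -> NightSummary:
    """Totals of passes starting within the night's inter-train gaps."""
    species = sorted({p.species for p in night.bat_passes})
    per_species = {sp: nightly_total(night, sp) for sp in species}
    edges = np.array([[g.start_s, g.end_s] for g in night.gaps]).ravel() \
        if night.gaps else np.array([])
    buzz = sum(1 for p in night.bat_passes if p.feeding_buzz and edges.size
               and np.searchsorted(edges, p.start_s, side="right") % 2 == 1)
    return NightSummary(night_id=night.night_id, site_id=night.site_id,
                        nightly_total=sum(per_species.values()),
                        species_totals=per_species,
                        feeding_buzz_total=int(buzz), weather=dict(night.weather))


def make_intervals(gap: InterTrainGap, d: float) -> list[AnalysisInterval]:
    """The 0 or 3 analysis intervals a gap yields at duration ``d``.

    A gap qualifies when its duration is at least ``3 d`` (e.g. 90 s gaps
    at d = 30); a qualifying gap of exactly ``3 d`` is tiled edge to edge.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    if gap.duration_s < 3 * d:
        return []
    mid = (gap.start_s + gap.end_s) / 2.0
    return [
        AnalysisInterval(gap.gap_id, "after", d, gap.start_s, gap.start_s + d),
        AnalysisInterval(gap.gap_id, "between", d, mid - d / 2.0, mid + d / 2.0),
        AnalysisInterval(gap.gap_id, "before", d, gap.end_s - d, gap.end_s),
    ]


def count_passes(interval: AnalysisInterval, passes: list[BatPass],
                 species: str | None = None) -> int:
    """Passes whose start time falls in ``[start, end)``; optional species filter."""
    starts = [p.start_s for p in passes
              if species is None or p.species == species]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("passes must be sorted by start time")
    return bisect_left(starts, interval.end_s) - bisect_left(starts, interval.start_s)


def nightly_total(night: NightData, species: str | None = None) -> int:
    """Total bat passes starting within the night's inter-train gaps."""
    starts = np.array([p.start_s for p in night.bat_passes
                       if species is None or p.species == species])
    if starts.size == 0 or not night.gaps:
        return 0
    edges = np.array([[g.start_s, g.end_s] for g in night.gaps]).ravel()
    # gaps are disjoint and sorted; odd insertion index = inside a gap
    return int(np.sum(np.searchsorted(edges, starts, side="right") % 2 == 1))


def assemble_dataset(nights: list[NightData], d: float,
                     species: str | None = None) -> pd.DataFrame:
    """One row per analysis interval across nights, with counts + covariates.

    Row count is 3 x (number of qualifying gaps).  Both pipistrelle
    species are pooled unless ``species`` filters to one.  Missing weather
    covariates are kept as NaN and flagged in ``missing_covariates``.
    """
    rows = []
    for night in nights:
        tot = nightly_total(night, species)
        for gap in night.gaps:
            for iv in make_intervals(gap, d):
                iv.bat_count = count_passes(iv, night.bat_passes, species)
                w = night.weather
                rows.append({
                    "site_id": night.site_id,
                    "night_id": night.night_id,
                    "gap_id": gap.gap_id,
                    "category": iv.category,
                    "start_s": iv.start_s,
                    "end_s": iv.end_s,
                    "duration_s": d,
                    "count": iv.bat_count,
                    "nightly_total": tot,
                    "time_since_start_h": iv.start_s / 3600.0,
                    "wind": w.get("wind", np.nan),
                    "humidity": w.get("humidity", np.nan),
                    "temperature": w.get("temperature", np.nan),
                    "gap_duration_s": gap.duration_s,
                    "trains_per_hour": night.trains_per_hour,
                    "date": night.date,
                })
    df = pd.DataFrame(rows)
    if df.empty:
        warnings.warn(f"no gaps of duration >= {3 * d:.0f} s; empty analysis table")
        df = pd.DataFrame(columns=[
            "site_id", "night_id", "gap_id", "category", "start_s", "end_s",
            "duration_s", "count", "nightly_total", "time_since_start_h",
            "wind", "humidity", "temperature", "gap_duration_s",
            "trains_per_hour", "date"])
    cov = ["wind", "humidity", "temperature", "trains_per_hour", "date"]
    df["missing_covariates"] = df[cov].isna().any(axis=1) if len(df) else pd.Series(dtype=bool)
    df["category"] = pd.Categorical(df["category"],
                                    categories=["between", "before", "after"])
    return df
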