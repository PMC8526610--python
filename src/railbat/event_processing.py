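"""Segmentation of call detections into bat passes, train-log physics,
and construction of inter-train gaps.

Conventions: all times are seconds from recording start, intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BatPass",
    "TrainPass",
    "InterTrainGap",
    "segment_passes",
    "estimate_train_length",
    "estimate_train_speed",
    "build_gaps",
    "MEAN_CAR_LENGTH_M",
    "PASS_GAP_S",
]

#: mean car length (m) across the train models operating on the study lines
MEAN_CAR_LENGTH_M = 21.0

#: a new bat pass starts when the inter-call gap strictly exceeds this (s)
PASS_GAP_S = 1.0


@dataclass
class BatPass:
    """One bat pass: a call or call series separated from others by more
    than one second."""

    species: str
    start_s: float
    end_s: float
    feeding_buzz: bool = False
    n_calls: int = 1

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("end_s must be >= start_s")


@dataclass
class TrainPass:
    """One train transit past the detector."""

    start_s: float
    end_s: float
    track: int = 1
    n_cars: int = 1
    overlap: bool = False
    length_m: float | None = None
    speed_kmh: float | None = None
    max_spl_db: float | None = None
    corrected_spl_db: float | None = None
    freq_group: str = "unknown"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("train pass must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def with_physics(self, mean_car_length: float = MEAN_CAR_LENGTH_M) -> "TrainPass":
        """Fill length and speed estimates from car count and timing."""
        self.length_m = estimate_train_length(self.n_cars, mean_car_length)
        self.speed_kmh = estimate_train_speed(self.length_m, self.duration_s)
        return self


@dataclass
class InterTrainGap:
    """Train-free span between two consecutive non-overlapping passes."""

    start_s: float
    end_s: float
    bounded: bool = True
    gap_id: int = -1

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("gap must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def segment_passes(call_times, species=None, buzz=None,
                   max_gap_s: float = PASS_GAP_S) -> list[BatPass]:
    """Group call timestamps into bat passes.

    A new pass starts exactly when the gap to the previous call strictly
    exceeds ``max_gap_s`` (a gap of exactly 1.0 s keeps calls in the same
    pass).  When ``species`` labels are given, each species stream is
    segmented independently, so passes of different species may overlap.
    The pass buzz flag is true if any constituent call is flagged.
    """
    t = np.asarray(call_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("call times must be sorted")
    species = np.asarray(species) if species is not None else np.repeat("pipistrelle", t.size)
    buzz = np.asarray(buzz, dtype=bool) if buzz is not None else np.zeros(t.size, dtype=bool)
    if species.size != t.size or buzz.size != t.size:
        raise ValueError("species/buzz must align with call_times")

    passes: list[BatPass] = []
    for sp in sorted(set(species.tolist())):
        m = species == sp
        ts, bz = t[m], buzz[m]
        brk = np.flatnonzero(np.diff(ts) > max_gap_s) + 1
        for seg_t, seg_b in zip(np.split(ts, brk), np.split(bz, brk)):
            passes.append(BatPass(species=str(sp), start_s=float(seg_t[0]),
                                  end_s=float(seg_t[-1]),
                                  feeding_buzz=bool(seg_b.any()),
                                  n_calls=int(seg_t.size)))
    passes.sort(key=lambda p: (p.start_s, p.species))
    return passes


def estimate_train_length(n_cars: int, mean_car_length: float = MEAN_CAR_LENGTH_M) -> float:
    """Train length in metres: car count times mean car length."""
    if n_cars < 1:
        raise ValueError("n_cars must be >= 1")
    return n_cars * mean_car_length


def estimate_train_speed(length_m: float, duration_s: float) -> float:
    """Train speed in km/h: (length [m] / pass duration [s]) * 3.6."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    return length_m / duration_s * 3.6


def build_gaps(trains: list[TrainPass],
               recording_window: tuple[float, float]) -> list[InterTrainGap]:
    """Inter-train gaps usable for before/after/between sampling.

    Gaps adjacent to an overlap-flagged pass are excluded (overlapping
    passes are a different stimulus), as are the spans between the
    recording boundary and the first/last train, which lack one anchoring
    train.  Same-track passes that overlap in time are malformed input.
    """
    trains = sorted(trains, key=lambda p: p.start_s)
    for a, b in zip(trains, trains[1:]):
        if b.start_s < a.end_s and b.track == a.track:
            raise ValueError("overlapping same-track train passes")
    lo, hi = recording_window
    gaps: list[InterTrainGap] = []
    gid = 0
    for a, b in zip(trains, trains[1:]):
        start = max(a.end_s, lo)
        end = min(b.start_s, hi)
        # cross-track coincidence without an overlap flag: no usable gap
        if end <= start:
            continue
        if a.overlap or b.overlap:
            continue
        # a third pass must not intersect the gap interior
        if any(p.start_s < end and p.end_s > start for p in trains if p is not a and p is not b):
            continue
        gaps.append(InterTrainGap(start_s=start, end_s=end, gap_id=gid))
        gid += 1
    return gaps
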