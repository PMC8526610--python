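"""Synthetic rail-side survey generator.

Produces the three ingredients a trackside bat survey yields — a train
schedule, a stream of time-stamped bat passes, and a calibrated acoustic
recording — with known ground truth, so that the downstream event
processing, interval analysis and count models can be tested end to end
without field data.

The bat stream is an inhomogeneous Poisson process realised by thinning:

    lambda(t) = lambda0 * exp(b_site + beta_t * t) * s^{1[suppressed(t)]} * g(t)

where ``b_site`` is a per-site log-scale intercept, ``beta_t`` a within-night
log-linear trend, ``s`` a multiplicative suppression factor active for
``tau`` seconds after the end of every train pass, and ``g(t)`` an optional
piecewise gamma frailty producing negative-binomial overdispersion in
interval counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_processing import TrainPass

__all__ = [
    "SiteConfig",
    "SuppressionConfig",
    "TrainScheduleConfig",
    "generate_train_schedule",
    "generate_bat_events",
    "generate_calibration_audio",
]

#: dB SPL reference pressure, pascal.
P_REF = 20e-6


@dataclass
class SiteConfig:
    """Static description of one rail-side recording site.

    Rates are per hour; the recording window starts at t = 0 s.
    """

    site_id: str = "site"
    trains_per_hour: float = 6.0
    n_tracks: int = 2
    #: detector-to-train distance in metres, one entry per track
    detector_train_distance: tuple[float, ...] = (10.6, 13.4)
    #: baseline bat-pass rate lambda0, passes per hour
    baseline_rate: float = 47.0
    #: SD of the per-site log-scale random intercept
    site_effect_sd: float = 0.2
    #: within-night log-rate slope, per hour since recording start
    time_trend: float = 0.41
    #: recording duration in seconds (3.5 h nightly survey window)
    recording_duration: float = 12600.0

    def __post_init__(self) -> None:
        if self.trains_per_hour < 0:
            raise ValueError("trains_per_hour must be >= 0")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be > 0")
        if self.n_tracks not in (1, 2):
            raise ValueError("n_tracks must be 1 or 2")
        if any(d <= 0 for d in self.detector_train_distance):
            raise ValueError("detector_train_distance must be > 0")


@dataclass
class SuppressionConfig:
    """Post-train suppression and overdispersion of the bat stream.

    ``factor_s`` multiplies the rate for ``duration_tau`` seconds after each
    train pass ends (rectangular window, full recovery afterwards).
    ``dispersion_theta`` is the NB2 shape of the gamma frailty; ``inf``
    disables the frailty and leaves the process Poisson.
    """

    factor_s: float = 0.5
    duration_tau: float = 120.0
    dispersion_theta: float = 2.0
    #: length of the iid frailty blocks, seconds
    frailty_block_s: float = 30.0
    #: if True, the suppression factor recovers exponentially over tau
    #: instead of switching off; off by default
    exponential_recovery: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.factor_s <= 1.0):
            raise ValueError("factor_s must be in (0, 1]")
        if self.duration_tau < 0:
            raise ValueError("duration_tau must be >= 0")
        if not self.dispersion_theta > 0:
            raise ValueError("dispersion_theta must be > 0")


@dataclass
class TrainScheduleConfig:
    """Physical train population at a site."""

    mean_car_length: float = 21.0
    car_count_range: tuple[int, int] = (1, 12)
    speed_range: tuple[float, float] = (40.0, 170.0)  # km/h
    pass_overlap_prob: float = 0.015

    def __post_init__(self) -> None:
        if self.mean_car_length <= 0:
            raise ValueError("mean_car_length must be > 0")
        if self.car_count_range[1] < self.car_count_range[0]:
            raise ValueError("car_count_range empty")
        if self.speed_range[1] < self.speed_range[0]:
            raise ValueError("speed_range empty")


def _draw_pass(rng: np.random.Generator, tcfg: TrainScheduleConfig,
               start: float, track: int, overlap: bool = False) -> TrainPass:
    n_cars = int(rng.integers(tcfg.car_count_range[0], tcfg.car_count_range[1] + 1))
    speed = float(rng.uniform(*tcfg.speed_range))
    length = n_cars * tcfg.mean_car_length
    duration = length / (speed / 3.6)
    return TrainPass(start_s=start, end_s=start + duration, track=track,
                     n_cars=n_cars, overlap=overlap,
                     length_m=length, speed_kmh=speed)


def generate_train_schedule(cfg: SiteConfig, tcfg: TrainScheduleConfig | None = None,
                            seed: int = 0) -> list[TrainPass]:
    """Simulate one night of train passes at a site.

    Arrivals are homogeneous Poisson at ``cfg.trains_per_hour``; starts are
    pushed forward where needed so that passes never overlap on the same
    notional corridor (minimum headway = pass duration).  At two-track
    sites each pass spawns, with probability ``pass_overlap_prob``, a
    coincident opposite-track pass; both are flagged ``overlap``.
    """
    tcfg = tcfg or TrainScheduleConfig()
    rng = np.random.default_rng(seed)
    T = cfg.recording_duration
    rate_s = cfg.trains_per_hour / 3600.0
    if rate_s == 0:
        return []

    # mean occupancy check: passes must be placeable without full overlap
    mean_len = tcfg.mean_car_length * (tcfg.car_count_range[0] + tcfg.car_count_range[1]) / 2
    mean_speed_ms = (tcfg.speed_range[0] + tcfg.speed_range[1]) / 2 / 3.6
    mean_dur = mean_len / mean_speed_ms
    if rate_s * mean_dur >= 1.0:
        raise ValueError(
            f"trains_per_hour={cfg.trains_per_hour} implies occupancy "
            f">= 100% (mean pass duration {mean_dur:.1f} s); cannot place passes")

    n = rng.poisson(rate_s * T)
    starts = np.sort(rng.uniform(0.0, T, size=n))
    passes: list[TrainPass] = []
    t_free = 0.0
    for s in starts:
        s = max(float(s), t_free)
        if s >= T:
            break
        p = _draw_pass(rng, tcfg, s, track=int(rng.integers(1, cfg.n_tracks + 1)))
        passes.append(p)
        t_free = p.end_s
        if cfg.n_tracks == 2 and rng.uniform() < tcfg.pass_overlap_prob:
            # coincident opposite-track pass; both are overlap events
            other = 1 if p.track == 2 else 2
            off = rng.uniform(0.0, max(p.end_s - p.start_s, 1e-6))
            q = _draw_pass(rng, tcfg, p.start_s + off, track=other, overlap=True)
            p.overlap = True
            passes.append(q)
            t_free = max(t_free, q.end_s)
    passes.sort(key=lambda p: p.start_s)
    return passes


def suppression_windows(schedule: list[TrainPass], tau: float) -> np.ndarray:
    """(n, 2) array of [pass end, pass end + tau) windows."""
    if not schedule or tau <= 0:
        return np.empty((0, 2))
    ends = np.array([p.end_s for p in schedule])
    return np.column_stack([ends, ends + tau])


def _merge_windows(win: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping [a, b) windows into disjoint sorted ones."""
    order = np.argsort(win[:, 0])
    out = []
    for a, b in win[order]:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.array(out)


def _in_windows(t: np.ndarray, win: np.ndarray) -> np.ndarray:
    """Boolean mask: is each time inside any [a, b) window."""
    if win.size == 0:
        return np.zeros(t.shape, dtype=bool)
    hit = np.zeros(t.shape, dtype=bool)
    for a, b in win:
        hit |= (t >= a) & (t < b)
    return hit


def generate_bat_events(schedule: list[TrainPass], cfg: SiteConfig,
                        sup: SuppressionConfig | None = None, seed: int = 0,
                        site_effect: float | None = None) -> np.ndarray:
    """Draw bat-pass start times from the suppressed inhomogeneous process.

    Returns a sorted array of event times in seconds.  ``site_effect`` is
    the realised log-scale site intercept; when ``None`` it is drawn from
    N(0, cfg.site_effect_sd) using ``seed``.

    The process is realised block-wise by thinning: within each frailty
    block the rate envelope is the block maximum of
    ``lambda0 * exp(site_effect + trend * t) * frailty``; candidates are
    homogeneous Poisson at the envelope and are retained with probability
    ``lambda(t) / envelope``.
    """
    sup = sup or SuppressionConfig()
    rng = np.random.default_rng(seed)
    if site_effect is None:
        site_effect = float(rng.normal(0.0, cfg.site_effect_sd))
    T = cfg.recording_duration
    lam0 = cfg.baseline_rate / 3600.0 * math.exp(site_effect)
    if lam0 == 0:
        return np.array([])

    block = sup.frailty_block_s
    n_blocks = int(math.ceil(T / block))
    edges = np.minimum(np.arange(n_blocks + 1) * block, T)
    if math.isinf(sup.dispersion_theta):
        frailty = np.ones(n_blocks)
    else:
        th = sup.dispersion_theta
        frailty = rng.gamma(shape=th, scale=1.0 / th, size=n_blocks)

    trend_s = cfg.time_trend / 3600.0  # per second
    win = suppression_windows(schedule, sup.duration_tau)

    lo = edges[:-1]
    hi = edges[1:]
    width = hi - lo
    # per-block envelope: frailty is constant, the trend peaks at one edge
    env = lam0 * frailty * np.exp(trend_s * np.where(trend_s > 0, hi, lo))
    n_cand = rng.poisson(env * width)
    total = int(n_cand.sum())
    if total == 0:
        return np.array([])
    bix = np.repeat(np.arange(n_blocks), n_cand)
    t = lo[bix] + rng.uniform(size=total) * width[bix]
    rate = lam0 * frailty[bix] * np.exp(trend_s * t)
    if win.size:
        if sup.exponential_recovery:
            fac = np.ones_like(t)
            for a, bb in win:
                m = (t >= a) & (t < bb)
                # factor rises from s back to 1 over tau
                frac = (t[m] - a) / max(bb - a, 1e-12)
                fac[m] = np.minimum(fac[m], sup.factor_s ** (1.0 - frac))
            rate = rate * fac
        else:
            merged = _merge_windows(win)
            inside = np.searchsorted(merged.ravel(), t, side="right") % 2 == 1
            rate = np.where(inside, rate * sup.factor_s, rate)
    keep = rng.uniform(size=total) < rate / env[bix]
    return np.sort(t[keep])


def _band_noise(rng: np.random.Generator, n: int, sr: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise via FFT masking."""
    x = rng.normal(size=n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / sr)
    X[(f < lo) | (f > hi)] = 0.0
    y = np.fft.irfft(X, n=n)
    return y / max(np.sqrt(np.mean(y ** 2)), 1e-300)


def generate_calibration_audio(ref_level_db: float = 94.0, tone_freq: float = 1000.0,
                               passes: list[TrainPass] | None = None,
                               peak_spl: float | list[float] = 107.3,
                               sample_rate: float = 48000.0, seed: int = 0,
                               tone_duration_s: float = 10.0,
                               total_duration_s: float | None = None,
                               gain: float = 0.005,
                               squeal: bool = False) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize an acoustic survey recording with known SPL ground truth.

    The waveform opens with a ``tone_duration_s`` pure reference tone whose
    true level is ``ref_level_db`` dB SPL, followed by one band-limited
    noise burst per train pass whose plateau level is the requested peak
    SPL.  ``gain`` is the arbitrary recorder sensitivity (digital units per
    pascal) that calibration must recover.  With ``squeal=True`` each burst
    carries harmonic tonal components at 6/9/12 kHz, emulating wheel squeal
    at curved-track sites.

    Returns ``(waveform, truth)`` where ``truth`` has one row per pass with
    columns ``start_s, end_s, true_peak_spl_db``.
    """
    if sample_rate < 4 * tone_freq:
        raise ValueError("sample_rate must be >= 4 * tone_freq")
    passes = passes or []
    if np.isscalar(peak_spl):
        peaks = [float(peak_spl)] * len(passes)
    else:
        peaks = [float(v) for v in peak_spl]
        if len(peaks) != len(passes):
            raise ValueError("peak_spl list must match passes")

    end = max([tone_duration_s] + [p.end_s + 6.0 for p in passes])
    if total_duration_s is not None:
        end = max(end, total_duration_s)
    n = int(round(end * sample_rate))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)

    # reference tone: rms pressure for ref_level_db, sine amplitude sqrt(2)*rms
    t_tone = np.arange(int(tone_duration_s * sample_rate)) / sample_rate
    rms_pa = P_REF * 10 ** (ref_level_db / 20.0)
    x[: t_tone.size] = math.sqrt(2.0) * rms_pa * np.sin(2 * math.pi * tone_freq * t_tone)

    truth = []
    for p, spl in zip(passes, peaks):
        rms = P_REF * 10 ** (spl / 20.0)
        ramp = 2.0
        plateau = max(p.end_s - p.start_s, 1.5)
        a = p.start_s - ramp
        b = p.start_s + plateau + ramp
        i0, i1 = max(int(a * sample_rate), 0), min(int(b * sample_rate), n)
        m = i1 - i0
        if m <= 0:
            continue
        tt = np.arange(m) / sample_rate + i0 / sample_rate
        envelope = np.ones(m)
        r = (tt - a) / ramp
        envelope = np.minimum(envelope, np.clip(r, 0, 1))
        r2 = (b - tt) / ramp
        envelope = np.minimum(envelope, np.clip(r2, 0, 1))
        burst = _band_noise(rng, m, sample_rate, 200.0, 4000.0)
        if squeal:
            for k, fh in enumerate((6000.0, 9000.0, 12000.0)):
                amp = math.sqrt(2.0) * 0.5 / (k + 1)
                burst = burst + amp * np.sin(2 * math.pi * fh * tt)
            burst = burst / np.sqrt(np.mean(burst[envelope > 0.99] ** 2))
        x[i0:i1] += rms * burst * envelope
        truth.append({"start_s": p.start_s, "end_s": p.end_s,
                      "true_peak_spl_db": spl})

    x = x * gain
    if np.max(np.abs(x)) > 1.0:
        raise ValueError("requested SPL clips at this gain; reduce gain or level")
    return x, pd.DataFrame(truth, columns=["start_s", "end_s", "true_peak_spl_db"])
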