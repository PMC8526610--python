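"""End-to-end drivers: synthetic campaign -> interval table -> averaged model.

These functions wire the generator, event processing, interval analysis
and count models together the way the analysis scripts use them, so that
recovery simulations run through exactly the code path a user would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .count_models import (AveragedModel, ModelSpec, fit_nb,
                           pairwise_contrasts, rank_and_average,
                           screen_univariate)
from .event_processing import segment_passes
from .interval_analysis import NightData, assemble_dataset
from .synthetic_data import (SiteConfig, SuppressionConfig,
                             TrainScheduleConfig, generate_bat_events,
                             generate_train_schedule)

__all__ = ["simulate_campaign", "run_analysis_chain", "after_train_table",
           "ChainResult"]

#: candidate confounders screened before the all-subsets step
DEFAULT_CANDIDATES = ("nightly_total", "time_since_start_h", "wind",
                      "humidity", "temperature")


def simulate_campaign(seed: int, n_sites: int = 12, nights_per_site: int = 4,
                      sup: SuppressionConfig | None = None,
                      site_cfgs: list[SiteConfig] | None = None,
                      tcfg: TrainScheduleConfig | None = None) -> list[NightData]:
    """Simulate a multi-site survey campaign with per-site train rates.

    Site train rates are spread over the study's observed range
    (1.7-19.3 per hour) unless explicit configs are given; each site
    keeps one realised random intercept across its nights.  Weather is
    drawn per night within the survey's collection limits (wind <= 15
    km/h, temperature >= 10 C) and carries no true effect on activity.
    """
    sup = sup or SuppressionConfig()
    rng = np.random.default_rng(seed)
    if site_cfgs is None:
        rates = np.linspace(1.7, 19.3, n_sites)
        site_cfgs = [SiteConfig(site_id=f"site{i:02d}", trains_per_hour=float(r))
                     for i, r in enumerate(rates)]
    nights = []
    for cfg in site_cfgs:
        site_eff = float(rng.normal(0.0, cfg.site_effect_sd))
        for j in range(nights_per_site):
            sch = generate_train_schedule(cfg, tcfg, seed=int(rng.integers(2 ** 31)))
            ev = generate_bat_events(sch, cfg, sup, seed=int(rng.integers(2 ** 31)),
                                     site_effect=site_eff)
            passes = segment_passes(ev) if len(ev) else []
            nights.append(NightData.from_events(
                cfg.site_id, f"{cfg.site_id}_n{j}", passes, sch,
                (0.0, cfg.recording_duration),
                trains_per_hour=cfg.trains_per_hour,
                weather={"wind": float(rng.uniform(0.0, 15.0)),
                         "humidity": float(rng.uniform(40.0, 95.0)),
                         "temperature": float(rng.uniform(10.0, 22.0))},
                date=float(rng.integers(196, 264))))  # mid-Jul to late Sep
    return nights


def after_train_table(nights: list[NightData], d: float = 30.0) -> pd.DataFrame:
    """One row per *after* interval, joined to the preceding train's
    physical and acoustic attributes (SPL, length, speed, frequency group).

    This is the severity analysis surface: does how loud/long/fast the
    train was predict the activity immediately after it?
    """
    rows = []
    from .interval_analysis import count_passes, make_intervals, nightly_total

    for night in nights:
        tot = nightly_total(night)
        trains = sorted(night.trains, key=lambda t: t.start_s)
        for gap in night.gaps:
            ivs = make_intervals(gap, d)
            if not ivs:
                continue
            after = next(iv for iv in ivs if iv.category == "after")
            prev = max((t for t in trains if t.end_s <= gap.start_s + 1e-9),
                       key=lambda t: t.end_s, default=None)
            if prev is None:
                continue
            rows.append({
                "site_id": night.site_id, "night_id": night.night_id,
                "count": count_passes(after, night.bat_passes),
                "corrected_spl_db": prev.corrected_spl_db,
                "max_spl_db": prev.max_spl_db,
                "train_length_m": prev.length_m,
                "train_speed_kmh": prev.speed_kmh,
                "freq_group": prev.freq_group,
                "nightly_total": tot,
                "time_since_start_h": after.start_s / 3600.0,
                "wind": night.weather.get("wind", np.nan),
            })
    return pd.DataFrame(rows)


@dataclass
class ChainResult:
    table: pd.DataFrame
    screened_terms: list[str]
    averaged: AveragedModel
    contrasts: pd.DataFrame

    @property
    def after_vs_before(self) -> float:
        row = self.contrasts[self.contrasts["contrast"] == "after vs before"]
        return float(row["estimate"].iloc[0])


def run_analysis_chain(nights: list[NightData], d: float = 30.0,
                       candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
                       random_intercept: str | None = "site_id",
                       alpha: float = 0.1) -> ChainResult:
    """Screening -> all-subsets AICc -> averaging on a simulated campaign.

    Interval category always enters the candidate set (it is the term
    under study, not a screened confounder).  The random intercept is
    dropped throughout when the full model fits its variance below 1e-4.
    """
    table = assemble_dataset(nights, d)
    base = ModelSpec(random_intercept=random_intercept)
    if random_intercept is not None:
        full = fit_nb(ModelSpec(fixed_terms=("category",) + candidates,
                                random_intercept=random_intercept), table)
        if full.re_removed or full.re_var < 1e-4:
            base = ModelSpec(random_intercept=None)
    kept = screen_univariate(list(candidates), table, base, alpha=alpha)
    terms = ["category"] + kept
    avg = rank_and_average(terms, table, base)
    contrasts = pairwise_contrasts(avg)
    return ChainResult(table=table, screened_terms=kept, averaged=avg,
                       contrasts=contrasts)
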