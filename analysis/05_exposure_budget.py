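"""Disturbance time budget across the simulated sites.

Converts a 120 s post-train suppression into the fraction of night lost
per site: min(1, rate x 120 / 3600).  At 6 trains/hr that is one-fifth
of the available time; at one train every three minutes, two-thirds; at
one train every half hour, about seven percent.  Writes
results/exposure.csv.
"""

from pathlib import Path

import pandas as pd

from railbat.exposure import site_exposure_report, suppressed_fraction
from railbat.pipeline import simulate_campaign

ROOT = Path(__file__).resolve().parent.parent / "results"
EFFECT_S = 120.0


def main() -> None:
    nights = simulate_campaign(20210819)
    sites = sorted({(n.site_id, n.trains_per_hour) for n in nights})
    reports = site_exposure_report(sites, EFFECT_S)
    df = pd.DataFrame([r.__dict__ for r in reports])
    df.to_csv(ROOT / "exposure.csv", index=False)
    print(df[["site_id", "trains_per_hour", "percent_time_lost"]]
          .to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print(f"\nreference points: 6/hr -> {suppressed_fraction(6, EFFECT_S):.0%}, "
          f"20/hr -> {suppressed_fraction(20, EFFECT_S):.0%}, "
          f"2/hr -> {suppressed_fraction(2, EFFECT_S):.1%}")
    print(f"wrote {ROOT / 'exposure.csv'}")


if __name__ == "__main__":
    main()
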