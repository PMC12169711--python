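"""Ratio-method temporal extrapolation of annual LUR estimates.

Walks the extrapolation chain on a simulated monitoring world: reference
period annual means per site, cross-site daily ratios with surrogate
substitution, weekly pre-scan averages, and the residence-weighted
long-term average.
"""

import pandas as pd

import airdfc as a
from airdfc import exposure as expo

world = a.simulate_monitoring_world(seed=4)
annual = expo.annual_site_means(world.panel, world.reference_period)
ratios = expo.daily_ratio_series(world.panel, annual)

date = world.dates[500]
r, substituted = expo.daily_ratio(world.panel, annual, date, "NOX")
print(f"cross-site NOX ratio on {date.date()}: {r:.3f} (substituted={substituted})")
print(f"annual 40 ug/m3 x ratio -> daily {expo.extrapolate_daily(40.0, r):.1f} ug/m3")

week = expo.weekly_exposure(40.0, ratios, date + pd.Timedelta(days=7), "NOX")
print(f"weekly pre-scan average: {week.mean:.1f} ug/m3 over {week.n_days_used} days")

surface = pd.DataFrame({"NOX": [20.0, 40.0]}, index=pd.Index(["old", "new"], name="address"))
history = [("old", "2002-01-01", "2004-12-31"), ("new", "2005-01-01", "2012-06-30")]
lt = expo.longterm_exposure(history, surface, ("2002-01-01", "2012-06-30"), "NOX")
print(f"childhood average over two addresses (time-weighted): {lt:.1f} ug/m3")
print("Coefficients are later reported per fixed increments, e.g. per")
print(f"{expo.DEFAULT_INCREMENTS['NOX']:.0f} ug/m3 NOX.")
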