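"""Build a week-long synthetic trajectory and its nighttime temporal weights.

Shows the solar-event computation, the one-minute trajectory with habitual
nighttime excursions, and the left-constant temporal weights whose nighttime
share scales every mobility-oriented exposure value.
"""

from datetime import date

import numpy as np

from alanex.exposure import HomeLocation
from alanex.mobility import temporal_weights
from alanex.solar import night_windows_for_range, sun_times
from alanex.synthetic_data import TrajectoryProfile, make_trajectory

sunrise, sunset, _ = sun_times(date(2021, 6, 7), lon=114.1, lat=22.3, utc_offset=8.0)
print(f"Hong Kong, 2021-06-07: sunrise {sunrise:%H:%M}, sunset {sunset:%H:%M}")

windows = night_windows_for_range(date(2021, 6, 7), 7, 114.1, 22.3, 8.0)
profile = TrajectoryProfile(home=HomeLocation(3000.0, 3000.0), days=7,
                            excursions_per_night=2.0, excursion_radius=500.0,
                            bounds=(1.0, 1.0, 6499.0, 6499.0))
traj = make_trajectory(profile, windows, seed=7)
weights = temporal_weights(traj, windows)

night = weights.night_flags
dist = np.hypot(traj.x - 3000.0, traj.y - 3000.0)
away = night & (dist > 50.0)
print(f"fixes: {len(traj)} at 1-minute cadence over {profile.days} days")
print(f"temporal weights sum: {weights.weights.sum():.1f} (by construction)")
print(f"nighttime share of the week: {weights.night_fraction:.3f}")
print(f"night fixes away from home: {away.sum()} "
      f"({away.sum() / max(night.sum(), 1):.1%} of nighttime)")
print("Those away-from-home night minutes are what residence-based exposure")
print("measures miss and mobility-oriented measures capture.")
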