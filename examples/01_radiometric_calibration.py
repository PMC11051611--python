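"""Calibrate raw digital numbers to band radiance and degrade resolution.

Builds a tiny raw-DN grid for a power-law sensor, converts it to spectral
then band radiance, and coarsens it — the preprocessing every nighttime-light
product passes through before exposure assessment.
"""

import numpy as np

from alanex import NTLRaster, SensorSpec, calibrate_power_law, degrade_resolution, to_band_radiance

dn = NTLRaster(np.array([[0.0, 100.0, 400.0, 900.0]] * 4), origin_x=0.0, origin_y=40.0,
               pixel_size=10.0, units_tag="DN")
sensor = SensorSpec(name="panchromatic-130m", nominal_resolution=130.0,
                    spectral_range=(460.0, 980.0), bandwidth=520.0,
                    calibration_kind="power_law")

spectral = calibrate_power_law(dn, sensor)  # DN^1.5 / 1e10, W m^-2 sr^-1 um^-1
band = to_band_radiance(spectral, sensor)  # x bandwidth(um) x 1e5 -> nW cm^-2 sr^-1
coarse = degrade_resolution(band, 2)  # 2x2 block means, 20 m pixels

print("raw DN row:          ", dn.values[0])
print("spectral radiance row:", spectral.values[0])
print("band radiance row:   ", band.values[0].round(3))
print("2x degraded grid mean:", round(coarse.valid_mean(), 3),
      "(equals the fine-grid mean", round(band.valid_mean(), 3), ")")
print("The block mean is conservative: coarsening never changes total light,")
print("only how finely its spatial pattern is resolved.")
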