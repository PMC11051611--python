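"""Compute the four exposure estimators and a small contextual-setting matrix.

Contrasts residence-based (RBM) and mobility-oriented (MOM) exposure for a
handful of synthetic participants under in-situ and buffer-zone settings.
"""

from alanex.exposure import canonical_settings, exposure_matrix
from alanex.pipeline import simulate_study

study = simulate_study(seed=0, n_per_community=6, days=2, grid_size=390,
                       n_calibration_points=30, calibration_grid_size=1300,
                       calibration_radius=300.0)
matrix = exposure_matrix(study.participants, study.trajectories, study.rasters,
                         canonical_settings(), study.calibrations, study.weights)

means = matrix.groupby(["community", "setting"])["value"].mean().unstack("community")
print("mean exposure (nW/cm^2/sr) per contextual setting:")
print(means.round(1).to_string())
m = means.loc["M_b065m"]
r = means.loc["R_b065m"]
print(f"\n65-m buffer, old town: MOM {m['old_town']:.1f} vs RBM {r['old_town']:.1f}")
print("MOM values fold the whole week's duration in (daytime terms are zero),")
print("so they sit near RBM x nighttime-share plus whatever bright places the")
print("participant visited after dark; settings labelled _CC are mapped onto")
print("the reference sensor's radiance scale by the fitted cross-calibration.")
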