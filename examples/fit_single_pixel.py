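"""Fit one cloud-gapped NDVI pixel history and classify its trajectory.

Builds a synthetic inundation pixel (forest at NDVI ~0.8 abruptly flooded in
mid-1996), removes 55% of the acquisition dates with an autocorrelated gap
model, adds cloud-contaminated noise, fits the piecewise trajectory at the
study parameter set, and prints the breakpoints plus the classified event.
"""

import numpy as np

from nita import NITAParams, fit_pixel
from nita.classify import classify_trajectory
from nita.simulate import (GapModel, IdealTrajectory, NoiseModel,
                          default_calendar, sample_valid_dates,
                          synthesize_pixel)
from nita.timeseries import ordinal_to_year, year_to_ordinal

calendar = default_calendar()
snap = lambda yr: calendar[np.argmin(np.abs(calendar - year_to_ordinal(yr)))]
truth = IdealTrajectory(
    bx=np.array([calendar[0], snap(1996.4), snap(1997.3), calendar[-1]]),
    by=np.array([0.80, 0.80, 0.15, 0.15]),
    stratum="single_inundation",
    disturbance_start=int(snap(1996.4)),
    disturbance_nadir=int(snap(1997.3)),
)

rng = np.random.default_rng(7)
dates = sample_valid_dates(GapModel(), calendar, 1, rng)[0]
pixel = synthesize_pixel(truth, dates, NoiseModel(), rng, calendar=calendar)
print(f"observations: {pixel.series.n_valid} valid of {calendar.size} "
      f"acquisition dates (55% cloud)")

model = fit_pixel(pixel.series, NITAParams.study())
print(f"\nfitted {model.segments} segments "
      f"(noise={model.noise:.3f}, BIC={model.bic:.1f}):")
for bp in model.breakpoints:
    print(f"  {ordinal_to_year(bp.date)}  day {bp.date}  NDVI {bp.value:.3f}")

print("\nclassified events (0.70 / 0.40 / 0.10 per year rules):")
for rec in classify_trajectory(model):
    print(f"  {rec.event_class}: drop {rec.magnitude:.2f} NDVI at "
          f"{rec.drop_rate:.2f}/yr, nadir in "
          f"{ordinal_to_year(rec.date_of_nadir)}, recovered={rec.recovered}")
print(f"\ntrue decline start {ordinal_to_year(truth.disturbance_start)}, "
      f"true nadir {ordinal_to_year(truth.disturbance_nadir)} — the fitted "
      f"event dates land within a few valid-observation gaps of the truth.")
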