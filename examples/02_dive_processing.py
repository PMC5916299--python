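"""Process a time-depth record into dives, bouts, trips, and summaries.

Simulates a mixed-strategy deployment (benthic + epipelagic diving), detects
dives with the 4 m / 16 s thresholds, partitions them into bouts with the
log-survivorship criterion, segments foraging trips at haul-outs, and prints
the trip-level behavioral metrics.
"""

from divefmr.dive import detect_dives, segment_trips, trip_metrics, zero_offset_correct
from divefmr.simulate import SimConfig, simulate_dive_record

cfg = SimConfig(seed=7, sampling_interval_s=2.0, n_trips_range=(2, 2),
                trip_duration_days_range=(1.0, 2.0))
trace, fixes, truth = simulate_dive_record(cfg, animal_index=0, strategy="mixed")

corrected = zero_offset_correct(trace)
dives = detect_dives(corrected)
trips = segment_trips(corrected, dives)

print(f"record: {len(trace.depth_m)} samples at {trace.sampling_interval_s:.0f} s")
print(f"dives detected: {len(dives)} (planted: {truth.n_valid_dives}; "
      f"{truth.n_subthreshold} sub-threshold excursions correctly ignored)")
print(f"trips: {len(trips)} (planted: {len(truth.trip_bounds)})")
for i, trip in enumerate(trips):
    m = trip_metrics(trip)
    print(f"\ntrip {i}: {m['trip_duration_hr']:.1f} hr, {int(m['n_dives'])} dives "
          f"in {len(trip.bouts)} bouts")
    print(f"  mean depth {m['mean_depth_m']:.0f} m, mean duration "
          f"{m['mean_duration_s']:.0f} s, mean bout {m['mean_bout_duration_hr']:.1f} hr")
    print(f"  {m['percent_time_diving']:.0f}% of trip spent diving; "
          f"{m['percent_dives_gt200m']:.0f}% of dives deeper than 200 m")
print()
print("Dive counts match the simulator's plant exactly on noise-free traces;")
print("the percent of deep/long dives reflects the mixed foraging regime.")
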