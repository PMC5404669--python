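#!/usr/bin/env python
"""Simulate the calibrated breeding-season cohort and export its inputs.

30 lesser-kestrel-like central-place foragers (15 females, 15 males), 10
complete tracking days each at 1-min GPS cadence, movement strategies
calibrated so the pooled trip/day statistics match the published summary
values.  Writes the small text inputs (breeding records, colony site, trip
and day ground truth, a one-day Movebank-style fix sample) to results/ and
the full raw fix table to scratch/ (large, regenerable).
"""
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
from cpforage import simulate_cohort, write_fixes

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "sim"
SEED = 42


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    tracks, trip_truth, day_truth, records, colony, params = simulate_cohort(seed=SEED)

    write_fixes(tracks, SCRATCH / "fixes_full.csv")
    first_day = tracks[0].fixes.iloc[:841]
    sample = tracks[0].__class__(
        individual_id=tracks[0].individual_id, fixes=first_day, sex=tracks[0].sex
    )
    write_fixes([sample], RESULTS / "sample_fixes_one_day.csv")

    pd.DataFrame(
        [
            {
                "pair_id": pid,
                "arrival": r.arrival_date.date(),
                "laying": r.laying_date.date(),
                "hatching": r.hatching_date.date(),
                "fledging": r.fledging_date.date(),
            }
            for pid, r in records.items()
        ]
    ).to_csv(RESULTS / "breeding_records.csv", index=False)
    pd.DataFrame(
        [{"name": colony.name, "lon": colony.lon, "lat": colony.lat, "radius_m": colony.attendance_radius}]
    ).to_csv(RESULTS / "sites.csv", index=False)
    trip_truth.round(4).to_csv(RESULTS / "truth_trips.csv", index=False)
    day_truth.round(4).to_csv(RESULTS / "truth_days.csv", index=False)

    print(f"simulated {len(tracks)} individuals, {sum(len(t) for t in tracks)} fixes")
    print(f"{len(trip_truth)} planted foraging trips over {len(day_truth)} complete days")
    print(f"resampled schedules: {int(day_truth['n_resample'].sum())} draws")
    print(f"raw fixes  -> {SCRATCH / 'fixes_full.csv'}")
    print(f"truth etc. -> {RESULTS}")


if __name__ == "__main__":
    main()
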