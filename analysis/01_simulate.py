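"""Generate the synthetic spike-in study.

Builds the 24-vessel design (16 DoE + 8 control), the 14-day sampling
schedule with spiking from day 6 through 13 (24*(14+8) = 528 scheduled
spectra, 48 samples on each spiking day), the rotating spike scheme, and the
full synthetic Raman dataset, then writes design.csv, schedule.csv,
spikes.csv, dataset.csv and truth.csv.
"""

import argparse
from pathlib import Path

from ramcal import (build_design, build_schedule, assign_spike_scheme,
                    daily_sample_count, generate_dataset)
from ramcal.experiment_design import spike_events_frame
from ramcal.pipeline_io import write_dataset, write_truth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    design = build_design(seed=args.seed)
    schedule = build_schedule()
    spikes = assign_spike_scheme(design, seed=args.seed)
    records = generate_dataset(design, schedule=schedule, spike_events=spikes,
                               seed=args.seed)

    design.to_csv(args.out / "design.csv", index=False)
    schedule.to_csv(args.out / "schedule.csv", index=False)
    spike_events_frame(spikes).to_csv(args.out / "spikes.csv", index=False)
    write_dataset(records, args.out / "dataset.csv")
    write_truth(records, args.out / "truth.csv")

    print(f"vessels: {len(design)} "
          f"({(design.group == 'doe').sum()} DoE, "
          f"{(design.group == 'control').sum()} control)")
    print(f"scheduled spectra: {len(schedule)}")
    print(f"samples on day 7: {daily_sample_count(schedule, 7)}; "
          f"on day 2: {daily_sample_count(schedule, 2)}")
    print(f"generated records: {len(records)} -> {args.out/'dataset.csv'}")


if __name__ == "__main__":
    main()
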