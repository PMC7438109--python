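#!/usr/bin/env python
"""Generate a synthetic prey-capture session and write its raw-style bundle.

Produces overhead/eye landmark CSVs, an IMU voltage CSV, the ground-truth
event log, and the noiseless kinematics table. Everything downstream
(02-05) runs from these files alone.

    python analysis/01_simulate_session.py --seed 1 --duration 600 \
        --out-dir results/session
"""

import argparse

import numpy as np

from preygaze.synthetic import (SimulationParams, export_raw_style,
                                simulate_session)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--duration", type=float, default=600.0)
    ap.add_argument("--out-dir", default="results/session")
    ap.add_argument("--params", default=None,
                    help="optional YAML file overriding SimulationParams fields")
    args = ap.parse_args()

    kwargs = {"seed": args.seed, "duration": args.duration}
    if args.params:
        import yaml
        with open(args.params) as fh:
            kwargs.update(yaml.safe_load(fh) or {})
    params = SimulationParams(**kwargs)
    session = simulate_session(params)
    paths = export_raw_style(session, args.out_dir)
    session.table().to_csv(f"{args.out_dir}/kinematics_true.csv", index=False)

    gt = session.ground_truth
    fl = gt.fixation_intervals[:, 1] - gt.fixation_intervals[:, 0]
    print(f"session: {args.duration:.0f} s at {params.rate:.0f} Hz, "
          f"seed {args.seed}")
    print(f"  saccades: {gt.saccade_onset_frames.size}  "
          f"(median fixation {np.median(fl) * 1000:.0f} ms)")
    print(f"  approach intervals: {gt.approach_intervals.shape[0]} "
          f"({np.sum(gt.approach_intervals[:, 1] - gt.approach_intervals[:, 0]):.1f} s)")
    for key, path in paths.items():
        print(f"  wrote {key}: {path}")


if __name__ == "__main__":
    main()
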