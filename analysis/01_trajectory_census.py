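#!/usr/bin/env python
"""Trajectory bookkeeping of the monomer/dimer study.

Tabulates the acquired 50 ns trajectories per alloform, assembly state and
water model, and the number of conformations entering the structural
analysis under the (20, 50] ns window at one frame per 50 ps.
"""

import os

import pandas as pd

from abensemble.reference import TRAJECTORY_COUNTS, census

OUT = "results/analysis"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    c = census()
    rows = [
        {"assembly": a, "alloform": al, "water_model": w,
         "trajectories": n, "conformations": c["conformations"][(a, al, w)]}
        for (a, al, w), n in TRAJECTORY_COUNTS.items()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(f"{OUT}/census.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\ntotal trajectories: {c['total_trajectories']}")
    print(f"total simulation time: {c['total_time_us']:.2f} us")
    print(f"frames per trajectory in the analysis window: "
          f"{c['frames_per_trajectory']}")
    print(f"total conformations analyzed: {c['total_conformations']:,}")


if __name__ == "__main__":
    main()
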