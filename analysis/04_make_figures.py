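#!/usr/bin/env python
"""Render the study-summary figures from the simulated dataset.

Three panels: phase-by-phase mean time-compression thresholds ±1 SE per
talker, pre/post thresholds only, and pre/post AzBio-in-noise scores.
Reads results/study/, writes results/figures/.
"""

import argparse
from pathlib import Path

from tempotrain import StudyDataset
from tempotrain.figures import render_figures


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results/figures"))
    args = ap.parse_args()

    dataset = StudyDataset.from_dir(args.data)
    for f in render_figures(dataset, args.out):
        print(f"wrote {f}")


if __name__ == "__main__":
    main()
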