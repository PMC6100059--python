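#!/usr/bin/env python
"""Generate the synthetic scene set that stands in for the seed image archive.

Ten scenes, each with four seeds of every variety laid out as non-touching
ellipses on a dark plate, 200 bands over 975-1644 nm; raw counts plus dark
and white reference frames are written so the chain starts from
uncalibrated data.  Cubes land in scratch/run (binary working data); the
per-scene ground-truth tables are copied to results/.
"""

import shutil
import sys
from pathlib import Path

from seedhsi.cli import main

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def run() -> None:
    RUN.parent.mkdir(exist_ok=True)
    main(["simulate", "--workdir", str(RUN), "--seed", "1"], standalone_mode=False)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "ground_truth"
    out.mkdir(exist_ok=True)
    n = 0
    for csv in sorted(RUN.glob("scenes/*_truth.csv")):
        shutil.copy(csv, out / csv.name)
        n += 1
    print(f"generated {n} scenes under {RUN}; ground-truth tables in {out}")


if __name__ == "__main__":
    sys.exit(run())
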