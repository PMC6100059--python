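#!/usr/bin/env python
"""Predict the external-validation scene and paint per-seed variety maps.

Applies the trained model to seeds the model has never seen (whole scene
withheld), writes the classification map (each seed coloured by predicted
variety) and the per-seed prediction table with object-level accuracy.
"""

import shutil
import sys
from pathlib import Path

import pandas as pd

from seedhsi.cli import main

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def run() -> None:
    main(["predict", "--workdir", str(RUN)], standalone_mode=False)
    main(["map", "--workdir", str(RUN)], standalone_mode=False)
    RESULTS.mkdir(exist_ok=True)
    for f in (RUN / "maps").iterdir():
        shutil.copy(f, RESULTS / f.name)
    for csv in sorted(RESULTS.glob("scene_*_predictions.csv")):
        table = pd.read_csv(csv)
        correct, total = int(table["correct"].sum()), len(table)
        print(f"{csv.stem}: {100 * correct / total:.1f}% ({correct}/{total}) seeds correct")
    print(f"classification maps and prediction tables in {RESULTS}")


if __name__ == "__main__":
    sys.exit(run())
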