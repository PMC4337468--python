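"""Mobility-model accuracy as the sampling frequency drops.

Decimates the calibrated 64-Hz trace to 32/16/8/4/2 Hz, re-extracts
features and retrains the mobility forest on the same window split at each
frequency. Writes results/downsampling.csv. Accuracy should stay high at
16 Hz and degrade only at the lowest rates, where the locomotor dominant
frequencies alias.
"""

import sys
from pathlib import Path

from collarmotion import classify, io as cio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    (trace,) = cio.read_accel_csv(ROOT / "dataset" / "accel_cal.csv")
    labels = cio.read_labels_csv(ROOT / "dataset" / "labels.csv")["behavior"].to_numpy()
    table = classify.downsampling_experiment(trace, labels, seed=SEED)
    table.to_csv(ROOT / "downsampling.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
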