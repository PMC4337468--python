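"""Generate the captive-analog synthetic collar dataset.

Produces a labeled 64-Hz tri-axial trace with the captive-style class mix,
a 15-min GPS track, a miscalibrated raw copy with tumble-calibration data,
and an injected predation-burst cluster — the inputs every later stage
consumes. Writes the CSVs under results/dataset/.
"""

import sys
from pathlib import Path

import numpy as np

from collarmotion import io as cio
from collarmotion import synthetic as syn
from collarmotion.experiments import imbalanced_schedule
from collarmotion.trace import CalibrationParams

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    schedule = imbalanced_schedule(2 * 3600, seed=SEED)
    ds = syn.gen_dataset(schedule, fs=64, gps_interval=900, seed=SEED)

    truth = CalibrationParams(offset=[0.08, -0.12, 0.05], scale=[1.06, 0.94, 1.03])
    raw = syn.inject_miscalibration(ds.trace, truth)
    raw, bursts = syn.inject_predation(
        raw, at=3600, n_bursts=5, burst_magnitude=4.5, gap=60, seed=SEED
    )
    tumble = syn.gen_tumble(truth, 500, noise_sd=0.005, seed=SEED)

    cio.write_accel_csv(raw, OUT / "accel_raw.csv")
    cio.write_gps_csv(ds.gps, OUT / "gps.csv")
    cio.write_labels_csv(
        ds.true_labels.rename(columns={"behavior": "label"}), OUT / "labels.csv"
    )
    np.savetxt(OUT / "tumble.csv", tumble, delimiter=",", header="x,y,z", comments="")
    cio.write_calibration_json(truth, OUT / "calibration_truth.json")
    bursts.to_csv(OUT / "injected_bursts.csv", index=False)

    counts = ds.true_labels["behavior"].value_counts()
    print(f"dataset: {len(ds.trace)} samples, {len(ds.true_labels)} windows, "
          f"{len(ds.gps)} GPS fixes, {len(bursts)} injected bursts")
    print("class mix:")
    print(counts.to_string())


if __name__ == "__main__":
    main()
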