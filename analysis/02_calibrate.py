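"""Recover the sensor-error parameters from the tumble data.

Fits per-axis null shift and scale factor by the pairwise-ellipse method and
compares them with the injected truth; converts the raw trace to units of g
for the feature stage. Writes results/calibration.json and the calibrated
trace to results/dataset/accel_cal.csv.
"""

from pathlib import Path

import numpy as np

from collarmotion import calibration, io as cio

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tumble = np.loadtxt(ROOT / "dataset" / "tumble.csv", delimiter=",", skiprows=1)
    truth = cio.read_calibration_json(ROOT / "dataset" / "calibration_truth.json")

    params = calibration.fit_calibration(tumble)
    cio.write_calibration_json(params, ROOT / "calibration.json")

    res = calibration.sphere_residuals(calibration.apply_calibration(tumble, params))
    print("fitted:", {k: round(v, 4) for k, v in params.to_dict().items()})
    print("truth: ", {k: round(v, 4) for k, v in truth.to_dict().items()})
    print(f"max |offset error| = {np.abs(params.offset - truth.offset).max():.4f} g")
    print(f"max |scale error|  = {np.abs(params.scale - truth.scale).max():.4f}")
    print(f"sphere residual RMS = {np.sqrt(np.mean(res**2)):.4f} g")

    (seg,) = cio.read_accel_csv(ROOT / "dataset" / "accel_raw.csv")
    cal = calibration.apply_calibration(seg, params)
    cio.write_accel_csv(cal, ROOT / "dataset" / "accel_cal.csv")
    print("wrote calibrated trace")


if __name__ == "__main__":
    main()
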