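"""Activity budget and GPS validation of the mobility predictions.

Builds the 24-hour activity budget from model predictions on the synthetic
day, then fits the mixed model (step distance ~ percent time mobile, random
intercept per individual) on a multi-individual synthetic validation set.
Writes results/budget.csv and results/validation.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from collarmotion import classify, ethogram, io as cio
from collarmotion.experiments import _validation_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    feats = cio.read_features_csv(ROOT / "features.csv")
    yb = feats["label"].to_numpy()
    ym = classify.mobility_labels(yb)
    tr, _ = classify.train_test_split_indices(yb, 0.3, seed=SEED)
    model = classify.train(feats.iloc[tr], ym[tr], task="mobility", seed=SEED)
    preds = pd.DataFrame(
        {"window_start": feats["window_start"], "label": model.predict(feats)}
    )

    budget = ethogram.hourly_budget(preds)
    budget.to_csv(ROOT / "budget.csv", index=False)
    active = budget[budget["has_data"]]
    print("hourly activity budget (observed hours):")
    print(active[["hour", "proportion_mobile", "n_windows"]].to_string(index=False))

    steps = _validation_dataset(seed=SEED)
    result = ethogram.mobility_distance_model(steps)
    (ROOT / "validation.json").write_text(json.dumps(vars(result), indent=2) + "\n")
    print(f"\nmixed model over {result.n_individuals} individuals, "
          f"{result.n_steps} steps:")
    print(f"  slope {result.slope:.3f} m per % mobile "
          f"(SE {result.se:.3f}, p {result.pvalue:.2g})")
    if result.singular:
        print("  note: singular fit - random-intercept variance ~ 0 "
              "(individuals share one generator)")


if __name__ == "__main__":
    main()
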