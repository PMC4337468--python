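"""Train and cross-validate the mobility and behavior forests.

Uses the standard recipe (500 trees, per-tree subsample of 1000 without
replacement, 5 candidate predictors per split) on a stratified 70/30 window
split. Writes the two confusion matrices and the permutation variable
importances under results/, and prints the accuracies.
"""

import sys
from pathlib import Path

from collarmotion import classify, io as cio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    feats = cio.read_features_csv(ROOT / "features.csv")
    yb = feats["label"].to_numpy()
    ym = classify.mobility_labels(yb)
    tr, te = classify.train_test_split_indices(yb, 0.3, seed=SEED)

    for task, y in (("mobility", ym), ("behavior", yb)):
        model = classify.train(feats.iloc[tr], y[tr], task=task, seed=SEED)
        cm = classify.evaluate(model, feats.iloc[te], y[te])
        cm.to_frame().to_csv(ROOT / f"confusion_{task}.csv")
        print(f"\n{task} model: overall accuracy {cm.overall_accuracy:.1f}%")
        print(cm.to_frame().to_string())
        if task == "mobility":
            imp = classify.variable_importance(
                model, feats.iloc[te], y[te], n_permutations=10, seed=SEED
            )
            imp.to_csv(ROOT / "importance_mobility.csv", index=False)
            print("top predictors:", ", ".join(imp["predictor"].head(3)))


if __name__ == "__main__":
    main()
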