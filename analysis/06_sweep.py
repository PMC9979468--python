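#!/usr/bin/env python
"""Desk-scale channel x parameter x classifier sweep.

Trains tuned SVM and logistic-regression classifiers on scattering features
for a small grid of transform settings and two channel representations, then
reports the best setting per channel/classifier by held-out F1 (glaucoma
positive).  The full factorial grid is available through
``fundus_scattering.modeling.run_sweep``; this driver keeps the grid small so
the whole study runs in minutes.
"""

from pathlib import Path

from fundus_scattering.filterbank import ScatteringConfig
from fundus_scattering.modeling import HyperparamSpace, best_settings, run_sweep, sweep_frame
from fundus_scattering.preprocessing import iter_image_paths, load_image

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    train = [load_image(p) for p in iter_image_paths(ROOT / "data" / "train")]
    test = [load_image(p) for p in iter_image_paths(ROOT / "data" / "test")]
    grid = [
        ScatteringConfig(invariance_scale=s, quality_factors=(1, 1))
        for s in (75, 125)
    ]
    space = HyperparamSpace(budget=10, folds=5, seed=1)
    records = run_sweep(train, test, ["GS", "GC"], grid, ["svm", "logreg"], space)
    frame = sweep_frame(records)
    frame.to_csv(ROOT / "sweep_results.csv", index=False)
    best = best_settings(records)
    best.to_csv(ROOT / "best_settings.csv", index=False)
    cols = ["channel", "classifier", "s", "q1", "q2", "n_features", "precision", "recall", "f1"]
    print(f"{len(records)} records; best setting per channel/classifier:")
    print(best[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
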