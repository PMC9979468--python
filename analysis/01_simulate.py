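#!/usr/bin/env python
"""Generate the synthetic fundus-phantom study data.

Writes a desk-scale two-class dataset in the class-directory PNG layout the
pipeline reads: a train split and a test split whose class ratios mirror the
~219:120 / 94:52 imbalance of a random fundus-dataset partition, with the
cup-to-disc ratio as the class-separating latent (healthy mean 0.30,
glaucoma mean 0.65).
"""

from pathlib import Path

from fundus_scattering.phantom import PhantomParams, generate_dataset

ROOT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 2024


def main() -> None:
    params = PhantomParams()
    train = generate_dataset(22, 12, params, seed=SEED, out_dir=ROOT / "train")
    test = generate_dataset(11, 6, params, seed=SEED + 1, out_dir=ROOT / "test")
    print(f"train: {train.class_counts[0]} healthy / {train.class_counts[1]} glaucoma")
    print(f"test:  {test.class_counts[0]} healthy / {test.class_counts[1]} glaucoma")
    man = train.manifest()
    by_class = man.groupby("label")["cdr"].agg(["mean", "std"])
    print("drawn CDR by class (train):")
    print(by_class.round(3).to_string())
    print(f"wrote PNGs and manifests under {ROOT}")


if __name__ == "__main__":
    main()
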