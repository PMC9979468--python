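#!/usr/bin/env python
"""Preprocess the phantom splits: channel extraction and 300x300 resize.

Each image yields four 2-D representations (blue, green, red, grayscale);
this driver materializes the grayscale manifest for both splits and checks
the dimensionality bookkeeping (90,000 scalars per preprocessed image).
"""

from pathlib import Path

from fundus_scattering.preprocessing import dataset_manifest, preprocess_dataset

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    for split in ("train", "test"):
        images = preprocess_dataset(ROOT / "data" / split, "GS", (300, 300))
        assert all(im.pixels.size == 90000 for im in images)
        manifest = dataset_manifest(images)
        manifest.to_csv(out / f"{split}_GS.csv", index=False)
        counts = manifest["label"].value_counts().to_dict()
        print(f"{split}: {len(images)} images at 300x300 (90,000 scalars each), {counts}")
    print(f"manifests under {out}")


if __name__ == "__main__":
    main()
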