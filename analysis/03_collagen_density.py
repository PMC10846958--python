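#!/usr/bin/env python
"""Quantify collagen fibre density on synthetic polarized-light images.

Renders one polarized-light-like montage per histology group, with each
density-carrying ROI built at a ground-truth bright-fibre coverage
coupled to that ROI's modulus, then measures the density back through
the analysis chain (greyscale -> 75/255 binarization -> % white pixels
per 50x50 um ROI).  Writes results/density.csv and the healthy-media
montage as a TIFF for inspection.
"""

from pathlib import Path

import numpy as np
import tifffile

from arterynano.pipeline import default_study_config, measure_collagen, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = default_study_config(seed=0)
    seqs = np.random.SeedSequence(config.seed).spawn(3)
    rois = simulate_cohort(config, np.random.default_rng(seqs[0]))
    density, images = measure_collagen(config, rois, np.random.default_rng(seqs[1]))

    RESULTS.mkdir(exist_ok=True)
    density.to_csv(RESULTS / "density.csv", index=False)
    tifffile.imwrite(RESULTS / "healthy_media_polarized_synthetic.tif", images["healthy_wall"])

    print(f"measured {len(density)} ROIs at threshold {config.threshold}/255")
    for label, sub in density.groupby("label"):
        err = (sub["density_pct"] - sub["true_coverage_pct"]).abs().max()
        print(
            f"  {label:22s} n={len(sub):3d}  median density = {sub['density_pct'].median():5.1f}%"
            f"  (max |measured - truth| = {err:.2f} points)"
        )
    print(f"densities -> {RESULTS / 'density.csv'}")


if __name__ == "__main__":
    main()
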