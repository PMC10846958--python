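#!/usr/bin/env python
"""Simulate the synthetic indentation cohorts.

Generates the four histological groups of the default study (healthy
medial wall, lipid-rich necrotic core, fibrous-cap shoulder and
mid-cap), each as a set of 50x50 um ROIs carrying 25 Hertzian approach
curves with 5% force noise and baseline artefacts.  Writes the per-ROI
ground truth to results/cohort_truth.csv and a few example curves in
the TSV + JSON-sidecar exchange format.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from arterynano import write_force_curve
from arterynano.pipeline import default_study_config, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = default_study_config(seed=0)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    rois = simulate_cohort(config, rng)

    truth = pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in rois],
            "label": [r.label for r in rois],
            "true_E_kPa": [r.true_E_kPa for r in rois],
            "n_curves": [len(r.curves) for r in rois],
        }
    )
    RESULTS.mkdir(exist_ok=True)
    truth.to_csv(RESULTS / "cohort_truth.csv", index=False)

    sample_dir = RESULTS / "sample_curves"
    for curve in rois[0].curves[:3]:
        write_force_curve(curve, sample_dir / f"{curve.roi_id}_{curve.position}.tsv")

    print(f"simulated {len(rois)} ROIs / {int(truth['n_curves'].sum())} force curves")
    for label, sub in truth.groupby("label"):
        print(
            f"  {label:22s} n_rois={len(sub):3d}  "
            f"true median E = {sub['true_E_kPa'].median():6.2f} kPa"
        )
    print(f"ground truth -> {RESULTS / 'cohort_truth.csv'}")
    print(f"example curves -> {sample_dir}/")


if __name__ == "__main__":
    main()
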