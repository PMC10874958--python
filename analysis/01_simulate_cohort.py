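#!/usr/bin/env python
"""Simulate the study cohort: 84 eyes (33 normal / 36 NPDR / 15 PDR).

Renders one horizontal and one vertical B-scan per eye with group-specific
smoothness-index and area targets, writes the images and ground-truth
sidecars under scratch/cohort (large, regenerable) and the manifest under
results/.  Run from the repository root.
"""

import logging
import shutil
from pathlib import Path

from octlayers.pipeline import PipelineConfig, cmd_simulate

logging.basicConfig(level="INFO")

OUT = Path("scratch/cohort")
RESULTS = Path("results")


def main():
    cfg = PipelineConfig(seed=20240218, orientations=("horizontal", "vertical"))
    manifest = cmd_simulate(cfg, OUT)
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(OUT / "manifest.csv", RESULTS / "manifest.csv")
    cfg.save(RESULTS / "pipeline_config.json")
    n_pat = manifest["patient_id"].nunique()
    print(f"simulated {len(manifest)} scans: "
          f"{manifest['eye'].size // len(cfg.orientations)} eyes "
          f"from {n_pat} patients "
          f"({manifest.groupby('group')['scan_id'].count().to_dict()})")
    print(f"images + ground truth under {OUT}, manifest copied to {RESULTS}")


if __name__ == "__main__":
    main()
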