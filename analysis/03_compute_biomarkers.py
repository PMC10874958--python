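#!/usr/bin/env python
"""Compute per-eye biomarkers from the segmented boundaries.

Locates the fovea, partitions each scan into its three zones (central 20%
of columns around the fovea, flanked nasally/temporally or
superiorly/inferiorly), and computes the smoothness index of the IPL, the
upper OPL border and the EZ plus the INL/OPL/ONL areas in every zone.
Writes the analysis table (one row per eye, VAR.H.zone variable names) to
results/biomarkers.csv.  Run 02_segment_layers.py first.
"""

import logging
from pathlib import Path

from octlayers.pipeline import Manifest, PipelineConfig, cmd_analyze

logging.basicConfig(level="INFO")

COHORT = Path("scratch/cohort")
LAYERS = Path("scratch/layers")
RESULTS = Path("results")


def main():
    cfg = PipelineConfig.load(RESULTS / "pipeline_config.json")
    manifest = Manifest.load(COHORT / "manifest.csv")
    tables = cmd_analyze(manifest, LAYERS, cfg, RESULTS)
    bio = tables["biomarkers"]
    print(f"wrote results/biomarkers.csv: {len(bio)} eyes x "
          f"{len(bio.columns) - 5} biomarkers")
    means = bio.groupby("group")[["SI_IPL.H.Nasal", "S_INL.H.fovea"]].agg(["mean", "std"])
    print("group summaries (nasal IPL smoothness, foveal INL area):")
    print(means.round(4).to_string())


if __name__ == "__main__":
    main()
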