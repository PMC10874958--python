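#!/usr/bin/env python
"""Cohort statistics over the biomarker table.

For every biomarker: the age/sex-adjusted GEE group comparison with
patient-level clustering (fellow eyes are correlated) and the three pairwise
Wald contrasts; ROC/AUC with DeLong 95% CI for the two clinical contrasts
(diabetic vs normal, PDR vs NPDR); and Spearman correlations of each
biomarker with age.  Writes group_comparisons.csv, roc_results.csv and
age_correlations.csv under results/.  Run 03_compute_biomarkers.py first.
"""

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from octlayers.stats import pairwise_contrasts, roc_auc, spearman

logging.basicConfig(level="INFO")
RESULTS = Path("results")
COVARS = ["patient_id", "eye", "group", "age", "sex"]


def main():
    bio = pd.read_csv(RESULTS / "biomarkers.csv")
    variables = [c for c in bio.columns if c not in COVARS]

    comparisons = []
    for var in variables:
        try:
            out = pairwise_contrasts(bio, var)
        except Exception as exc:
            logging.warning("GEE failed for %s: %s", var, exc)
            continue
        comparisons.append({"biomarker": var, **out})
    comp = pd.DataFrame(comparisons)
    comp.to_csv(RESULTS / "group_comparisons.csv", index=False, float_format="%.5g")
    sig = comp[comp["p_overall"] < 0.05]["biomarker"].tolist()
    print(f"GEE comparisons: {len(comp)} biomarkers, "
          f"{len(sig)} with overall p < 0.05: {sig}")

    rocs = []
    contrasts = {
        "diabetic_vs_normal": (bio["group"].isin(["NPDR", "PDR"]).astype(int),
                               bio.index >= 0),
        "PDR_vs_NPDR": ((bio["group"] == "PDR").astype(int),
                        bio["group"].isin(["NPDR", "PDR"])),
    }
    for name, (labels, mask) in contrasts.items():
        for var in variables:
            sub, lab = bio[mask], labels[mask]
            ok = sub[var].notna()
            if lab[ok].nunique() < 2:
                continue
            r = roc_auc(sub.loc[ok, var], lab[ok])
            rocs.append({"contrast": name, "biomarker": var,
                         "auc_pct": 100 * r.auc, "ci_low": r.ci_low,
                         "ci_high": r.ci_high, "polarity": r.polarity})
    roc = pd.DataFrame(rocs)
    roc.to_csv(RESULTS / "roc_results.csv", index=False, float_format="%.5g")
    for name in contrasts:
        best = roc[roc.contrast == name].nlargest(1, "auc_pct").iloc[0]
        print(f"best discriminator {name}: {best.biomarker} "
              f"AUC {best.auc_pct:.1f}% (CI {best.ci_low:.3f}-{best.ci_high:.3f})")

    ages = []
    for var in variables:
        ok = bio[var].notna()
        if ok.sum() < 3 or np.ptp(bio.loc[ok, var]) == 0:
            continue
        rho, p = spearman(bio.loc[ok, "age"], bio.loc[ok, var])
        ages.append({"biomarker": var, "spearman_rho": rho, "p": p})
    pd.DataFrame(ages).to_csv(RESULTS / "age_correlations.csv", index=False,
                              float_format="%.5g")
    print(f"wrote age_correlations.csv ({len(ages)} biomarkers)")


if __name__ == "__main__":
    main()
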