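#!/usr/bin/env python
"""Concentration-comparison statistics.

Computes the percent of correctly identified cells per type (relative
to 1x), antigens detected per cell with ANOVA/Tukey across arms, raw
ADT depth ratios with the detecting-vs-nondetecting Mann-Whitney test,
per-antibody dose-response fits, antigen sharing across the major
types, and the top marker genes per type.
"""

import json
import os

import numpy as np
import pandas as pd

import cite_titration as ct
from cite_titration import metrics, preprocess, thresholding
from cite_titration.model import ARM_FACTORS

RUN_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "run")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    dataset = ct.read_count_bundle(os.path.join(RUN_DIR, "bundle"))
    annotations = pd.read_csv(os.path.join(RUN_DIR, "annotations_gated.csv"))
    clr = np.load(os.path.join(RUN_DIR, "clr.npy"))
    call_table = pd.read_csv(os.path.join(RESULTS, "detectability_calls.csv"))
    calls = thresholding.calls_from_frame(call_table)

    pct = metrics.percent_correctly_identified(annotations)
    pct.round(1).to_csv(os.path.join(RESULTS, "percent_correct.csv"))
    print("percent correctly identified (vs 1x):")
    print(pct.round(1).to_string())

    binary = thresholding.binarize(clr, calls, annotations, dataset.panel)
    _, per_type = metrics.antigens_per_cell(binary, annotations)
    per_type.round(2).to_csv(os.path.join(RESULTS, "antigens_per_cell.csv"),
                             index=False)
    anova_rows = []
    for cell_type, sub in per_type.groupby("major_type"):
        groups = {}
        counts = binary.sum(axis=0)
        for arm in ARM_FACTORS:
            mask = (annotations.qc_pass & (annotations.arm_label == arm)
                    & (annotations.major_type == cell_type)).to_numpy()
            groups[arm] = counts[mask]
        result = metrics.compare_groups_anova(groups)
        anova_rows.append({"major_type": cell_type,
                           "F": round(result["F"], 2),
                           "p": result["p"]})
    pd.DataFrame(anova_rows).to_csv(
        os.path.join(RESULTS, "antigens_per_cell_anova.csv"), index=False)
    print("antigens per cell differ across concentrations in every type "
          f"(min F = {min(r['F'] for r in anova_rows):.0f})")

    depth = metrics.adt_depth_metrics(dataset.adt_counts, annotations,
                                      calls, dataset.panel)
    ratios = {k: round(v, 3) for k, v in depth["ratios_vs_reference"].items()}
    with open(os.path.join(RESULTS, "adt_depth.json"), "w") as fh:
        json.dump({"ratios_vs_1x": ratios,
                   "tests": depth["tests"]}, fh, indent=2)
    print(f"total ADT depth vs 1x: {ratios}")
    print("detecting vs non-detecting antibodies: "
          f"p(mean)={depth['tests']['mean_counts']['p']:.2e}, "
          f"p(sd)={depth['tests']['sd_counts']['p']:.2e}")

    dose = metrics.dose_response_table(clr, annotations, dataset.panel,
                                       ARM_FACTORS, detect_calls=calls)
    dose.round(4).to_csv(os.path.join(RESULTS, "dose_response.csv"),
                         index=False)
    print(f"dose-response fits for {dose.antibody_id.nunique()} detectable "
          f"antibodies ({(dose.b1 > 0).mean():.0%} with positive slope)")

    _, sharing = metrics.antigen_sharing(binary, annotations, dataset.panel,
                                         calls)
    with open(os.path.join(RESULTS, "antigen_sharing.json"), "w") as fh:
        json.dump(sharing, fh, indent=2)
    print(f"antigen sharing at 1x: {sharing}")

    keep = annotations.qc_pass.to_numpy()
    rna = np.asarray(dataset.rna_counts.todense(), float)[:, keep]
    logged = preprocess.lognorm_rna(rna)
    markers = metrics.marker_genes(
        logged, annotations[keep].reset_index(drop=True), dataset.gene_ids)
    markers.round(4).to_csv(os.path.join(RESULTS, "marker_genes.csv"),
                            index=False)
    n_sig = int(markers.significant.sum())
    print(f"marker genes: {n_sig} significant top-10 entries across types")


if __name__ == "__main__":
    main()
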