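#!/usr/bin/env python
"""Droplet QC, hashtag demultiplexing, and normalization.

Applies the four filters (mitochondrial content > 10%, total ADT
outside [200, 100000], hashtag max/mean ratio > 3, all hashtags <= 20)
and assigns each surviving singlet to its concentration arm; then CLR-
normalizes the antibody counts.  Writes the QC report and caches the
annotations and CLR matrix for the next steps.
"""

import json
import os

import numpy as np

import cite_titration as ct
from cite_titration import preprocess
from cite_titration.model import annotations_to_frame

RUN_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "run")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    dataset = ct.read_count_bundle(os.path.join(RUN_DIR, "bundle"))
    annotations, report = preprocess.run_qc(dataset)
    clr = preprocess.clr_normalize(dataset.adt_counts)

    frame = annotations_to_frame(annotations)
    frame.to_csv(os.path.join(RUN_DIR, "annotations_qc.csv"), index=False)
    np.save(os.path.join(RUN_DIR, "clr.npy"), clr)
    with open(os.path.join(RESULTS, "qc_report.json"), "w") as fh:
        fh.write(report.to_json())

    print(f"QC: {report.n_input} droplets in, {report.n_remaining} kept")
    for reason, n in report.n_removed_per_reason.items():
        print(f"  removed {n:5d}  ({reason})")
    per_arm = frame[frame.qc_pass].arm_label.value_counts().to_dict()
    print(f"surviving singlets per arm: {per_arm}")


if __name__ == "__main__":
    main()
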