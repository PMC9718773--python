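"""Shared fixtures.

``default_run`` executes the full pipeline once per session on the
default synthetic dataset (the study conditions: 192-plex panel, four
concentration arms, 2000 droplets per arm) and is shared by all
recovery and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import cite_titration as ct
from cite_titration import gating, panel as panelmod, preprocess, thresholding
from cite_titration.model import annotations_to_frame

PIPELINE_SEED = 12345


@dataclass
class PipelineRun:
    config: ct.GeneratorConfig
    dataset: ct.TitrationDataset
    truth: ct.SyntheticTruth
    annotations: "object"       # DataFrame with gate labels
    qc_report: ct.QCReport
    clr: np.ndarray
    gate_thresholds: gating.GateThresholds
    calls: list
    plan: panelmod.PanelPlan

    def detectable_count(self, arm_label: str) -> int:
        return sum(1 for c in self.calls
                   if c.arm_label == arm_label and c.detectable)


@pytest.fixture(scope="session")
def default_run() -> PipelineRun:
    config = ct.default_config()
    dataset, truth = ct.generate_dataset(config, seed=PIPELINE_SEED)
    annotations, report = preprocess.run_qc(dataset)
    clr = preprocess.clr_normalize(dataset.adt_counts)
    thresholds = gating.derive_gate_thresholds(clr, annotations,
                                               dataset.panel, seed=0)
    gated = annotations_to_frame(
        gating.gate_all(clr, annotations, thresholds, dataset.panel))
    calls = thresholding.call_all_arms(clr, gated, dataset.panel)
    plan = panelmod.build_optimized_panel(calls, dataset.panel)
    return PipelineRun(config=config, dataset=dataset, truth=truth,
                       annotations=gated, qc_report=report, clr=clr,
                       gate_thresholds=thresholds, calls=calls, plan=plan)


@pytest.fixture()
def tiny_dataset():
    """A small clean dataset (no doublets/negatives/low-viability)."""
    config = ct.simulate.clean_config(ct.default_config(n_cells_per_arm=80))
    dataset, truth = ct.generate_dataset(config, seed=11)
    return config, dataset, truth
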