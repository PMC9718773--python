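# cite-titration

Antibody titration analysis for CITE-Seq experiments on human PBMCs.

CITE-Seq measures surface proteins alongside transcriptomes by
sequencing antibody-derived tags (ADTs) from oligo-tagged antibodies.
Antibody cocktails are a dominant cost of such experiments, and most
panels are run at the manufacturer-recommended concentration without
evidence that it is needed. This package implements the analysis of a
four-arm titration — cells stained at 2x, 1x, 0.2x and 0.04x of the
recommended dose, hashtagged per arm and pooled — that answers, per
antibody: *is the target antigen detectable at this concentration, and
what is the lowest concentration that loses no information?* From the
answers it assembles an optimized panel and quantifies the antibody
amount saved.

It is aimed at groups designing or trimming CITE-Seq antibody panels,
and at method developers who need a fully ground-truthed synthetic
titration dataset.

## What it computes

For droplet counts `x` the antibody data is centered-log-ratio
normalized per cell, `clr_i = ln(x_i+1) − mean_j ln(x_j+1)`. Per
antibody and concentration, a two-component Gaussian mixture (tied
variance, multi-start EM) splits stained from background cells;
separation is Ashman's D = |μ₁−μ₂|/√((σ₁²+σ₂²)/2). An antibody is
detectable when D ≥ 2, the positive component is non-negligible, and it
clears the pooled isotype-control background — or, for antigens present
on all cells, when ≥90% of cells exceed that background. Thresholds sit
at the 95th percentile of the negative population (5th percentile of
the positive population for ubiquitous antigens). The optimal
concentration is the lowest detectable arm retaining ≥80% of the best
separation; the panel's cost proxy is the **relative antibody amount**
Σ(count_class × factor_class)/n_total.

The pipeline also gates the five major PBMC types
(B: CD3⁻CD19⁺; CD4 T: CD3⁺CD4⁺CD8⁻; CD8 T: CD3⁺CD4⁻CD8⁺;
classical monocytes: CD3⁻CD19⁻CD14⁺CD16⁻; NK: CD3⁻CD19⁻CD14⁻CD56⁺),
demultiplexes hashtags (max/mean HTO ratio > 3 → doublet, all
hashtags ≤ 20 → negative), applies droplet QC, and computes
concentration-comparison statistics: correctly identified cells per
type, antigens per cell (ANOVA/Tukey), ADT depth ratios
(Mann–Whitney), log-link dose–response fits, antigen sharing across
types, and Wilcoxon/Bonferroni marker genes.

A synthetic-data generator (`cite_titration.simulate`) emulates the
whole experiment — saturation-binding signal, concentration-scaled
ambient background, hashtag doublets, low-viability cells — with known
per-antibody and per-droplet ground truth, so every stage is testable
without the original sequencing data. See `docs/methods.md` for the
model and all defaults.

## Worked example

The analysis is organised as numbered scripts that chain over a run
directory:

```bash
python analysis/01_simulate.py --seed 12345
python analysis/02_qc_normalize.py
python analysis/03_gate.py
python analysis/04_threshold.py
python analysis/05_metrics.py
python analysis/06_optimize.py
```

The run prints, among other things:

```
QC: 8000 droplets in, 7188 kept
composition at the recommended concentration:
  CD4T        54.5%
  ...
    2x: 124 of 188 antibodies detectable (66.0%)
    1x: 124 of 188 antibodies detectable (66.0%)
  0.2x: 114 of 188 antibodies detectable (60.6%)
 0.04x:  63 of 188 antibodies detectable (33.5%)
total ADT depth vs 1x: {'2x': 1.505, '1x': 1.0, '0.2x': 0.355, '0.04x': 0.123}
antigen sharing at 1x: {'all_five': 16, 'exclusive_B': 21, 'exclusive_CM': 17,
                        'exclusive_NK': 5, 'exclusive_other': 0, 'multi': 65}
optimal concentration classes: {'2x': 7, '1x': 81, '0.2x': 32, '0.04x': 8, 'drop': 64}
optimized panel keeps 128 of 192 antibodies
relative antibody amount: 0.53 (47% less than the tested panel,
                                26% less than an all-1x 137-plex)
```

Reading: two thirds of the antibodies detect their antigen at the
recommended dose and doubling the dose adds nothing; dilution to 0.2x
and 0.04x loses antibodies roughly as the ground truth dictates
(116 and 64 of 188). One third of the panel shows no signal on PBMCs at
any dose and is dropped. Keeping each remaining antibody at its lowest
sufficient concentration cuts the total antibody amount roughly in
half while retaining the panel's information. Tables behind each
number land in `results/`.

Library use is a few lines:

```python
import cite_titration as ct
from cite_titration import preprocess, gating, thresholding, panel

config = ct.default_config()
dataset, truth = ct.generate_dataset(config, seed=1)
annotations, report = preprocess.run_qc(dataset)
clr = preprocess.clr_normalize(dataset.adt_counts)
gates = gating.derive_gate_thresholds(clr, annotations, dataset.panel)
gated = ct.model.annotations_to_frame(
    gating.gate_all(clr, annotations, gates, dataset.panel))
calls = thresholding.call_all_arms(clr, gated, dataset.panel)
plan = panel.build_optimized_panel(calls, dataset.panel)
print(plan.class_counts(), round(plan.relative_amount, 2))
```

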