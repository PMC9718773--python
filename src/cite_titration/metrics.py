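"""Concentration-comparison statistics.

Covers the quantitative readouts used to compare the four staining
concentrations: the percentage of correctly identified cells per type
(relative to the recommended concentration), antigens detected per cell
with ANOVA/Tukey group comparisons, raw ADT depth metrics with a
Mann-Whitney test of detecting vs non-detecting antibodies, per-antibody
dose-response fits on a log link, antigen sharing across the major cell
types, and one-vs-rest Wilcoxon marker genes with Bonferroni control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .gating import GATED_TYPES
from .model import ValidationError
from .thresholding import percentile


@dataclass
class DoseResponseFit:
    """Log-link fit mean(c) = exp(b0 + b1 * log10 c) to per-arm averages."""

    antibody_id: str
    major_type: str
    b0: float
    b1: float
    fitted_means: dict[str, float]
    flat: bool = False


@dataclass
class SharingProfile:
    antibody_id: str
    expressing_types: frozenset
    category: str

    def __post_init__(self) -> None:
        n = len(self.expressing_types)
        expected = _category(self.expressing_types)
        if self.category != expected or n > 5:
            raise ValidationError("sharing category inconsistent with set")


def _category(types: frozenset) -> str:
    if len(types) == 5:
        return "all_five"
    if len(types) == 1:
        only = next(iter(types))
        if only in ("B", "CM", "NK"):
            return f"exclusive_{only}"
        return "exclusive_other"
    return "multi"


def _to_frame(annotations) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        return annotations
    return pd.DataFrame([vars(a) for a in annotations])


def percent_correctly_identified(annotations,
                                 reference_arm: str = "1x") -> pd.DataFrame:
    """Per-type cell proportions at each arm, normalized to the
    proportions at the recommended concentration (x100); the reference
    arm is 100% for every detected type by construction.  Types absent
    at the reference arm are reported as missing."""
    ann = _to_frame(annotations)
    gated = ann[ann["qc_pass"] & ann["major_type"].isin(GATED_TYPES)]
    if reference_arm not in set(ann["arm_label"].dropna()):
        raise ValidationError(f"reference arm {reference_arm!r} not present")
    totals = ann[ann["qc_pass"]].groupby("arm_label").size()
    props = (gated.groupby(["arm_label", "major_type"]).size()
             .unstack(fill_value=0)
             .reindex(index=totals.index, columns=GATED_TYPES, fill_value=0)
             .div(totals, axis=0))
    ref = props.loc[reference_arm]
    pct = 100.0 * props.div(ref, axis=1)
    pct[ref.index[ref == 0]] = np.nan
    return pct


def antigens_per_cell(binary_calls: np.ndarray,
                      annotations) -> tuple[np.ndarray, pd.DataFrame]:
    """Number of antigens detected per cell (column sums of the
    positivity matrix) and mean +/- SD grouped by (major type, arm)."""
    ann = _to_frame(annotations)
    if binary_calls.shape[1] != len(ann):
        raise ValidationError("positivity matrix not aligned to annotations")
    per_cell = binary_calls.sum(axis=0).astype(int)
    gated = ann["qc_pass"] & ann["major_type"].isin(GATED_TYPES)
    table = (pd.DataFrame({"major_type": ann["major_type"],
                           "arm_label": ann["arm_label"],
                           "n_antigens": per_cell})[gated]
             .groupby(["major_type", "arm_label"])["n_antigens"]
             .agg(["mean", "std", "count"]).reset_index())
    return per_cell, table


def compare_groups_anova(groups: dict[str, np.ndarray]) -> dict:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons."""
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValidationError("ANOVA needs >= 2 groups of >= 2 observations")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f_stat, p = scipy.stats.f_oneway(*arrays)
    if all(np.allclose(a, np.concatenate(arrays).mean()) for a in arrays):
        f_stat, p = 0.0, 1.0
    tukey = scipy.stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({"group_a": names[i], "group_b": names[j],
                         "mean_diff": arrays[i].mean() - arrays[j].mean(),
                         "p_adj": float(tukey.pvalue[i, j])})
    return {"F": float(f_stat), "p": float(p),
            "tukey": pd.DataFrame(rows)}


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null distribution for small
    samples without ties, normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method=method)
    return float(res.statistic), float(res.pvalue)


def adt_depth_metrics(adt_counts, annotations, detect_calls, panel,
                      reference_arm: str = "1x") -> dict:
    """Raw ADT depth summaries and the detecting-vs-nondetecting test.

    Returns per-arm total ADT (and ratio to the reference arm), the
    per-antibody mean and SD of counts per cell at the reference arm,
    and two-sided Mann-Whitney U tests comparing antibodies that detect
    their target at the reference arm against those that do not, on both
    the mean and the SD statistic.
    """
    ann = _to_frame(annotations)
    x = np.asarray(adt_counts.todense() if sp.issparse(adt_counts)
                   else adt_counts, dtype=float)
    qc = ann["qc_pass"].to_numpy()
    arms = ann["arm_label"].to_numpy(dtype=object)

    arm_totals = {}
    for arm in pd.unique(ann["arm_label"].dropna()):
        cols = np.flatnonzero(qc & (arms == arm))
        arm_totals[arm] = float(x[:, cols].sum())
    if reference_arm not in arm_totals or arm_totals[reference_arm] == 0:
        raise ValidationError("reference arm absent or empty")
    ratios = {a: t / arm_totals[reference_arm] for a, t in arm_totals.items()}

    ref_cols = np.flatnonzero(qc & (arms == reference_arm))
    per_ab = pd.DataFrame({
        "antibody_id": [c.antibody_id for c in detect_calls
                        if c.arm_label == reference_arm],
        "detectable": [c.detectable for c in detect_calls
                       if c.arm_label == reference_arm]})
    per_ab = per_ab.drop_duplicates("antibody_id").reset_index(drop=True)
    row_of = {e.antibody_id: i for i, e in enumerate(panel.entries)}
    means = x[:, ref_cols].mean(axis=1)
    sds = x[:, ref_cols].std(axis=1, ddof=1)
    per_ab["mean_counts"] = [means[row_of[a]] for a in per_ab["antibody_id"]]
    per_ab["sd_counts"] = [sds[row_of[a]] for a in per_ab["antibody_id"]]

    det = per_ab[per_ab["detectable"]]
    ndet = per_ab[~per_ab["detectable"]]
    tests = {}
    if len(det) and len(ndet):
        for stat in ("mean_counts", "sd_counts"):
            u, p = mann_whitney_exact(det[stat].to_numpy(),
                                      ndet[stat].to_numpy())
            tests[stat] = {"U": u, "p": p}
    return {"arm_totals": arm_totals, "ratios_vs_reference": ratios,
            "per_antibody": per_ab, "tests": tests}


def fit_dose_response(mean_by_arm: dict[str, float],
                      arm_factors: dict[str, float],
                      antibody_id: str = "", major_type: str = "",
                      ) -> DoseResponseFit:
    """Least-squares fit of mean(c) = exp(b0 + b1 log10 c) to the per-arm
    average CLR values (clipped at zero).

    This mirrors the display-grade log-link curve drawn through per-arm
    averages; it is not a count-likelihood inference.  All-zero means are
    flagged as a flat fit with b1 = 0.
    """
    arms = [a for a in mean_by_arm if a in arm_factors]
    if len(arms) < 3:
        raise ValidationError("dose-response fit needs >= 3 arms")
    y = np.clip([float(mean_by_arm[a]) for a in arms], 0.0, None)
    t = np.log10([arm_factors[a] for a in arms])
    if np.all(y == 0):
        return DoseResponseFit(antibody_id, major_type, -np.inf, 0.0,
                               {a: 0.0 for a in arms}, flat=True)
    if np.allclose(y, y[0]):
        b0, b1 = float(np.log(y[0])), 0.0
    else:
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        else:
            slope, intercept = 0.0, np.log(max(y.max(), 1e-8))
        from scipy.optimize import least_squares
        res = least_squares(
            lambda b: np.exp(b[0] + b[1] * t) - y,
            x0=[intercept, slope], method="lm", xtol=1e-14, ftol=1e-14)
        b0, b1 = float(res.x[0]), float(res.x[1])
    fitted = {a: float(np.exp(b0 + b1 * ti)) for a, ti in zip(arms, t)}
    return DoseResponseFit(antibody_id, major_type, b0, b1, fitted)


def dose_response_table(clr_adt: np.ndarray, annotations, panel,
                        arm_factors: dict[str, float],
                        detect_calls=None) -> pd.DataFrame:
    """Per (antibody, major type): mean CLR per arm and the fitted
    (b0, b1).  Restricted to antibodies detectable at >= 1 arm when
    calls are given."""
    ann = _to_frame(annotations)
    keep_ids = None
    if detect_calls is not None:
        keep_ids = {c.antibody_id for c in detect_calls if c.detectable}
    rows = []
    gated = ann["qc_pass"] & ann["major_type"].isin(GATED_TYPES)
    arms_col = ann["arm_label"].to_numpy(dtype=object)
    types_col = ann["major_type"].to_numpy(dtype=object)
    for i, e in enumerate(panel.entries):
        if keep_ids is not None and e.antibody_id not in keep_ids:
            continue
        for t in GATED_TYPES:
            mean_by_arm = {}
            for a in arm_factors:
                cols = np.flatnonzero(gated.to_numpy()
                                      & (arms_col == a) & (types_col == t))
                if cols.size:
                    mean_by_arm[a] = float(clr_adt[i, cols].mean())
            if len(mean_by_arm) < 3:
                continue
            fit = fit_dose_response(mean_by_arm, arm_factors,
                                    e.antibody_id, t)
            row = {"antibody_id": e.antibody_id, "major_type": t,
                   "b0": fit.b0, "b1": fit.b1}
            row.update({f"mean_{a}": m for a, m in mean_by_arm.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def antigen_sharing(binary_calls: np.ndarray, annotations, panel,
                    detect_calls, arm_label: str = "1x",
                    positivity_fraction: float = 0.10,
                    ) -> tuple[list[SharingProfile], dict[str, int]]:
    """Which major types express each detectable antibody at one arm.

    An antibody is "expressed in" a type iff at least
    ``positivity_fraction`` of that type's cells are positive.
    """
    ann = _to_frame(annotations)
    detectable = {c.antibody_id for c in detect_calls
                  if c.arm_label == arm_label and c.detectable}
    arms_col = ann["arm_label"].to_numpy(dtype=object)
    types_col = ann["major_type"].to_numpy(dtype=object)
    gated = (ann["qc_pass"].to_numpy() & (arms_col == arm_label))
    profiles = []
    counts = {"all_five": 0, "exclusive_B": 0, "exclusive_CM": 0,
              "exclusive_NK": 0, "exclusive_other": 0, "multi": 0}
    for i, e in enumerate(panel.entries):
        if e.antibody_id not in detectable:
            continue
        expressed = set()
        for t in GATED_TYPES:
            cols = np.flatnonzero(gated & (types_col == t))
            if cols.size and binary_calls[i, cols].mean() >= positivity_fraction:
                expressed.add(t)
        if not expressed:
            continue
        cat = _category(frozenset(expressed))
        profiles.append(SharingProfile(e.antibody_id, frozenset(expressed), cat))
        counts[cat] += 1
    return profiles, counts


def marker_genes(lognorm_rna: np.ndarray, annotations, gene_ids,
                 top_k: int = 10, alpha: float = 0.05,
                 min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker genes per major type.

    P values are Bonferroni-corrected by the number of genes tested;
    genes are ranked by adjusted p, then by effect size (difference of
    group means on the log scale).  Types with fewer than ``min_cells``
    cells are skipped.
    """
    ann = _to_frame(annotations)
    gated = ann["qc_pass"] & ann["major_type"].notna()
    types_col = ann["major_type"].to_numpy(dtype=object)
    use = gated.to_numpy()
    present = [t for t in pd.unique(types_col[use]) if t is not None]
    if sum((types_col[use] == t).sum() >= min_cells for t in present) < 2:
        raise ValidationError("marker finding needs >= 2 types with cells")
    n_genes = len(gene_ids)
    rows = []
    for t in present:
        in_t = use & (types_col == t)
        rest = use & (types_col != t)
        if in_t.sum() < min_cells or rest.sum() < min_cells:
            continue
        a = lognorm_rna[:, in_t]
        b = lognorm_rna[:, rest]
        stat, p = scipy.stats.mannwhitneyu(a, b, axis=1,
                                           alternative="two-sided")
        p_adj = np.minimum(1.0, p * n_genes)
        effect = a.mean(axis=1) - b.mean(axis=1)
        order = np.lexsort((-effect, p_adj))
        for g in order[:top_k]:
            rows.append({"major_type": t, "gene": gene_ids[g],
                         "p_raw": float(p[g]), "p_adj": float(p_adj[g]),
                         "log_fold_effect": float(effect[g]),
                         "significant": bool(p_adj[g] < alpha)})
    return pd.DataFrame(rows)
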